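# Methods

This note documents the models, rules, parameters and deliberate
simplifications behind `acescreen`, in the spirit of a statistical
package's methods appendix. Nothing here states an empirical result the
test suite or `scripts/acceptance.py` does not itself compute.

## The ontology and its inference semantics

The ontology is a set of categorized concepts plus axioms
`subject relation object` with relation in `{is_a, equivalent_to, causes,
leads_to, risk_factor_of}` and mandatory provenance. Design choices:

- **Causal relations are interchangeable for closure.** `causes`,
  `leads_to` and `risk_factor_of` differ rhetorically, not inferentially,
  in screening practice ("obesity is a risk factor of diabetes" and
  "blight causes exposure to toxicants" both license the same forward
  step). Each keeps its label on edges so explanations read naturally.
- **Subtype inheritance in causal closure.** `closure(c)` may take upward
  is-a hops between causal steps: a subtype is subject to its supertypes'
  causal axioms (lead-based paint, being a toxicant, inherits the
  toxicant→asthma risk). Only concepts *entered through a causal axiom*
  are reported; pure supertypes are traversal scaffolding, though the
  witnessing chain records the is-a hops for the rendered explanation.
  Reported order is breadth-first, lexicographic within a frontier, so
  output is deterministic.
- **Equivalence** expands to mutual subsumption in the reachability index
  only. The acyclicity invariant is checked on declared `is_a` axioms; a
  declared equivalence is not a hierarchy defect.
- **Entity tagging is maximal-munch**: candidates (lexicon phrases plus
  regex patterns for open-valued types such as zip codes and ages) are
  sorted by start position then descending length, and consumed greedily
  left to right, so "lead-based paint" always beats "paint". Matching is
  case-insensitive with whitespace-tolerant phrase patterns; spans index
  the original text. Word boundaries are alphanumeric, so "male" never
  fires inside "female".

## Dialog engine

Intent matching is intentionally transparent rather than statistical: an
utterance is scored against each candidate intent by the number of tagged
entity types shared with the intent's training phrases, with a Jaccard
token-overlap fallback (threshold 0.5) for entity-free phrasings ("I have
several issues"). Candidates are restricted to follow-ups of active
contexts when any exist, falling back to top-level intents. Ties break
toward the deepest intent in the parent hierarchy, then lexicographic
name — an arbitrary but documented rule, since nothing in the domain
dictates one.

Contexts live on a LIFO stack with a default lifespan of 5 turns,
decremented once per turn; re-activation resets the lifespan and moves the
context to the top. Mandatory parameters are prompted in their configured
order; a cooperative user therefore reaches fulfillment in at most
|required_params| prompts. Events activate the (unique) intent that
registers them exactly as a user match would, including slot filling.
Issue ordering is stable mention order, except that an issue mentioned
within 40 characters after a priority cue ("prefer", "first", "mostly
concerned", ...) is promoted. All timestamps come from an injectable
clock (`FakeClock` advances 0.05 s per call), making transcripts, latencies
and logs byte-reproducible.

## Surveillance and scoring

The ACE questionnaire pool holds the ten classic categories (abuse ×3,
neglect ×2, household dysfunction ×5). The score is the count of positive
items; **inferred positives count identically to provided ones**, since an
axiom-derived adversity (emotional neglect from night terror) is exactly
the signal early screening exists to surface. Strata default to 0 / 1–3 /
≥4 → "no reported ACEs" / "moderate" / "high risk"; the boundaries are
configuration (`score_rules`) because stratification rules are a clinical
policy, not a property of the count.

Outcome hypotheses merge two evidence routes per observed symptom: the
ontology's causal closure, and a bundled evidence table keyed by
(stratum, symptom) that stands in for live literature lookup. Every
hypothesis carries non-empty provenance and is replayable through one of
those routes (a tested invariant).

Intervention policy: SDoH issues map to resource-backed interventions
(food pantry, school, legal aid, job search, housing); behavioral and
developmental symptoms map to a psychologist appointment; a medical
appointment plus clinic search fires only when the stratum is "high risk"
*and* an outcome was inferred — a deliberate escalation threshold so a
moderate-score session with an incidental inferred outcome is not pushed
to a physician visit.

## Personal knowledge graph

Each session's graph starts with a single user node. Parameters add
concept and value nodes (idempotently), linked upward along is-a;
saturation then runs to fixpoint: a causal axiom fires forward when its
subject concept is present, and fires *abductively* when its object is a
symptom-category concept present in the graph (the edge stays in axiom
direction, flagged `abduced`). Abduction is restricted to symptom
consequents: observing an effect justifies suspecting its recorded cause
only where the ontology marks the effect as an observable sign; back-
chaining from outcomes in general would flood the graph with unfounded
suspicions.

Neighborhood attachment adds a `livesIn` edge to a neighborhood instance,
records every metric's value, and causally expands **only the
maximum-valued metric's concept** (all tied metrics on a tie; none when
every metric is zero). Non-dominant metrics stay in the graph as values
but are excluded from later forward firing (`suppressed_causal`), so a
20%-blight neighborhood never materializes the blight→asthma chain.

Edge confidences are fixed per knowledge source — ontology 1.0,
neighborhood repository 0.9, literature 0.8, questionnaire 1.0 — surfaced
in explanations but not yet used for ranking; no data exists here to fit
anything better.

Resource suggestion filters by specialty subsumption, language, and
haversine distance from the user's zip centroid (default radius 10 miles —
"a small radius" made concrete), ranking by distance then id. With no zip
on the graph the radius filter is skipped and the result flagged.
**Language preference** uses an explicit parameter when stated, otherwise
a documented ethnicity→language default (hispanic → spanish). This
reproduces the intended demographic personalization but is a blunt
simplification with obvious equity caveats — ethnicity does not determine
language — and should be replaced by an asked preference in any real
deployment.

Explanations take the shortest directed path from the user node to the
recommendation; ties prefer fewer inferred edges, then the
lexicographically least node sequence (a single highlighted route needs
*some* deterministic selection rule). The metapath abstracts nodes to
their kind (concept nodes to their ontology category) and edges to their
relation label; `MetaPath.match` re-instantiates it on another user's
graph, the mechanism for route reuse across similar users.

## Analytics

Session logs are flat JSONL turn records grouped by session id; malformed
records are skipped and tallied, never fatal. "Exit intent" is defined as
the last matched intent of a session — the log alone cannot distinguish
completion from abandonment. Mismatch percentage is mismatched turns over
all turns; path counts always sum to the session count (a tested
conservation law). Route suggestion is the modal path of the cohort
matching exactly on coarse age group and ethnicity group; anything
fancier (collaborative filtering, community detection) is out of scope.
Percentages are rendered to one decimal with raw values retained.

## Synthetic fixtures: what they do and do not show

The bundled ontology is deliberately compact: the concepts, lexicon
entries and causal axioms needed by the four walkthrough scenarios, the
ten-category question pool, and a handful of hierarchy scaffolds. The
neighborhood table fixes zip 38103 at 80% blight (its strict maximum)
with control zips for other-maximum, all-zero and tie cases. The resource
directory (seeded, ≥20 entries) guarantees a Spanish-speaking pediatric
asthma clinic at the 38103 centroid and everyday resources near each core
zip; coordinates and names are plausible synthetic points, not real
facilities, to avoid implying actual referrals. Scenario 4's score of 4
is realized as: parental separation (stated), emotional neglect
(inferred), plus two scripted positive questionnaire answers (household
mental illness, witnessing household violence) — the last two are a
synthetic choice fixed by the fixture, flagged in its notes. Simulated
session logs (default 100 sessions, per-turn mismatch probability 0.1,
gamma-jittered latencies, profile-weighted routes) exercise the analytics
layer at a size that keeps the whole suite under a few seconds.

Passing tests on these fixtures demonstrate the *mechanics* — tagging,
inference, scoring, filtering, explanation, aggregation — under clean,
unambiguous language and a small closed vocabulary. They do not show
robustness to real conversational text (typos, negation, paraphrase,
code-switching), real ontology scale, or the clinical validity of the
axioms and thresholds; those require a curated ontology and field data.

## Numerical and degenerate-input choices

Haversine uses a spherical Earth of radius 3958.8 miles; at city scale the
ellipsoidal error is far below the 10-mile radius granularity. Metric
values print as integers when integral. Empty logs yield a zero-total
report; an empty script yields an empty transcript and a score-0 alert;
unknown entity types, unknown zips and unreachable services degrade to
warnings/flags rather than exceptions, while configuration errors
(unknown fulfillment service, ambiguous event registration, malformed
ontology) fail fast. Score strata must tile the non-negative integers
from 0, so every score has exactly one stratum.

## Known limitations

- Intent matching has no notion of negation or tense ("no mold" tags
  mold); acceptable for scripted intake prompts, wrong for free text.
- Abduction emits suspicions, not diagnoses; confidences are static
  configuration.
- The ethnicity→language default noted above.
- The graph grows monotonically within a session; retraction is not
  supported — a "no" answer records a negative questionnaire item but
  does not remove an abduced suspicion, which stays visible with its
  provenance for the practitioner to judge.
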