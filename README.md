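# acescreen

An explainable, ontology-driven screening assistant for **adverse childhood
experiences (ACEs)** and **social determinants of health (SDoH)**, aimed at
family-resilience intake settings: a rule-based conversational agent collects
contextual parameters (symptoms, household circumstances, demographics, zip
code), surveillance services score and stratify the ACE questionnaire, and a
personalized knowledge-graph recommender suggests follow-up questions and
geocoded community resources — every recommendation justified by an explicit,
provenance-labelled inference path. It is intended for informatics teams
prototyping knowledge-driven clinical decision support, and for anyone who
wants a fully offline, reproducible testbed for explanation-first
recommendation over a causal ontology.

## The model

The knowledge base is an ontology `O = (C, A)` with concepts `C` (ACE, SDoH,
symptom, outcome, and demographic categories under is-a hierarchies) and
axioms `A` of the form *s r o* with `r ∈ {is_a, equivalent_to, causes,
leads_to, risk_factor_of}`, each carrying a provenance source (ontology,
literature, neighborhood repository, questionnaire). Three inference
primitives drive the system:

- **Subsumption** `a ⊑ b`: reflexive-transitive reachability over is-a
  (equivalence expands to mutual subsumption).
- **Causal closure** `closure(c)`: concepts reachable from `c` through
  causal axioms, with upward is-a hops allowed so a subtype inherits its
  supertypes' axioms (lead-based paint *is a* toxicant; toxicants are a
  *risk factor of* asthma). Each reached concept keeps one witnessing axiom
  chain and its provenance list.
- **Saturation**: per-session forward chaining to fixpoint over the concepts
  present in the user's personal graph, plus abduction for causal axioms
  whose consequent is an observed *symptom* (night terror ⇒ suspected
  emotional neglect).

The **ACE score** is `X = #{questionnaire items answered positive}`, counting
provided and inferred positives alike, stratified by configurable rules
(default: 0 → no reported ACEs, 1–3 → moderate, ≥4 → high risk). Outcome
hypotheses answer *"given an ACE score of X and symptoms S1…Sn, what should
be screened for early?"* by merging causal closure of the symptoms with an
evidence table keyed by (stratum, symptom). Resources are filtered by
specialty subsumption, preferred language, and great-circle (haversine)
radius around the user's zip centroid, and the winning recommendation is
explained by the shortest provenance-complete path from the user node,
together with its type-level **metapath**, reusable for future users with
similar parameters.

## Worked example

Everything runs from generated fixtures — no downloads:

```bash
acescreen fixtures generate --out fixtures --seed 1
acescreen chat --fixtures fixtures --script fixtures/scenario4.jsonl --out-dir run4
```

The scripted conversation opens with *"I am a Hispanic 21-year-old female
living in Memphis. My 6-year-old child experiences night terror. I have
recently separated from my husband."*, answers the zip-code prompt with
38103, and works through the remaining ACE questionnaire. The run ends with:

```
ACEs alert: score 4 (high risk)
Symptoms: night terror
ACEs detected: provided (parental separation); inferred (emotional neglect)
Screen early for asthma (evidence: ace_lit)
Interventions: schedule medical appointment
Suggested resource: Downtown Pediatric Asthma Clinic (0.0 mi)
Why this recommendation:
user session-1 --[has_concept]--> zip code  (source: Compact ACEs/SDoH screening ontology (bundled synthetic edition)., confidence 1.00)
zip code --[locatedIn]--> neighborhood  (source: Neighborhood-level indicator repository keyed by zip code (synthetic)., confidence 0.90)
neighborhood --[hasCharacteristic]--> blight prevalence  (source: Neighborhood-level indicator repository keyed by zip code (synthetic)., confidence 0.90)
blight prevalence --[causes]--> exposure to toxicants  (source: Compact ACEs/SDoH screening ontology (bundled synthetic edition)., confidence 1.00)
exposure to toxicants --[leads_to]--> asthma  (source: Compact ACEs/SDoH screening ontology (bundled synthetic edition)., confidence 1.00)
asthma --[suggests_resource]--> Downtown Pediatric Asthma Clinic  (source: Neighborhood-level indicator repository keyed by zip code (synthetic)., confidence 0.90)
```

Reading the numbers: the score of 4 counts parental separation (stated),
emotional neglect (inferred from night terror via an axiom), and two positive
questionnaire answers; "high risk" is the stratum that score falls in. The
explanation block is the concrete inference path: the user's zip code places
them in a neighborhood whose dominant metric (80% blight prevalence) causally
chains to asthma, which — with the Spanish language preference defaulted from
the stated ethnicity — selects the nearest matching pediatric clinic. Each
hop names its knowledge source and confidence. `run4/` then contains the
transcript, a JSONL session log, and the graph (`graph.json`; re-export with
`acescreen graph export --in run4/graph.json --format dot --out run4.dot`).

Population analytics over many sessions:

```bash
acescreen analytics report --logs fixtures/sessions.jsonl --out report.json
```

which writes intent popularity (sessions matched / total uses), exit rates,
mismatch percentage, mean response time, and the conversational-path
frequency table, plus a markdown rendering.

## Layout

- `src/acescreen/ontology.py` — ontology model, JSON serialization,
  subsumption / closure / entity tagging / risk-factor classification
- `src/acescreen/dialog.py` — intents, context stack, slot filling, events,
  fulfillment dispatch, issue ordering
- `src/acescreen/surveillance.py` — SDoH detection, ACE question selection,
  scoring, outcome hypotheses, neighborhood metrics provider
- `src/acescreen/graph.py` — personal knowledge graph, saturation,
  neighborhood attachment, question/resource suggestion, explanation paths,
  exports (JSON / GraphML / DOT)
- `src/acescreen/session.py` — end-to-end chat orchestration
- `src/acescreen/analytics.py` — session-log aggregation and route guidance
- `src/acescreen/fixtures.py` — synthetic ontology, scenarios, directories,
  simulated logs
- `src/acescreen/cli.py` — `acescreen` command-line interface

See `docs/methods.md` for the modelling assumptions, parameter defaults, and
known limitations.
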