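"""ACEs and SDoH surveillance services.

These are the fulfillment backends of the dialog engine: detecting
SDoH-classified risk factors (with their causal consequences and
neighborhood metrics), selecting follow-up questions from the ACE pool,
counting the ACE screening score, stratifying it, and hypothesizing
negative health outcomes to screen for — "given an ACE score and observed
symptoms, what should this child be screened for early?" — each hypothesis
citing the knowledge source that supports it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd

from .ontology import AceQuestion, CausalConsequence, Category, Ontology

EVIDENCE_COLUMNS = ["stratum", "symptom", "outcome", "source", "citation"]


@dataclass
class SdohFinding:
    """One SDoH-classified risk factor detected in conversation."""

    concept: str
    value: str
    causal_consequences: list[CausalConsequence]
    neighborhood_metrics: Optional[dict[str, float]] = None
    metrics_missing: bool = False


@dataclass(frozen=True)
class AceAnswer:
    question_id: str
    answer: Literal["positive", "negative", "unanswered"]
    source: Literal["provided", "inferred"] = "provided"


@dataclass(frozen=True)
class AceScore:
    """Count of positive ACE items and the stratum label it falls in."""

    score: int
    stratum: str


@dataclass
class OutcomeHypothesis:
    """A negative outcome worth screening for, with its evidence trail."""

    outcome: str
    supporting_symptoms: list[str]
    evidence: list[str] = field(default_factory=list)  # provenance source ids
    citations: list[str] = field(default_factory=list)


def resolve_param_concept(ont: Ontology, entity_type: str, value: str) -> Optional[str]:
    """Map a tagged (entity type, value) pair to the most specific concept.

    Canonical lexicon values that are themselves concept ids (e.g.
    lead_based_paint under housing_circumstance) win over the entity type.
    """
    if value in ont:
        return value
    if entity_type in ont:
        return entity_type
    return None


def detect_sdoh(
    ont: Ontology,
    params: Mapping[str, tuple[str, str]],
    provider=None,
) -> list[SdohFinding]:
    """One finding per SDoH-classified parameter, causal closure attached.

    ``params`` maps parameter names to ``(value, entity_type)``. When a zip
    code parameter is present and a neighborhood provider is supplied, its
    metrics are attached to every finding; a zip the provider does not know
    yields findings flagged ``metrics_missing``.
    """
    zip_value = None
    for _name, (value, etype) in params.items():
        if etype == "zip_code":
            zip_value = value
    metrics = None
    missing = False
    if zip_value is not None and provider is not None:
        metrics = provider.metrics_for(zip_value)
        missing = metrics is None

    findings: list[SdohFinding] = []
    seen: set[str] = set()
    for _name, (value, etype) in params.items():
        concept = resolve_param_concept(ont, etype, value)
        if concept is None or concept in seen:
            continue
        if ont.classify_risk_factor(concept) != "SDoH":
            continue
        seen.add(concept)
        findings.append(
            SdohFinding(
                concept=concept,
                value=value,
                causal_consequences=ont.causal_closure(concept),
                neighborhood_metrics=metrics,
                metrics_missing=missing,
            )
        )
    return findings


def select_ace_questions(
    ont: Ontology, concepts: Sequence[str]
) -> list[AceQuestion]:
    """Questions whose probed concept relates to a supplied concept.

    A question qualifies when its concept is the supplied concept, an
    ancestor of it, or a descendant of it. Pool order is preserved, so the
    selection is deterministic.
    """
    usable = [c for c in concepts if c in ont]
    out = []
    for q in ont.ace_questions:
        if any(ont.is_subtype(q.concept, c) or ont.is_subtype(c, q.concept) for c in usable):
            out.append(q)
    return out


def compute_ace_score(
    answers: Iterable[AceAnswer],
    score_rules: Optional[Sequence[tuple[int, str]]] = None,
    ont: Optional[Ontology] = None,
) -> AceScore:
    """Count positive answers (provided and inferred alike) and stratify."""
    answers = list(answers)
    qids = [a.question_id for a in answers]
    if len(qids) != len(set(qids)):
        dupes = sorted({q for q in qids if qids.count(q) > 1})
        raise ValueError(f"duplicate answers for questions: {dupes}")
    if score_rules is None:
        if ont is None:
            raise ValueError("need score_rules or an ontology carrying them")
        score_rules = ont.score_rules
    score = sum(1 for a in answers if a.answer == "positive")
    stratum = ""
    for lower, label in sorted(score_rules):
        if score >= lower:
            stratum = label
    return AceScore(score=score, stratum=stratum)


def load_evidence(path: str | Path) -> pd.DataFrame:
    """Load the external-knowledge evidence table.

    Rows map (score stratum, symptom concept) to an outcome concept with a
    provenance source id and citation, standing in for live literature
    lookup.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"evidence table missing columns: {missing}")
    return df


def hypothesize_outcomes(
    score: AceScore,
    symptoms: Sequence[str],
    ont: Ontology,
    evidence: Optional[pd.DataFrame] = None,
) -> list[OutcomeHypothesis]:
    """Outcomes to screen for, given a score stratum and observed symptoms.

    Two evidence routes are merged per symptom: outcome-categorized
    concepts in the symptom's causal closure (ontology axioms), and
    evidence-table rows keyed by (stratum, symptom). Hypotheses for the
    same outcome are merged; every hypothesis carries non-empty evidence.
    """
    by_outcome: dict[str, OutcomeHypothesis] = {}
    order: list[str] = []

    def add(outcome: str, symptom: str, sources: Sequence[str], citations: Sequence[str]):
        hyp = by_outcome.get(outcome)
        if hyp is None:
            hyp = OutcomeHypothesis(outcome=outcome, supporting_symptoms=[])
            by_outcome[outcome] = hyp
            order.append(outcome)
        if symptom not in hyp.supporting_symptoms:
            hyp.supporting_symptoms.append(symptom)
        for s in sources:
            if s not in hyp.evidence:
                hyp.evidence.append(s)
        for c in citations:
            if c and c not in hyp.citations:
                hyp.citations.append(c)

    for symptom in symptoms:
        if symptom not in ont:
            continue
        for cons in ont.causal_closure(symptom):
            if ont.concept(cons.concept).category is Category.OUTCOME:
                add(cons.concept, symptom, cons.provenance, [])
        if evidence is not None:
            rows = evidence[
                (evidence["stratum"] == score.stratum)
                & (evidence["symptom"] == symptom)
            ]
            for _, row in rows.iterrows():
                add(row["outcome"], symptom, [row["source"]], [row["citation"]])
    return [by_outcome[o] for o in order]


class NeighborhoodProvider:
    """Neighborhood-metrics lookup keyed by zip code.

    Emulates a population-health observatory endpoint from a plain table
    (columns: ``zip`` plus one column per metric, values in [0, 100] for
    percentage metrics).
    """

    def __init__(self, table: pd.DataFrame):
        if "zip" not in table.columns:
            raise ValueError("neighborhood table needs a 'zip' column")
        self._by_zip = {
            str(row["zip"]): {
                k: float(v) for k, v in row.items() if k != "zip"
            }
            for _, row in table.iterrows()
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "NeighborhoodProvider":
        return cls(pd.read_csv(path, dtype={"zip": str}))

    def metrics_for(self, zip_code: str) -> Optional[dict[str, float]]:
        return self._by_zip.get(str(zip_code))

    def max_metrics(self, zip_code: str) -> list[str]:
        """Metric names attaining the strict positive maximum (ties kept)."""
        metrics = self.metrics_for(zip_code)
        if not metrics:
            return []
        top = max(metrics.values())
        if top <= 0:
            return []
        return sorted(name for name, v in metrics.items() if v == top)
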