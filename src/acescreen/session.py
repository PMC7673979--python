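"""Chat-session orchestration: one intake conversation, end to end.

A :class:`ChatSession` wires the dialog engine to its fulfillment services
(SDoH surveillance, ACE surveillance / questionnaire, recommendation) and
grows the personalized knowledge graph turn by turn. Finalizing a session
produces the surveillance alert (ACE score, stratum, symptoms, outcome
hypotheses), the ordered intervention list, ranked resource suggestions,
and a provenance-labelled explanation for the leading recommendation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import pandas as pd

from . import dialog
from .dialog import (
    ConversationState,
    FakeClock,
    FulfillmentRequest,
    FulfillmentResponse,
    IntentRegistry,
    Turn,
    order_issues,
    process_turn,
)
from .graph import (
    PersonalGraph,
    Resource,
    apply_axioms,
    attach_neighborhood,
    explain_recommendation,
    ingest_parameters,
    suggest_questions,
    suggest_resources,
)
from .ontology import Category, Ontology
from .surveillance import (
    AceAnswer,
    NeighborhoodProvider,
    OutcomeHypothesis,
    SdohFinding,
    compute_ace_score,
    detect_sdoh,
    hypothesize_outcomes,
    resolve_param_concept,
)

#: Issue-concept -> (intervention wording, resource kind, resource specialty).
INTERVENTION_RULES: dict[str, tuple[str, str, str]] = {
    "food_insecurity": ("food pantry information", "food_pantry", "food_insecurity"),
    "education_issue": ("school information", "school", "education_issue"),
    "legal_issue": ("legal follow-up", "legal_aid", "legal_issue"),
    "employment_issue": ("job search assistance", "employment_center", "employment_issue"),
    "housing_circumstance": ("housing assistance referral", "housing_agency", "housing_circumstance"),
}
#: Symptom concepts that call for a psychologist appointment.
SYMPTOM_INTERVENTION: dict[str, str] = {
    "behavioral_issue": "schedule psychologist appointment",
    "developmental_delay": "schedule psychologist appointment",
}
MEDICAL_INTERVENTION = "schedule medical appointment"
#: Documented simplification: default language preference by ethnicity when
#: the user states none. See the methods note for the equity caveat.
ETHNICITY_LANGUAGE: dict[str, str] = {"hispanic": "spanish"}

_YES = {"yes", "y", "yeah", "yep", "true", "positive"}
_NO = {"no", "n", "nope", "false", "negative"}


@dataclass
class AcesAlert:
    """The practitioner-facing ACE surveillance alert."""

    score: int
    stratum: str
    symptoms: list[str]
    provided_aces: list[str]
    inferred_aces: list[str]
    hypotheses: list[OutcomeHypothesis]


@dataclass
class SessionResult:
    session_id: str
    transcript: list[tuple[str, str]]
    graph: PersonalGraph
    detections: dict
    alert: Optional[AcesAlert]
    sdoh_findings: list[SdohFinding]
    resources: list
    explanation: Optional[object]
    profile: dict
    log_records: list[dict]
    summary: str


class ChatSession:
    """One scripted or interactive intake conversation."""

    def __init__(
        self,
        ont: Ontology,
        registry: IntentRegistry,
        provider: Optional[NeighborhoodProvider] = None,
        directory: Sequence[Resource] = (),
        centroids: Optional[dict] = None,
        evidence: Optional[pd.DataFrame] = None,
        session_id: str = "session-1",
        clock: Optional[Callable[[], float]] = None,
        radius_miles: float = 10.0,
        language: Optional[str] = None,
    ):
        self.ont = ont
        self.registry = registry
        self.provider = provider
        self.directory = list(directory)
        self.centroids = centroids or {}
        self.evidence = evidence
        self.clock = clock or FakeClock()
        self.radius_miles = radius_miles
        self.language_override = language

        self.state = ConversationState(session_id=session_id)
        self.graph = PersonalGraph(session_id)
        self.services = {
            "recommendation": self._svc_recommendation,
            "sdoh_surveillance": self._svc_sdoh,
            "aces_surveillance": self._svc_aces,
            "appointment": self._svc_appointment,
        }
        self.transcript: list[tuple[str, str]] = []
        self.issue_queue: list[str] = []
        self.symptoms: list[str] = []
        self.provided_concepts: list[str] = []
        self.answers: dict[str, AceAnswer] = {}
        self.inferred_aces: list[str] = []
        self.neighborhood_risks: list[str] = []
        self.pending_questions: list = []
        self.current_question = None
        self.sdoh_findings: list[SdohFinding] = []
        self.appointments: list[dict] = []
        self.result: Optional[SessionResult] = None
        self._finalized = False

    # -- public API --------------------------------------------------------

    def post(self, utterance: str) -> str:
        """Process one user utterance and return the agent's reply."""
        self.transcript.append(("user", utterance))
        self._track_mentions(utterance)
        if self.current_question is not None:
            reply = self._answer_question(utterance)
        else:
            resp = process_turn(
                self.state, self.registry, self.services, utterance,
                self.ont, clock=self.clock,
            )
            reply = resp.text
        self.transcript.append(("agent", reply))
        return reply

    def run_script(self, turns: Sequence[str]) -> SessionResult:
        """Replay a scripted conversation and finalize the session."""
        for turn in turns:
            self.post(turn)
        return self.finalize()

    # -- mention tracking --------------------------------------------------

    def _track_mentions(self, utterance: str) -> None:
        matches = self.ont.tag_entities(utterance)
        issues: list[tuple[str, int]] = []
        for m in matches:
            concept = resolve_param_concept(self.ont, m.entity_type, m.value)
            if concept is None:
                continue
            if concept not in self.provided_concepts:
                self.provided_concepts.append(concept)
            cat = self.ont.concept(concept).category
            if cat is Category.SYMPTOM and concept not in self.symptoms:
                self.symptoms.append(concept)
            try:
                cls = self.ont.classify_risk_factor(concept)
            except Exception:
                continue
            if cls in ("ACE", "SDoH"):
                issues.append((concept, m.span[0]))
        for concept in order_issues(issues, utterance):
            if concept not in self.issue_queue:
                self.issue_queue.append(concept)

    # -- fulfillment services ----------------------------------------------

    def _svc_recommendation(self, req: FulfillmentRequest) -> FulfillmentResponse:
        pairs = [(etype, value) for _n, (value, etype) in req.params.items()]
        ingest_parameters(self.graph, self.ont, pairs)
        new_edges = apply_axioms(self.graph, self.ont)
        self._record_ace_answers(new_edges)
        zip_value = self.graph.value_of("zip_code")
        if zip_value and self.provider is not None:
            attach_neighborhood(self.graph, self.ont, self.provider, zip_value)
            for metric in self.provider.max_metrics(zip_value):
                if metric in self.ont and self.ont.causal_closure(metric):
                    if metric not in self.neighborhood_risks:
                        self.neighborhood_risks.append(metric)
        self.sdoh_findings = detect_sdoh(self.ont, req.params, self.provider)
        questions = suggest_questions(
            self.graph, self.ont, answered=set(self.answers)
        )
        if questions:
            self.pending_questions = questions[1:]
            self.current_question = questions[0]
            return FulfillmentResponse(
                text=questions[0].text,
                payload={"question": questions[0].id},
            )
        result = self.finalize()
        return FulfillmentResponse(text=result.summary)

    def _svc_sdoh(self, req: FulfillmentRequest) -> FulfillmentResponse:
        findings = detect_sdoh(self.ont, req.params, self.provider)
        self.sdoh_findings = findings or self.sdoh_findings
        text = (
            "I hear you on " + ", ".join(f.concept.replace("_", " ") for f in findings)
            if findings else "Thank you for sharing."
        )
        return FulfillmentResponse(text=text)

    def _svc_aces(self, req: FulfillmentRequest) -> FulfillmentResponse:
        return FulfillmentResponse(text="Let me ask a few follow-up questions.")

    def _svc_appointment(self, req: FulfillmentRequest) -> FulfillmentResponse:
        record = {name: value for name, (value, _t) in req.params.items()
                  if name in {"date", "duration", "time", "appointment_type"}}
        self.appointments.append(record)
        return FulfillmentResponse(
            text="Your appointment request has been recorded.",
            payload={"appointment": record},
        )

    # -- questionnaire -----------------------------------------------------

    def _record_ace_answers(self, new_edges) -> None:
        by_concept = {q.concept: q for q in self.ont.ace_questions}
        for concept in self.provided_concepts:
            q = by_concept.get(concept)
            if q and q.id not in self.answers:
                self.answers[q.id] = AceAnswer(q.id, "positive", "provided")
                self.graph.answered_questions.add(q.id)
        for subject, _obj, _rel in new_edges:
            try:
                if self.ont.classify_risk_factor(subject) != "ACE":
                    continue
            except Exception:
                continue
            if subject not in self.inferred_aces and subject not in self.provided_concepts:
                self.inferred_aces.append(subject)
            q = by_concept.get(subject)
            if q and q.id not in self.answers:
                self.answers[q.id] = AceAnswer(q.id, "positive", "inferred")
                self.graph.answered_questions.add(q.id)

    def _answer_question(self, utterance: str) -> str:
        q = self.current_question
        token = utterance.strip().lower().rstrip(".!")
        if token in _YES:
            answer = "positive"
        elif token in _NO:
            answer = "negative"
        else:
            answer = "unanswered"
        self.answers[q.id] = AceAnswer(q.id, answer, "provided")
        self.graph.answered_questions.add(q.id)
        if answer == "positive":
            # a positive answer refines the graph like any provided concept
            cnode = self.graph.ensure_concept(self.ont, q.concept)
            self.graph.add_edge_once(
                self.graph.user_node, cnode, "has_concept",
                source_of_inference=self._question_source(), confidence=1.0,
            )
        t0 = self.clock()
        if self.pending_questions:
            self.current_question = self.pending_questions.pop(0)
            reply = self.current_question.text
        else:
            self.current_question = None
            reply = self.finalize().summary
        t1 = self.clock()
        self.state.history.append(
            Turn(timestamp=t0, utterance=utterance, intent="ACEs_Surveillance",
                 response=reply, latency=t1 - t0)
        )
        if self.result is not None:
            # finalize ran inside this turn; refresh its captured log
            self.result.log_records = self.log_records(self.result.profile)
        return reply

    def _question_source(self) -> str:
        try:
            return self.ont.default_source("questionnaire")
        except KeyError:
            return self.ont.default_source("ontology")

    # -- finalization ------------------------------------------------------

    def _language(self) -> Optional[str]:
        if self.language_override:
            return self.language_override
        lang = self.graph.value_of("preferred_language")
        if lang:
            return lang
        ethnicity = self.graph.value_of("ethnicity")
        if ethnicity:
            return ETHNICITY_LANGUAGE.get(ethnicity.lower())
        return None

    def _profile(self) -> dict:
        age_group = "unknown"
        age_value = self.graph.value_of("age")
        if age_value is not None:
            try:
                a = int(age_value)
                if a < 18:
                    age_group = "minor"
                elif a <= 25:
                    age_group = "18-25"
                elif a <= 40:
                    age_group = "26-40"
                elif a <= 65:
                    age_group = "41-65"
                else:
                    age_group = "65+"
            except ValueError:
                pass
        eth = self.graph.value_of("ethnicity") or "unknown"
        return {
            "age_group": age_group,
            "ethnicity_group": eth,
            "zip": self.graph.value_of("zip_code") or "",
        }

    def _inferred_outcomes(self, provided_outcomes: list[str]) -> list[str]:
        out = []
        for cid in self.graph.concept_ids():
            if self.ont.concept(cid).category is not Category.OUTCOME:
                continue
            if cid in provided_outcomes:
                continue
            node = self.graph.concept_node(cid)
            has_causal_in = any(
                d.get("relation") == "causal"
                for _u, _v, d in self.graph.g.in_edges(node, data=True)
            )
            if has_causal_in:
                out.append(cid)
        return sorted(out)

    def finalize(self) -> SessionResult:
        """Compute the alert, interventions, resources and explanation."""
        if self._finalized:
            return self.result
        self._finalized = True

        apply_axioms(self.graph, self.ont)
        score = compute_ace_score(self.answers.values(), self.ont.score_rules)
        hyps = hypothesize_outcomes(score, self.symptoms, self.ont, self.evidence)
        provided_outcomes = [
            c for c in self.provided_concepts
            if self.ont.concept(c).category is Category.OUTCOME
        ]
        inferred_outcomes = self._inferred_outcomes(provided_outcomes)
        for h in hyps:
            if h.outcome not in provided_outcomes and h.outcome not in inferred_outcomes:
                inferred_outcomes.append(h.outcome)

        provided_aces = [
            c for c in self.issue_queue
            if self.ont.classify_risk_factor(c) == "ACE"
        ]
        language = self._language()

        interventions: list[str] = []
        resources: list = []
        explanation = None

        def add_resources(specialty: str, trigger: str):
            nonlocal explanation
            result = suggest_resources(
                self.graph, self.ont, self.directory, self.centroids,
                specialty=specialty, language=language,
                radius_miles=self.radius_miles, trigger_concept=trigger,
            )
            for s in result.suggestions[:1]:
                resources.append(s)
                if explanation is None:
                    try:
                        explanation = explain_recommendation(self.graph, self.ont, s.node)
                    except Exception:
                        explanation = None

        # medical escalation first: high-risk stratum with an inferred outcome
        medical = score.stratum == "high risk" and bool(inferred_outcomes)
        if medical:
            interventions.append(MEDICAL_INTERVENTION)
        for issue in self.issue_queue:
            rule = INTERVENTION_RULES.get(issue)
            if rule is None:
                continue
            text, _kind, specialty = rule
            if text not in interventions:
                interventions.append(text)
            add_resources(specialty, issue)
        for symptom in self.symptoms:
            text = SYMPTOM_INTERVENTION.get(symptom)
            if text and text not in interventions:
                interventions.append(text)
        if medical:
            for outcome in inferred_outcomes:
                add_resources(outcome, outcome)

        alert = AcesAlert(
            score=score.score,
            stratum=score.stratum,
            symptoms=list(self.symptoms),
            provided_aces=provided_aces,
            inferred_aces=list(self.inferred_aces),
            hypotheses=hyps,
        )
        detections = {
            "symptoms": list(self.symptoms),
            "risk_factors": {
                "provided": list(self.issue_queue),
                "inferred": list(self.inferred_aces),
                "neighborhood": list(self.neighborhood_risks),
            },
            "outcomes": {
                "provided": provided_outcomes,
                "inferred": inferred_outcomes,
            },
            "interventions": interventions,
        }
        profile = self._profile()
        summary = self._render_summary(alert, detections, resources, explanation)
        self.result = SessionResult(
            session_id=self.state.session_id,
            transcript=self.transcript,
            graph=self.graph,
            detections=detections,
            alert=alert,
            sdoh_findings=self.sdoh_findings,
            resources=resources,
            explanation=explanation,
            profile=profile,
            log_records=self.log_records(profile),
            summary=summary,
        )
        return self.result

    def _render_summary(self, alert, detections, resources, explanation) -> str:
        lines = [
            f"ACEs alert: score {alert.score} ({alert.stratum})",
        ]
        if alert.symptoms:
            lines.append("Symptoms: " + ", ".join(s.replace("_", " ") for s in alert.symptoms))
        if alert.provided_aces or alert.inferred_aces:
            parts = [f"provided ({c.replace('_', ' ')})" for c in alert.provided_aces]
            parts += [f"inferred ({c.replace('_', ' ')})" for c in alert.inferred_aces]
            lines.append("ACEs detected: " + "; ".join(parts))
        for h in alert.hypotheses:
            lines.append(
                f"Screen early for {h.outcome.replace('_', ' ')} "
                f"(evidence: {', '.join(h.evidence)})"
            )
        if detections["interventions"]:
            lines.append("Interventions: " + "; ".join(detections["interventions"]))
        for s in resources:
            dist = f" ({s.distance_miles:.1f} mi)" if s.distance_miles is not None else ""
            lines.append(f"Suggested resource: {s.resource.name}{dist}")
        if explanation is not None:
            lines.append("Why this recommendation:")
            lines.append(explanation.text)
        return "\n".join(lines)

    def log_records(self, profile: Optional[dict] = None) -> list[dict]:
        profile = profile or self._profile()
        records = []
        for turn in self.state.history:
            records.append(
                {
                    "session_id": self.state.session_id,
                    "age_group": profile["age_group"],
                    "ethnicity_group": profile["ethnicity_group"],
                    "zip": profile["zip"],
                    "ts": turn.timestamp,
                    "utterance": turn.utterance,
                    "intent": turn.intent,
                    "response": turn.response,
                    "latency": round(turn.latency, 4),
                    "mismatch": turn.mismatch,
                }
            )
        return records
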