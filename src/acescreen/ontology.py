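"""Ontology model for ACEs/SDoH intake screening.

The ontology bundles everything the screening assistant needs to know about
the domain: a concept hierarchy (adverse childhood experiences, social
determinants of health, symptoms, health outcomes, demographics), causal
axioms with provenance ("blight causes exposure to toxicants", "exposure to
toxicants leads to asthma"), an entity lexicon mapping surface phrases to
concepts, the ACE questionnaire pool, and the score-stratification rules.

It is serialized as a versioned JSON document (see :data:`SCHEMA_VERSION`);
:func:`load_ontology` / :meth:`Ontology.to_json` round-trip it losslessly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Literal, Optional

import networkx as nx
from pydantic import BaseModel, Field, PrivateAttr, model_validator

SCHEMA_VERSION = "1.0"


class OntologyError(Exception):
    """Base class for ontology-related failures."""


class UnknownConceptError(OntologyError, KeyError):
    """A concept id does not resolve in the ontology."""


class OntologyValidationError(OntologyError):
    """The ontology document violates a structural invariant."""


class OntologyInconsistencyError(OntologyError):
    """A concept is classified under mutually exclusive roots."""


class Category(str, Enum):
    ACE = "ACE"
    SDOH = "SDoH"
    SYMPTOM = "symptom"
    OUTCOME = "outcome"
    DEMOGRAPHIC = "demographic"
    RESOURCE_KIND = "resource_kind"
    OTHER = "other"


class Relation(str, Enum):
    IS_A = "is_a"
    EQUIVALENT_TO = "equivalent_to"
    CAUSES = "causes"
    LEADS_TO = "leads_to"
    RISK_FACTOR_OF = "risk_factor_of"


#: causes / leads_to / risk_factor_of are interchangeable for closure
#: purposes; each keeps its label for explanation text.
CAUSAL_RELATIONS = frozenset(
    {Relation.CAUSES, Relation.LEADS_TO, Relation.RISK_FACTOR_OF}
)

SourceKind = Literal["ontology", "literature", "neighborhood_repository", "questionnaire"]

#: Default confidence attached to edges inferred from each knowledge source.
DEFAULT_CONFIDENCE: dict[str, float] = {
    "ontology": 1.0,
    "literature": 0.8,
    "neighborhood_repository": 0.9,
    "questionnaire": 1.0,
}


class Concept(BaseModel):
    id: str
    label: str
    category: Category


class ProvenanceSource(BaseModel):
    id: str
    kind: SourceKind
    citation: str = ""


class Axiom(BaseModel):
    """A single assertion ``subject relation object`` with provenance."""

    subject: str
    relation: Relation
    object: str
    provenance: str

    def render(self) -> str:
        return f"{self.subject} {self.relation.value} {self.object}"


class EntityPattern(BaseModel):
    """Regex-based entity tagger for open-valued types (zip codes, ages)."""

    entity_type: str
    regex: str
    value_group: int = 0


class AceQuestion(BaseModel):
    id: str
    text: str
    concept: str
    mandatory: bool = True


@dataclass(frozen=True)
class EntityMatch:
    """One tagged mention: entity type, canonical value, span in raw text."""

    entity_type: str
    value: str
    span: tuple[int, int]
    surface: str


@dataclass(frozen=True)
class CausalConsequence:
    """A concept causally reachable from a start concept.

    ``chain`` is the witnessing axiom sequence (is_a hops included so the
    explanation reads naturally, e.g. lead-based paint *is a* toxicant and
    toxicants are a *risk factor of* asthma); ``provenance`` collects the
    chain's source ids in order.
    """

    concept: str
    chain: tuple[Axiom, ...]
    provenance: tuple[str, ...]


def _normalize_phrase(phrase: str) -> str:
    return re.sub(r"\s+", " ", phrase.strip().lower())


class Ontology(BaseModel):
    schema_version: str = SCHEMA_VERSION
    name: str = ""
    ace_root: str = "ace"
    sdoh_root: str = "sdoh"
    sources: list[ProvenanceSource] = Field(default_factory=list)
    concepts: list[Concept] = Field(default_factory=list)
    axioms: list[Axiom] = Field(default_factory=list)
    lexicon: dict[str, tuple[str, str]] = Field(default_factory=dict)
    patterns: list[EntityPattern] = Field(default_factory=list)
    ace_questions: list[AceQuestion] = Field(default_factory=list)
    score_rules: list[tuple[int, str]] = Field(
        default_factory=lambda: [(0, "no reported ACEs"), (1, "moderate"), (4, "high risk")]
    )

    _by_id: dict[str, Concept] = PrivateAttr(default_factory=dict)
    _isa: nx.DiGraph = PrivateAttr(default=None)
    _causal: nx.MultiDiGraph = PrivateAttr(default=None)
    _matcher: Optional[re.Pattern] = PrivateAttr(default=None)
    _compiled_patterns: list[tuple[EntityPattern, re.Pattern]] = PrivateAttr(default_factory=list)

    # ------------------------------------------------------------------ #
    # validation and indexing

    @model_validator(mode="after")
    def _validate(self) -> "Ontology":
        ids = [c.id for c in self.concepts]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate concept ids: {sorted(dupes)}")
        known = set(ids)
        src_ids = [s.id for s in self.sources]
        if len(src_ids) != len(set(src_ids)):
            raise ValueError("duplicate provenance source ids")
        known_sources = set(src_ids)
        for ax in self.axioms:
            for end, field in ((ax.subject, "subject"), (ax.object, "object")):
                if end not in known:
                    raise ValueError(f"axiom {ax.render()!r}: {field} {end!r} is not a concept")
            if ax.relation in CAUSAL_RELATIONS and ax.subject == ax.object:
                raise ValueError(f"causal axiom with identical endpoints: {ax.render()!r}")
            if ax.provenance not in known_sources:
                raise ValueError(f"axiom {ax.render()!r}: unknown provenance {ax.provenance!r}")
        for phrase, (etype, _value) in self.lexicon.items():
            if not phrase.strip():
                raise ValueError("lexicon: empty phrase")
            if phrase != _normalize_phrase(phrase):
                raise ValueError(f"lexicon phrase not normalized: {phrase!r}")
            if etype not in known:
                raise ValueError(f"lexicon phrase {phrase!r}: unknown entity type {etype!r}")
        for pat in self.patterns:
            if pat.entity_type not in known:
                raise ValueError(f"pattern: unknown entity type {pat.entity_type!r}")
            re.compile(pat.regex)
        by_id = {c.id: c for c in self.concepts}
        for q in self.ace_questions:
            if q.concept not in known:
                raise ValueError(f"question {q.id!r}: unknown concept {q.concept!r}")
            if by_id[q.concept].category is not Category.ACE:
                raise ValueError(f"question {q.id!r}: concept {q.concept!r} is not ACE-categorized")
        qids = [q.id for q in self.ace_questions]
        if len(qids) != len(set(qids)):
            raise ValueError("duplicate ACE question ids")
        bounds = [b for b, _ in self.score_rules]
        if bounds != sorted(set(bounds)) or (bounds and bounds[0] != 0):
            raise ValueError(
                "score_rules lower bounds must be strictly increasing and start at 0 "
                "so every non-negative score falls in exactly one stratum"
            )
        # is_a edges (declared, not equivalence-derived) must form a DAG
        declared = nx.DiGraph()
        declared.add_nodes_from(known)
        for ax in self.axioms:
            if ax.relation is Relation.IS_A:
                declared.add_edge(ax.subject, ax.object)
        try:
            cycle = nx.find_cycle(declared)
        except nx.NetworkXNoCycle:
            pass
        else:
            path = " -> ".join(u for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise ValueError(f"is_a hierarchy contains a cycle: {path}")
        self._reindex()
        return self

    def model_post_init(self, __context) -> None:  # noqa: D105
        self._reindex()

    def _reindex(self) -> None:
        self._by_id = {c.id: c for c in self.concepts}
        isa = nx.DiGraph()
        isa.add_nodes_from(self._by_id)
        causal = nx.MultiDiGraph()
        causal.add_nodes_from(self._by_id)
        for ax in self.axioms:
            if ax.relation is Relation.IS_A:
                isa.add_edge(ax.subject, ax.object, axiom=ax)
            elif ax.relation is Relation.EQUIVALENT_TO:
                # equivalence behaves as mutual subsumption
                isa.add_edge(ax.subject, ax.object, axiom=ax)
                isa.add_edge(ax.object, ax.subject, axiom=ax)
            else:
                causal.add_edge(ax.subject, ax.object, axiom=ax)
        self._isa = isa
        self._causal = causal
        self._matcher = self._build_matcher()
        compiled = []
        for p in self.patterns:
            try:
                compiled.append((p, re.compile(p.regex, re.IGNORECASE)))
            except re.error:  # reported by schema validation instead
                pass
        self._compiled_patterns = compiled

    def _build_matcher(self) -> Optional[re.Pattern]:
        if not self.lexicon:
            return None
        phrases = sorted(self.lexicon, key=lambda p: (-len(p), p))
        alts = "|".join(re.escape(p).replace(r"\ ", r"\s+") for p in phrases)
        return re.compile(
            rf"(?<![A-Za-z0-9])(?:{alts})(?![A-Za-z0-9])", re.IGNORECASE
        )

    def __eq__(self, other: object) -> bool:
        # content equality; the private index structures compare by identity
        if not isinstance(other, Ontology):
            return NotImplemented
        return self.model_dump(mode="json") == other.model_dump(mode="json")

    __hash__ = None

    # ------------------------------------------------------------------ #
    # basic lookup

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._by_id

    def concept(self, concept_id: str) -> Concept:
        try:
            return self._by_id[concept_id]
        except KeyError:
            raise UnknownConceptError(concept_id) from None

    def parents(self, concept_id: str) -> list[str]:
        self.concept(concept_id)
        return sorted(self._isa.successors(concept_id))

    def source(self, source_id: str) -> ProvenanceSource:
        for s in self.sources:
            if s.id == source_id:
                return s
        raise KeyError(source_id)

    def default_source(self, kind: str = "ontology") -> str:
        """Id of the first provenance source of the given kind."""
        for s in self.sources:
            if s.kind == kind:
                return s.id
        raise KeyError(f"no provenance source of kind {kind!r}")

    def confidence_for(self, source_id: str) -> float:
        return DEFAULT_CONFIDENCE.get(self.source(source_id).kind, 1.0)

    # ------------------------------------------------------------------ #
    # subsumption

    def is_subtype(self, a: str, b: str) -> bool:
        """True iff ``b`` is reachable from ``a`` via is_a edges (reflexive)."""
        self.concept(a)
        self.concept(b)
        return a == b or nx.has_path(self._isa, a, b)

    def ancestors(self, concept_id: str) -> set[str]:
        """All supertypes of ``concept_id`` including itself."""
        self.concept(concept_id)
        return {concept_id} | nx.descendants(self._isa, concept_id)

    def classify_risk_factor(self, concept_id: str) -> str:
        """Classify a concept as ``"ACE"``, ``"SDoH"`` or ``"none"``.

        Raises :class:`OntologyInconsistencyError` if the concept sits under
        both roots, which would make a finding ambiguous.
        """
        is_ace = self.ace_root in self and self.is_subtype(concept_id, self.ace_root)
        is_sdoh = self.sdoh_root in self and self.is_subtype(concept_id, self.sdoh_root)
        if is_ace and is_sdoh:
            raise OntologyInconsistencyError(
                f"{concept_id!r} subsumed by both {self.ace_root!r} and {self.sdoh_root!r}"
            )
        if is_ace:
            return "ACE"
        if is_sdoh:
            return "SDoH"
        return "none"

    # ------------------------------------------------------------------ #
    # causal closure

    def causal_closure(self, start: str) -> list[CausalConsequence]:
        """All concepts causally reachable from ``start``, with witnesses.

        A step is either a causal axiom fired from the current concept or an
        upward is_a hop (a subtype is subject to its supertypes' causal
        axioms). Only concepts entered through a causal axiom are reported;
        pure supertypes are traversal scaffolding. Breadth-first order,
        lexicographic within a frontier, one (shortest) witness chain each.
        """
        self.concept(start)
        seen: set[str] = {start}
        reported: dict[str, CausalConsequence] = {}
        frontier: list[tuple[str, tuple[Axiom, ...]]] = [(start, ())]
        order: list[str] = []
        while frontier:
            next_frontier: list[tuple[str, tuple[Axiom, ...]]] = []
            for node, chain in sorted(frontier, key=lambda t: t[0]):
                steps: list[tuple[str, Axiom, bool]] = []
                for _u, v, data in sorted(
                    self._causal.out_edges(node, data=True), key=lambda e: e[1]
                ):
                    steps.append((v, data["axiom"], True))
                for v in sorted(self._isa.successors(node)):
                    steps.append((v, self._isa[node][v]["axiom"], False))
                for target, axiom, causal_step in steps:
                    new_chain = chain + (axiom,)
                    if causal_step and target != start and target not in reported:
                        reported[target] = CausalConsequence(
                            concept=target,
                            chain=new_chain,
                            provenance=tuple(ax.provenance for ax in new_chain),
                        )
                        order.append(target)
                    if target not in seen:
                        seen.add(target)
                        next_frontier.append((target, new_chain))
            frontier = next_frontier
        return [reported[c] for c in order]

    # ------------------------------------------------------------------ #
    # entity tagging

    def tag_entities(self, text: str) -> list[EntityMatch]:
        """Case-insensitive maximal-munch scan of the lexicon over ``text``.

        Lexicon phrases and regex patterns compete for spans; at each
        position the longest candidate wins and matches never overlap.
        Spans index into the original text.
        """
        candidates: list[tuple[int, int, str, str]] = []
        if self._matcher is not None:
            for m in self._matcher.finditer(text):
                key = _normalize_phrase(m.group(0))
                if key not in self.lexicon:
                    # hyphen/space variation: retry with hyphens as spaces
                    key = _normalize_phrase(key.replace("-", " "))
                entry = self.lexicon.get(key)
                if entry is None:
                    continue
                etype, value = entry
                candidates.append((m.start(), m.end(), etype, value))
        for spec, pat in self._compiled_patterns:
            for m in pat.finditer(text):
                candidates.append((m.start(), m.end(), spec.entity_type, m.group(spec.value_group)))
        candidates.sort(key=lambda c: (c[0], -(c[1] - c[0]), c[2]))
        out: list[EntityMatch] = []
        cursor = -1
        for start, end, etype, value in candidates:
            if start <= cursor:
                continue
            out.append(EntityMatch(etype, value, (start, end), text[start:end]))
            cursor = end - 1
        return out

    # ------------------------------------------------------------------ #
    # serialization

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def load_ontology(path: str | Path) -> Ontology:
    """Load and validate an ontology JSON document.

    Raises :class:`OntologyValidationError` (naming the offending field or
    listing the is_a cycle) when the document is malformed.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise OntologyValidationError(f"{path}: not valid JSON: {exc}") from exc
    return ontology_from_dict(raw, origin=str(path))


def ontology_from_dict(raw: dict, origin: str = "<dict>") -> Ontology:
    import pydantic

    try:
        return Ontology.model_validate(raw)
    except pydantic.ValidationError as exc:
        raise OntologyValidationError(f"{origin}: {exc}") from exc
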