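"""Personalized knowledge graph: population, inference, recommendation.

Each screening session grows a typed property graph rooted at a single
user node. Contextual parameters from the conversation become concept and
value nodes; bounded forward chaining over the ontology's causal axioms
adds inferred nodes and edges, every one labelled with its source of
inference and a confidence; neighborhood metrics attach under the user's
zip code; and question/resource recommendations are added as nodes whose
justification can be replayed as an explicit inference path (and its
type-level metapath) from the user node to the recommendation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .ontology import Axiom, Category, Ontology, Relation
from .surveillance import NeighborhoodProvider, select_ace_questions

EARTH_RADIUS_MILES = 3958.8
DEFAULT_RADIUS_MILES = 10.0
#: Child ages treated as school-age when linking the age parameter upward.
SCHOOL_AGE_RANGE = range(5, 13)

GRAPH_SCHEMA = "acescreen-graph/1"


class GraphIntegrityError(Exception):
    """A recommendation cannot be justified from the user node."""


def haversine_miles(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two (lat, lon) points, in miles."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_MILES * math.asin(math.sqrt(a))


@dataclass(frozen=True)
class Resource:
    """A community resource (clinic, food pantry, school, legal aid...)."""

    id: str
    kind: str
    name: str
    zip: str
    lat: float
    lon: float
    languages: tuple[str, ...]
    specialty: str

    def __post_init__(self):
        if not (-90 <= self.lat <= 90 and -180 <= self.lon <= 180):
            raise ValueError(f"resource {self.id}: invalid coordinates")
        if not self.languages:
            raise ValueError(f"resource {self.id}: languages must be non-empty")


def load_resources(path: str | Path) -> list[Resource]:
    df = pd.read_csv(path, dtype={"zip": str})
    return [
        Resource(
            id=row["id"],
            kind=row["kind"],
            name=row["name"],
            zip=str(row["zip"]),
            lat=float(row["lat"]),
            lon=float(row["lon"]),
            languages=tuple(str(row["languages"]).split(";")),
            specialty=row["specialty"],
        )
        for _, row in df.iterrows()
    ]


def load_centroids(path: str | Path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path, dtype={"zip": str})
    return {str(r["zip"]): (float(r["lat"]), float(r["lon"])) for _, r in df.iterrows()}


# ---------------------------------------------------------------------- #
# the graph itself

class PersonalGraph:
    """Typed property multigraph for one screening session.

    Node ids are namespaced (``user:``, ``concept:``, ``value:``,
    ``question:``, ``resource:``); every node has a ``kind`` attribute and
    every inferred edge a ``source_of_inference`` and ``confidence``.
    """

    def __init__(self, session_id: str):
        self.session_id = session_id
        self.g = nx.MultiDiGraph()
        self.user_node = f"user:{session_id}"
        self.g.add_node(self.user_node, kind="user", label=f"user {session_id}")
        self.answered_questions: set[str] = set()
        # neighborhood metrics observed but not dominant: present in the
        # graph as values, yet excluded from forward causal firing (the
        # maximum-metric rule owns their expansion)
        self.suppressed_causal: set[str] = set()

    # -- node/edge helpers -------------------------------------------------

    @staticmethod
    def concept_node(concept_id: str) -> str:
        return f"concept:{concept_id}"

    @staticmethod
    def value_node(concept_id: str, value: str) -> str:
        return f"value:{concept_id}:{value}"

    def concept_ids(self) -> list[str]:
        return sorted(
            d["concept"] for _n, d in self.g.nodes(data=True) if d.get("kind") == "concept"
        )

    def has_concept(self, concept_id: str) -> bool:
        return self.g.has_node(self.concept_node(concept_id))

    def add_edge_once(self, u: str, v: str, relation: str, **props) -> bool:
        """Add an edge unless an identical (u, v, relation, label) exists."""
        label = props.get("label", relation)
        for _k, data in self.g.get_edge_data(u, v, default={}).items():
            if data.get("relation") == relation and data.get("label", data.get("relation")) == label:
                return False
        self.g.add_edge(u, v, relation=relation, **props)
        return True

    def ensure_concept(self, ont: Ontology, concept_id: str) -> str:
        """Add a concept node and link it upward along is_a into the graph."""
        node = self.concept_node(concept_id)
        if not self.g.has_node(node):
            c = ont.concept(concept_id)
            self.g.add_node(
                node, kind="concept", concept=concept_id, label=c.label,
                category=c.category.value,
            )
        for parent in ont.parents(concept_id):
            pnode = self.ensure_concept(ont, parent)
            self.add_edge_once(
                node, pnode, "is_a",
                source_of_inference=ont.default_source("ontology"),
                confidence=1.0,
            )
        return node

    def ensure_value(self, ont: Ontology, concept_id: str, value: str,
                     source: Optional[str] = None) -> str:
        cnode = self.ensure_concept(ont, concept_id)
        vnode = self.value_node(concept_id, value)
        if not self.g.has_node(vnode):
            self.g.add_node(vnode, kind="value", concept=concept_id, payload=value,
                            label=str(value))
        self.add_edge_once(
            cnode, vnode, "has_value",
            source_of_inference=source or ont.default_source("ontology"),
            confidence=1.0,
        )
        return vnode

    def value_of(self, concept_id: str) -> Optional[str]:
        """First value recorded under a concept node, if any."""
        cnode = self.concept_node(concept_id)
        if not self.g.has_node(cnode):
            return None
        for _u, v, data in sorted(self.g.out_edges(cnode, data=True), key=lambda e: e[1]):
            if data.get("relation") == "has_value":
                return self.g.nodes[v].get("payload")
        return None

    def node_counts(self) -> tuple[int, int]:
        return self.g.number_of_nodes(), self.g.number_of_edges()


def init_graph(session_id: str) -> PersonalGraph:
    """A fresh graph containing exactly the user node."""
    return PersonalGraph(session_id)


def ingest_parameters(
    graph: PersonalGraph,
    ont: Ontology,
    params: Iterable[tuple[str, str]],
) -> PersonalGraph:
    """Add concept + value nodes for each (entity type, value) parameter.

    The concept resolves to the canonical lexicon value when that value is
    itself a concept (lead-based paint rather than generic housing
    circumstance). Concepts link upward along is_a; school-age children
    additionally link the age concept to the school-age concept. Unknown
    entity types are skipped with a warning. Idempotent.
    """
    from .surveillance import resolve_param_concept

    for etype, value in params:
        concept = resolve_param_concept(ont, etype, value)
        if concept is None:
            warnings.warn(f"unknown entity type {etype!r}; parameter skipped")
            continue
        cnode = graph.ensure_concept(ont, concept)
        graph.add_edge_once(
            graph.user_node, cnode, "has_concept",
            source_of_inference=ont.default_source("ontology"), confidence=1.0,
        )
        if value != concept:
            graph.ensure_value(ont, concept, value)
        if concept in ("age", "child_age") and "school_age" in ont:
            try:
                age = int(str(value))
            except ValueError:
                age = None
            if age in SCHOOL_AGE_RANGE:
                snode = graph.ensure_concept(ont, "school_age")
                graph.add_edge_once(
                    cnode, snode, "derived", label="in_age_band",
                    source_of_inference=ont.default_source("ontology"),
                    confidence=1.0,
                )
    return graph


def apply_axioms(graph: PersonalGraph, ont: Ontology) -> list[tuple[str, str, str]]:
    """Bounded forward chaining over the causal axioms, to fixpoint.

    A causal axiom fires forward when its subject concept is present,
    adding the object concept and a provenance-labelled causal edge. Axioms
    whose object is a *symptom* present in the graph additionally fire
    abductively — observing night terror adds emotional neglect as a
    suspected cause — with the edge kept in axiom direction and flagged
    ``abduced``. New concepts link upward along is_a, so inherited axioms
    fire on later sweeps. Terminates (finite concepts, duplicate-free
    edges) and is idempotent at fixpoint. Returns the new edges.
    """
    new_edges: list[tuple[str, str, str]] = []
    changed = True
    while changed:
        changed = False
        present = set(graph.concept_ids())
        for ax in ont.axioms:
            if ax.relation not in {Relation.CAUSES, Relation.LEADS_TO, Relation.RISK_FACTOR_OF}:
                continue
            fire_forward = (
                ax.subject in present and ax.subject not in graph.suppressed_causal
            )
            fire_abduce = (
                ax.object in present
                and ont.concept(ax.object).category is Category.SYMPTOM
            )
            if not (fire_forward or fire_abduce):
                continue
            snode = graph.ensure_concept(ont, ax.subject)
            onode = graph.ensure_concept(ont, ax.object)
            added = graph.add_edge_once(
                snode, onode, "causal", label=ax.relation.value,
                source_of_inference=ax.provenance,
                confidence=ont.confidence_for(ax.provenance),
                inferred=True, abduced=not fire_forward,
            )
            if added:
                changed = True
                new_edges.append((ax.subject, ax.object, ax.relation.value))
    return new_edges


def attach_neighborhood(
    graph: PersonalGraph,
    ont: Ontology,
    provider: NeighborhoodProvider,
    zip_value: str,
) -> PersonalGraph:
    """Attach neighborhood metrics for the user's zip and expand the worst.

    Adds a ``livesIn`` edge from the user to a neighborhood instance, links
    the zip-code concept into the neighborhood's physical characteristics,
    and records each metric's value. The maximum-valued metric's concept
    (all of them on a tie; none when every metric is zero) is expanded
    along its causal closure — e.g. dominant blight materializes the
    blight -> toxicant exposure -> asthma chain.
    """
    metrics = provider.metrics_for(zip_value)
    if metrics is None:
        warnings.warn(f"no neighborhood metrics for zip {zip_value!r}")
        return graph
    nbhd_src = ont.default_source("neighborhood_repository")
    conf = ont.confidence_for(nbhd_src)

    nbhd_cnode = graph.ensure_concept(ont, "neighborhood")
    nbhd_inst = graph.ensure_value(ont, "neighborhood", zip_value, source=nbhd_src)
    graph.add_edge_once(
        graph.user_node, nbhd_inst, "derived", label="livesIn",
        source_of_inference=nbhd_src, confidence=conf, inferred=True,
    )
    zip_cnode = graph.ensure_concept(ont, "zip_code")
    graph.add_edge_once(
        zip_cnode, nbhd_cnode, "derived", label="locatedIn",
        source_of_inference=nbhd_src, confidence=conf, inferred=True,
    )
    max_names = set(provider.max_metrics(zip_value))
    for name in sorted(metrics):
        if name not in ont:
            continue
        mnode = graph.ensure_concept(ont, name)
        graph.add_edge_once(
            nbhd_cnode, mnode, "derived", label="hasCharacteristic",
            source_of_inference=nbhd_src, confidence=conf, inferred=True,
        )
        graph.ensure_value(ont, name, _fmt_metric(metrics[name]), source=nbhd_src)
        if name in max_names:
            graph.suppressed_causal.discard(name)
        else:
            graph.suppressed_causal.add(name)
    for name in sorted(max_names):
        if name in ont:
            _expand_causal_chain(graph, ont, name)
    return graph


def _fmt_metric(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else str(v)


def _expand_causal_chain(graph: PersonalGraph, ont: Ontology, concept_id: str) -> None:
    """Materialize every witnessing axiom chain from ``concept_id``."""
    for cons in ont.causal_closure(concept_id):
        for ax in cons.chain:
            snode = graph.ensure_concept(ont, ax.subject)
            onode = graph.ensure_concept(ont, ax.object)
            if ax.relation is Relation.IS_A:
                continue  # ensure_concept already linked the hierarchy
            graph.add_edge_once(
                snode, onode, "causal", label=ax.relation.value,
                source_of_inference=ax.provenance,
                confidence=ont.confidence_for(ax.provenance),
                inferred=True, abduced=False,
            )


def suggest_questions(
    graph: PersonalGraph,
    ont: Ontology,
    answered: Optional[set[str]] = None,
) -> list:
    """Add question nodes for the graph's ACE-related concepts.

    Question selection delegates to the ACE surveillance pool filter;
    already-answered questions are excluded. Returns the newly suggested
    questions in pool order.
    """
    answered = answered if answered is not None else graph.answered_questions
    ace_concepts = []
    for cid in graph.concept_ids():
        try:
            if ont.classify_risk_factor(cid) == "ACE":
                ace_concepts.append(cid)
        except Exception:
            continue
    out = []
    q_src = None
    for q in select_ace_questions(ont, ace_concepts):
        if q.id in answered:
            continue
        qnode = f"question:{q.id}"
        if graph.g.has_node(qnode):
            continue
        if q_src is None:
            try:
                q_src = ont.default_source("questionnaire")
            except KeyError:
                q_src = ont.default_source("ontology")
        graph.g.add_node(qnode, kind="question", payload=q.id, label=q.text)
        cnode = graph.ensure_concept(ont, q.concept)
        graph.add_edge_once(
            cnode, qnode, "suggests_question",
            source_of_inference=q_src, confidence=1.0, inferred=True,
        )
        out.append(q)
    return out


@dataclass
class ResourceSuggestion:
    resource: Resource
    distance_miles: Optional[float]
    node: str


@dataclass
class SuggestionResult:
    suggestions: list[ResourceSuggestion]
    radius_applied: bool


def suggest_resources(
    graph: PersonalGraph,
    ont: Ontology,
    directory: Sequence[Resource],
    centroids: Mapping[str, tuple[float, float]],
    specialty: str,
    language: Optional[str] = None,
    radius_miles: float = DEFAULT_RADIUS_MILES,
    trigger_concept: Optional[str] = None,
) -> SuggestionResult:
    """Filter and rank the resource directory, adding resource nodes.

    Resources must match the requested specialty by concept subsumption,
    offer the requested language (when one is known), and lie within the
    great-circle radius of the user's zip centroid. Without a zip on the
    graph the radius filter is skipped and the result flagged. Ranked by
    distance ascending, then resource id.
    """
    user_zip = graph.value_of("zip_code")
    origin = centroids.get(user_zip) if user_zip else None
    radius_applied = origin is not None

    picked: list[tuple[float, str, Resource, Optional[float]]] = []
    for res in directory:
        if res.specialty in ont and specialty in ont:
            if not ont.is_subtype(res.specialty, specialty):
                continue
        elif res.specialty != specialty:
            continue
        if language is not None and language.lower() not in {
            l.strip().lower() for l in res.languages
        }:
            continue
        dist = None
        if radius_applied:
            dist = haversine_miles(origin[0], origin[1], res.lat, res.lon)
            if dist > radius_miles:
                continue
        picked.append((dist if dist is not None else 0.0, res.id, res, dist))

    picked.sort(key=lambda t: (t[0], t[1]))
    trigger = trigger_concept or specialty
    suggestions = []
    for _d, _rid, res, dist in picked:
        rnode = f"resource:{res.id}"
        if not graph.g.has_node(rnode):
            graph.g.add_node(
                rnode, kind="resource", payload=res.id, label=res.name,
                resource_kind=res.kind, zip=res.zip,
            )
        if trigger in ont:
            cnode = graph.ensure_concept(ont, trigger)
            graph.add_edge_once(
                cnode, rnode, "suggests_resource",
                source_of_inference=_directory_source(ont),
                confidence=ont.confidence_for(_directory_source(ont)),
                inferred=True,
                distance_miles=round(dist, 3) if dist is not None else None,
            )
        suggestions.append(ResourceSuggestion(resource=res, distance_miles=dist, node=rnode))
    return SuggestionResult(suggestions=suggestions, radius_applied=radius_applied)


def _directory_source(ont: Ontology) -> str:
    try:
        return ont.default_source("neighborhood_repository")
    except KeyError:
        return ont.default_source("ontology")


# ---------------------------------------------------------------------- #
# explanation

@dataclass
class InferencePath:
    """Concrete node/edge route from the user node to a recommendation."""

    nodes: list[str]
    edges: list[dict]

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class MetaPath:
    """Type-level abstraction of an inference path.

    Node elements are node kinds, except concept nodes which abstract to
    their ontology category; edge elements are relation labels. Reusable
    for future users with similar contextual parameters via :meth:`match`.
    """

    node_types: tuple[str, ...]
    relations: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.relations)

    def match(self, graph: PersonalGraph, start: Optional[str] = None) -> list[list[str]]:
        """Concrete paths in ``graph`` conforming to this metapath."""
        start = start or graph.user_node
        results: list[list[str]] = []

        def abstract(node: str) -> str:
            data = graph.g.nodes[node]
            if data.get("kind") == "concept":
                return data.get("category", "concept")
            return data.get("kind", "?")

        def walk(node: str, depth: int, path: list[str]):
            if abstract(node) != self.node_types[depth]:
                return
            if depth == len(self.node_types) - 1:
                results.append(list(path))
                return
            want = self.relations[depth]
            for _u, v, data in sorted(graph.g.out_edges(node, data=True), key=lambda e: e[1]):
                if data.get("label", data.get("relation")) == want and v not in path:
                    path.append(v)
                    walk(v, depth + 1, path)
                    path.pop()

        walk(start, 0, [start])
        return results


@dataclass
class Explanation:
    path: InferencePath
    metapath: MetaPath
    text: str


def explain_recommendation(
    graph: PersonalGraph, ont: Ontology, recommendation_node: str
) -> Explanation:
    """Replay why a recommendation node was added.

    Takes the shortest path from the user node (ties: fewest inferred
    edges, then lexicographic node sequence), abstracts it to a metapath,
    and renders one line per hop with the source of inference behind it.
    Raises :class:`GraphIntegrityError` when the recommendation is not
    reachable — a recommendation must never appear without a justification.
    """
    if not graph.g.has_node(recommendation_node):
        raise GraphIntegrityError(f"no such node: {recommendation_node}")

    def best_edge(u: str, v: str) -> dict:
        datas = sorted(
            graph.g.get_edge_data(u, v).values(),
            key=lambda d: (bool(d.get("inferred")), d.get("label", d.get("relation", ""))),
        )
        return datas[0]

    simple = nx.DiGraph(graph.g)
    try:
        paths = list(nx.all_shortest_paths(simple, graph.user_node, recommendation_node))
    except nx.NetworkXNoPath:
        raise GraphIntegrityError(
            f"{recommendation_node} is unreachable from the user node"
        ) from None

    def key(p: list[str]):
        inferred = sum(
            1 for u, v in zip(p, p[1:]) if best_edge(u, v).get("inferred")
        )
        return (inferred, tuple(p))

    nodes = min(paths, key=key)
    edges = [dict(best_edge(u, v), source=u, target=v) for u, v in zip(nodes, nodes[1:])]
    path = InferencePath(nodes=nodes, edges=edges)

    def abstract(node: str) -> str:
        data = graph.g.nodes[node]
        if data.get("kind") == "concept":
            return data.get("category", "concept")
        return data.get("kind", "?")

    meta = MetaPath(
        node_types=tuple(abstract(n) for n in nodes),
        relations=tuple(e.get("label", e.get("relation", "")) for e in edges),
    )

    lines = []
    for e in edges:
        src_id = e.get("source_of_inference", "")
        citation = ""
        try:
            s = ont.source(src_id)
            citation = s.citation or s.kind
        except KeyError:
            citation = src_id
        u_label = graph.g.nodes[e["source"]].get("label", e["source"])
        v_label = graph.g.nodes[e["target"]].get("label", e["target"])
        rel = e.get("label", e.get("relation", ""))
        conf = e.get("confidence")
        conf_txt = f", confidence {conf:.2f}" if isinstance(conf, (int, float)) else ""
        lines.append(f"{u_label} --[{rel}]--> {v_label}  (source: {citation}{conf_txt})")
    return Explanation(path=path, metapath=meta, text="\n".join(lines))


# ---------------------------------------------------------------------- #
# export

def graph_to_dict(graph: PersonalGraph) -> dict:
    return {
        "schema": GRAPH_SCHEMA,
        "session_id": graph.session_id,
        "answered_questions": sorted(graph.answered_questions),
        "suppressed_causal": sorted(graph.suppressed_causal),
        "graph": nx.node_link_data(graph.g, edges="edges"),
    }


def graph_from_dict(doc: dict) -> PersonalGraph:
    if doc.get("schema") != GRAPH_SCHEMA:
        raise ValueError(f"unsupported graph schema: {doc.get('schema')!r}")
    pg = PersonalGraph(doc["session_id"])
    pg.g = nx.node_link_graph(doc["graph"], directed=True, multigraph=True, edges="edges")
    pg.answered_questions = set(doc.get("answered_questions", []))
    pg.suppressed_causal = set(doc.get("suppressed_causal", []))
    return pg


def export_graph(graph: PersonalGraph, path: str | Path, fmt: str = "json") -> None:
    """Write the graph as ``json`` (lossless), ``graphml`` or ``dot``."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(graph_to_dict(graph), indent=1, sort_keys=True))
    elif fmt == "graphml":
        g = nx.MultiDiGraph()
        for n, d in graph.g.nodes(data=True):
            g.add_node(n, **{k: _gml(v) for k, v in d.items()})
        for u, v, d in graph.g.edges(data=True):
            g.add_edge(u, v, **{k: _gml(val) for k, val in d.items()})
        nx.write_graphml(g, path)
    elif fmt == "dot":
        path.write_text(to_dot(graph))
    else:
        raise ValueError(f"unknown export format: {fmt!r}")


def _gml(v):
    if v is None:
        return ""
    if isinstance(v, (str, int, float, bool)):
        return v
    return str(v)


_DOT_SHAPES = {
    "user": "doublecircle",
    "concept": "ellipse",
    "value": "box",
    "question": "note",
    "resource": "house",
}


def to_dot(graph: PersonalGraph) -> str:
    """Render a GraphViz DOT document; inferred edges are dashed."""
    def q(s: str) -> str:
        return '"' + str(s).replace('"', r"\"") + '"'

    lines = [f"digraph {q(graph.session_id)} {{", "  rankdir=LR;"]
    for n, d in sorted(graph.g.nodes(data=True)):
        shape = _DOT_SHAPES.get(d.get("kind", ""), "ellipse")
        lines.append(f"  {q(n)} [label={q(d.get('label', n))}, shape={shape}];")
    for u, v, d in sorted(graph.g.edges(data=True), key=lambda e: (e[0], e[1])):
        style = "dashed" if d.get("inferred") else "solid"
        rel = d.get("label", d.get("relation", ""))
        lines.append(f"  {q(u)} -> {q(v)} [label={q(rel)}, style={style}];")
    lines.append("}")
    return "\n".join(lines) + "\n"
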