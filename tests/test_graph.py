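"""Personal knowledge graph: population, inference, recommendation paths."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from acescreen.fixtures import build_aceso_lite
from acescreen.graph import (
    GraphIntegrityError,
    Resource,
    apply_axioms,
    attach_neighborhood,
    explain_recommendation,
    export_graph,
    graph_from_dict,
    graph_to_dict,
    haversine_miles,
    ingest_parameters,
    init_graph,
    suggest_questions,
    suggest_resources,
    to_dot,
)
from acescreen.ontology import Category, ontology_from_dict
from acescreen.surveillance import NeighborhoodProvider


# ---------------------------------------------------------------------- #
# initialization and ingestion

def test_init_graph_contains_exactly_the_user_node():
    g = init_graph("alice")
    assert g.node_counts() == (1, 0)
    g2 = init_graph("bob")
    assert g2.user_node != g.user_node
    assert g.node_counts() == (1, 0)  # independent graphs


def test_ingest_zip_code_adds_concept_and_value_nodes(ont):
    g = init_graph("s")
    ingest_parameters(g, ont, [("zip_code", "38103")])
    assert g.has_concept("zip_code")
    assert g.value_of("zip_code") == "38103"


def test_ingest_school_age_child_links_age_band(ont):
    g = init_graph("s")
    ingest_parameters(g, ont, [("child_age", "6")])
    assert g.has_concept("school_age")
    edges = [
        d.get("label")
        for _u, _v, d in g.g.out_edges(g.concept_node("child_age"), data=True)
    ]
    assert "in_age_band" in edges
    # a toddler does not get the link
    g2 = init_graph("s2")
    ingest_parameters(g2, ont, [("child_age", "4")])
    assert not g2.has_concept("school_age")


def test_ingest_is_idempotent(ont):
    g = init_graph("s")
    params = [("zip_code", "38103"), ("symptom", "night_terror")]
    ingest_parameters(g, ont, params)
    counts = g.node_counts()
    ingest_parameters(g, ont, params)
    assert g.node_counts() == counts


def test_unknown_entity_type_is_skipped_with_warning(ont):
    g = init_graph("s")
    with pytest.warns(UserWarning, match="unknown entity type"):
        ingest_parameters(g, ont, [("martian_concept", "42")])
    assert g.node_counts()[0] == 1


def test_ingest_links_concepts_upward_along_is_a(ont):
    g = init_graph("s")
    ingest_parameters(g, ont, [("symptom", "night_terror")])
    assert g.has_concept("symptom")  # the root arrived via the hierarchy


# ---------------------------------------------------------------------- #
# axiom saturation

def test_night_terror_abduces_emotional_neglect(ont):
    g = init_graph("s")
    ingest_parameters(g, ont, [("symptom", "night_terror")])
    new_edges = apply_axioms(g, ont)
    assert ("emotional_neglect", "night_terror", "causes") in new_edges
    assert g.has_concept("emotional_neglect")


def test_no_matching_concepts_no_new_edges(ont):
    g = init_graph("s")
    ingest_parameters(g, ont, [("zip_code", "38103")])
    assert apply_axioms(g, ont) == []


def test_apply_axioms_is_idempotent_at_fixpoint(ont):
    g = init_graph("s")
    ingest_parameters(g, ont, [("symptom", "night_terror"), ("stress", "stress")])
    apply_axioms(g, ont)
    assert apply_axioms(g, ont) == []


def test_every_inferred_edge_carries_provenance(ont, provider):
    g = init_graph("s")
    ingest_parameters(g, ont, [("zip_code", "38103"), ("symptom", "night_terror")])
    apply_axioms(g, ont)
    attach_neighborhood(g, ont, provider, "38103")
    for _u, _v, d in g.g.edges(data=True):
        if d.get("inferred"):
            assert d.get("source_of_inference")


def _tiny_ontology(rng, n=6):
    ids = [f"c{i}" for i in range(n)]
    cats = ["symptom" if rng.random() < 0.3 else "other" for _ in ids]
    axioms = []
    for i, j in itertools.combinations(range(n), 2):
        r = rng.random()
        if r < 0.15:
            axioms.append({"subject": ids[i], "relation": "is_a",
                           "object": ids[j], "provenance": "src"})
        elif r < 0.3:
            axioms.append({"subject": ids[i], "relation": "causes",
                           "object": ids[j], "provenance": "src"})
    return ontology_from_dict({
        "schema_version": "1.0",
        "sources": [{"id": "src", "kind": "ontology"}],
        "concepts": [{"id": c, "label": c, "category": cat}
                     for c, cat in zip(ids, cats)],
        "axioms": axioms,
        "score_rules": [[0, "all"]],
    })


def _brute_force_saturation(ont, seeds: set[str]) -> set[str]:
    """Independent closure of a node set under the firing rules: upward
    is_a, forward causal, and abduction into symptom-category objects."""
    present = set(seeds)
    changed = True
    while changed:
        changed = False
        for ax in ont.axioms:
            if ax.relation.value == "is_a":
                if ax.subject in present and ax.object not in present:
                    present.add(ax.object)
                    changed = True
            else:
                if ax.subject in present and ax.object not in present:
                    present.add(ax.object)
                    changed = True
                if (ax.object in present
                        and ont.concept(ax.object).category is Category.SYMPTOM
                        and ax.subject not in present):
                    present.add(ax.subject)
                    changed = True
    return present


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_fixpoint_equals_brute_force_closure_of_node_set(seed):
    rng = np.random.default_rng(seed)
    ont = _tiny_ontology(rng)
    ids = [c.id for c in ont.concepts]
    k = int(rng.integers(1, 4))
    seeds = set(rng.choice(ids, size=k, replace=False))
    g = init_graph("s")
    ingest_parameters(g, ont, [(c, c) for c in seeds])
    apply_axioms(g, ont)
    assert set(g.concept_ids()) == _brute_force_saturation(ont, seeds)


def test_population_is_order_insensitive(ont):
    params = [("zip_code", "38103"), ("symptom", "night_terror"),
              ("parental_separation", "parental_separation"), ("child_age", "6")]
    snapshots = []
    for perm in (params, params[::-1]):
        g = init_graph("s")
        ingest_parameters(g, ont, perm)
        apply_axioms(g, ont)
        snapshots.append(
            (sorted(g.g.nodes),
             sorted((u, v, d["relation"]) for u, v, d in g.g.edges(data=True)))
        )
    assert snapshots[0] == snapshots[1]


# ---------------------------------------------------------------------- #
# neighborhood attachment

def _seeded_graph(ont, zip_code="38103"):
    g = init_graph("s")
    ingest_parameters(g, ont, [("zip_code", zip_code)])
    return g


def test_dominant_blight_materializes_the_asthma_chain(ont, provider):
    g = _seeded_graph(ont)
    attach_neighborhood(g, ont, provider, "38103")
    assert g.value_of("blight") == "80"
    for cid in ("blight", "toxicant_exposure", "asthma"):
        assert g.has_concept(cid)
    labels = {
        (u, v): d.get("label")
        for u, v, d in g.g.edges(data=True) if d.get("relation") == "causal"
    }
    assert labels[(g.concept_node("blight"), g.concept_node("toxicant_exposure"))] == "causes"
    assert labels[(g.concept_node("toxicant_exposure"), g.concept_node("asthma"))] == "leads_to"


def test_all_zero_metrics_add_values_but_no_causal_expansion(ont, provider):
    g = _seeded_graph(ont, "38105")
    attach_neighborhood(g, ont, provider, "38105")
    assert g.has_concept("blight") and g.value_of("blight") == "0"
    assert not g.has_concept("asthma")
    assert not any(d.get("relation") == "causal" for *_e, d in g.g.edges(data=True))


def test_non_maximum_metric_never_drives_expansion(ont, provider):
    # 38104: walkability dominates; its 20% blight must stay inert even
    # through a later global saturation pass
    g = _seeded_graph(ont, "38104")
    attach_neighborhood(g, ont, provider, "38104")
    apply_axioms(g, ont)
    assert not g.has_concept("asthma")


def test_tied_maximum_expands_all_tied_metrics(ont):
    table = pd.DataFrame([
        {"zip": "11111", "blight": 50, "walkability": 50},
    ])
    provider = NeighborhoodProvider(table)
    assert provider.max_metrics("11111") == ["blight", "walkability"]
    g = _seeded_graph(ont, "11111")
    attach_neighborhood(g, ont, provider, "11111")
    # blight's chain fires; walkability has no causal axioms but is expanded
    assert g.has_concept("asthma")
    assert "blight" not in g.suppressed_causal
    assert "walkability" not in g.suppressed_causal


def test_unknown_zip_is_a_warning_no_op(ont, provider):
    g = _seeded_graph(ont, "99999")
    counts = g.node_counts()
    with pytest.warns(UserWarning, match="no neighborhood metrics"):
        attach_neighborhood(g, ont, provider, "99999")
    assert g.node_counts() == counts


def test_lives_in_edge_carries_neighborhood_provenance(ont, provider):
    g = _seeded_graph(ont)
    attach_neighborhood(g, ont, provider, "38103")
    lives = [
        d for _u, _v, d in g.g.out_edges(g.user_node, data=True)
        if d.get("label") == "livesIn"
    ]
    assert len(lives) == 1
    assert ont.source(lives[0]["source_of_inference"]).kind == "neighborhood_repository"


# ---------------------------------------------------------------------- #
# question suggestions

def test_ace_concept_triggers_its_follow_up_question(ont):
    g = init_graph("s")
    ingest_parameters(g, ont, [("symptom", "night_terror")])
    apply_axioms(g, ont)  # emotional neglect arrives by abduction
    qs = suggest_questions(g, ont)
    assert any(q.concept == "emotional_neglect" for q in qs)


def test_no_ace_concepts_no_questions(ont):
    g = init_graph("s")
    ingest_parameters(g, ont, [("zip_code", "38103")])
    assert suggest_questions(g, ont) == []


def test_answered_questions_are_not_resuggested(ont):
    g = init_graph("s")
    ingest_parameters(g, ont, [("parental_separation", "parental_separation")])
    g.answered_questions = {q.id for q in ont.ace_questions}
    assert suggest_questions(g, ont) == []


# ---------------------------------------------------------------------- #
# resource suggestions

def test_scenario4_graph_gets_spanish_asthma_clinic(ont, provider, directory, centroids):
    g = _seeded_graph(ont)
    attach_neighborhood(g, ont, provider, "38103")
    result = suggest_resources(
        g, ont, directory, centroids, specialty="asthma", language="spanish",
    )
    assert result.radius_applied
    names = [s.resource.name for s in result.suggestions]
    assert "Downtown Pediatric Asthma Clinic" in names
    # the far English-only clinic is filtered by both radius and language
    assert "Suburban Asthma and Allergy Clinic" not in names


def test_empty_directory_yields_nothing(ont, centroids):
    g = _seeded_graph(ont)
    result = suggest_resources(g, ont, [], centroids, specialty="asthma")
    assert result.suggestions == []


def test_missing_zip_skips_radius_and_flags(ont, directory, centroids):
    g = init_graph("s")
    result = suggest_resources(g, ont, directory, centroids, specialty="asthma")
    assert not result.radius_applied
    assert result.suggestions  # both asthma clinics, unfiltered by distance


def test_radius_zero_keeps_only_centroid_resources(ont, directory, centroids):
    g = _seeded_graph(ont)
    result = suggest_resources(
        g, ont, directory, centroids, specialty="asthma", radius_miles=0.0,
    )
    assert [s.resource.id for s in result.suggestions] == ["r001"]


def _brute_force_filter(directory, centroids, ont, zip_code, specialty,
                        language, radius):
    origin = centroids[zip_code]
    keep = []
    for r in directory:
        if not ont.is_subtype(r.specialty, specialty) if (r.specialty in ont and specialty in ont) else (r.specialty != specialty):
            continue
        if language and language not in {l.lower() for l in r.languages}:
            continue
        if haversine_miles(origin[0], origin[1], r.lat, r.lon) > radius:
            continue
        keep.append(r.id)
    return set(keep)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 5000),
    radius=st.floats(0.1, 30.0),
    specialty=st.sampled_from(["asthma", "food_insecurity", "education_issue", "sdoh"]),
    language=st.sampled_from([None, "spanish", "english"]),
)
def test_resource_filter_matches_exhaustive_haversine_check(seed, radius, specialty, language):
    from acescreen.fixtures import resource_directory

    ont = build_aceso_lite()
    rng = np.random.default_rng(seed)
    df, cdf = resource_directory(seed=seed % 7 + 1)
    directory = [
        Resource(id=r["id"], kind=r["kind"], name=r["name"], zip=str(r["zip"]),
                 lat=float(r["lat"]), lon=float(r["lon"]),
                 languages=tuple(str(r["languages"]).split(";")),
                 specialty=r["specialty"])
        for _, r in df.iterrows()
    ]
    centroids = {str(r["zip"]): (float(r["lat"]), float(r["lon"]))
                 for _, r in cdf.iterrows()}
    zip_code = str(rng.choice(sorted({r.zip for r in directory})))
    g = init_graph("s")
    ingest_parameters(g, ont, [("zip_code", zip_code)])
    result = suggest_resources(
        g, ont, directory, centroids, specialty=specialty,
        language=language, radius_miles=radius,
    )
    got = {s.resource.id for s in result.suggestions}
    expected = _brute_force_filter(directory, centroids, ont, zip_code,
                                   specialty, language, radius)
    assert got == expected
    # ranked by distance ascending
    dists = [s.distance_miles for s in result.suggestions]
    assert dists == sorted(dists)


# ---------------------------------------------------------------------- #
# explanation

def _scenario4_like_graph(ont, provider, directory, centroids):
    g = init_graph("alice")
    ingest_parameters(g, ont, [("zip_code", "38103"), ("symptom", "night_terror")])
    apply_axioms(g, ont)
    attach_neighborhood(g, ont, provider, "38103")
    suggest_resources(g, ont, directory, centroids, specialty="asthma",
                      language="spanish")
    return g


def test_explanation_traverses_zip_blight_toxicant_asthma(ont, provider, directory, centroids):
    g = _scenario4_like_graph(ont, provider, directory, centroids)
    expl = explain_recommendation(g, ont, "resource:r001")
    concepts = [n.split(":", 1)[1] for n in expl.path.nodes if n.startswith("concept:")]
    for a, b in zip(["zip_code", "blight", "toxicant_exposure", "asthma"],
                    ["blight", "toxicant_exposure", "asthma", None]):
        assert a in concepts
        if b:
            assert concepts.index(a) < concepts.index(b)
    # every hop exists in the graph and carries a source
    for e in expl.path.edges:
        assert g.g.has_edge(e["source"], e["target"])
        assert e.get("source_of_inference")
    sources = {ont.source(e["source_of_inference"]).kind for e in expl.path.edges}
    assert {"neighborhood_repository", "ontology"} <= sources


def test_metapath_length_matches_path_length(ont, provider, directory, centroids):
    g = _scenario4_like_graph(ont, provider, directory, centroids)
    expl = explain_recommendation(g, ont, "resource:r001")
    assert len(expl.metapath.node_types) == len(expl.path.nodes)
    assert len(expl.metapath.relations) == len(expl.path.edges)


def test_direct_user_edge_gives_length_one_path(ont):
    g = init_graph("s")
    g.g.add_node("resource:rX", kind="resource", payload="rX", label="X")
    g.g.add_edge(g.user_node, "resource:rX", relation="suggests_resource",
                 label="suggests_resource", source_of_inference="onto")
    expl = explain_recommendation(g, ont, "resource:rX")
    assert len(expl.path) == 1
    assert expl.metapath.node_types == ("user", "resource")
    assert expl.metapath.relations == ("suggests_resource",)


def test_unreachable_recommendation_is_an_integrity_error(ont):
    g = init_graph("s")
    g.g.add_node("resource:orphan", kind="resource", payload="o", label="o")
    with pytest.raises(GraphIntegrityError):
        explain_recommendation(g, ont, "resource:orphan")
    with pytest.raises(GraphIntegrityError):
        explain_recommendation(g, ont, "resource:never_added")


def test_metapath_transfers_to_a_similar_user(ont, provider, directory, centroids):
    """The abstraction of one user's route re-matches for a second user
    with analogous contextual parameters."""
    g1 = _scenario4_like_graph(ont, provider, directory, centroids)
    expl = explain_recommendation(g1, ont, "resource:r001")
    g2 = _scenario4_like_graph(ont, provider, directory, centroids)
    g2.session_id = "bob"  # same shape, different user
    matches = expl.metapath.match(g2)
    assert matches  # an analogous concrete route exists
    assert all(m[-1].startswith("resource:") for m in matches)


# ---------------------------------------------------------------------- #
# export

def test_json_export_round_trips_isomorphic(ont, provider, tmp_path):
    import networkx as nx

    g = _seeded_graph(ont)
    attach_neighborhood(g, ont, provider, "38103")
    p = tmp_path / "graph.json"
    export_graph(g, p, "json")
    import json

    g2 = graph_from_dict(json.loads(p.read_text()))
    assert nx.utils.graphs_equal(g.g, g2.g)
    assert g2.suppressed_causal == g.suppressed_causal


def test_dot_export_contains_asthma_and_dashed_inferred_edges(ont, provider, tmp_path):
    g = _seeded_graph(ont)
    attach_neighborhood(g, ont, provider, "38103")
    dot = to_dot(g)
    assert "concept:asthma" in dot
    assert "style=dashed" in dot
    p = tmp_path / "g.dot"
    export_graph(g, p, "dot")
    assert p.read_text() == dot


def test_graphml_export_preserves_kinds_and_relations(ont, tmp_path):
    import networkx as nx

    g = _seeded_graph(ont)
    p = tmp_path / "g.graphml"
    export_graph(g, p, "graphml")
    loaded = nx.read_graphml(p)
    kinds = {d.get("kind") for _n, d in loaded.nodes(data=True)}
    assert {"user", "concept", "value"} <= kinds
    assert {d.get("relation") for *_e, d in loaded.edges(data=True)} >= {"has_value"}


def test_empty_graph_exports_user_node_only(tmp_path):
    g = init_graph("solo")
    doc = graph_to_dict(g)
    assert len(doc["graph"]["nodes"]) == 1
    export_graph(g, tmp_path / "empty.dot", "dot")
    assert "user:solo" in (tmp_path / "empty.dot").read_text()


def test_unknown_format_rejected(tmp_path):
    with pytest.raises(ValueError, match="unknown export format"):
        export_graph(init_graph("s"), tmp_path / "x", "pdf")
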