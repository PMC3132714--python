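"""Ontology propagation and Parent-Child-Union enrichment, checked
against independent brute-force oracles in exact rational arithmetic."""

import random

import pytest

from blobcache.errors import ValidationError
from blobcache.service import ServiceRequest, handle
from blobcache.services.enrich import (
    EnrichService,
    OntologyDAG,
    go_enrichment,
    mesh_enrichment,
    parse_evidence_param,
    pcu_pvalue,
    propagate_annotations,
)

from conftest import commit_fixture_blob
from oracles import brute_pcu, brute_propagate, hypergeom_upper_tail_exact


def make_random_instance(rng, max_genes=50, max_terms=12):
    """One random DAG + annotation + study instance."""
    n_terms = rng.randint(2, max_terms)
    terms = [f"T{i}" for i in range(n_terms)]
    parents = {}
    for i, t in enumerate(terms):
        if i == 0:
            parents[t] = set()
        else:
            k = rng.randint(1, min(2, i))
            parents[t] = set(rng.sample(terms[:i], k))
    n_genes = rng.randint(2, max_genes)
    genes = list(range(1, n_genes + 1))
    direct = {}
    for g in genes:
        if rng.random() < 0.8:
            annotated = rng.sample(terms, rng.randint(1, min(3, n_terms)))
            direct[g] = {
                (t, rng.choice(["EXP", "IEA", "IDA"])) for t in annotated
            }
    study = set(rng.sample(genes, rng.randint(1, n_genes)))
    return parents, direct, study


# -- DAG basics --------------------------------------------------------------

def test_cycle_rejected():
    with pytest.raises(ValidationError):
        OntologyDAG({"A": {"B"}, "B": {"A"}})


def test_parent_outside_ontology_rejected():
    with pytest.raises(ValidationError):
        OntologyDAG({"A": {"GHOST"}})


def test_obo_reader_keeps_is_a_and_namespace(tmp_path):
    obo = tmp_path / "o.obo"
    obo.write_text(
        "format-version: 1.2\n\n"
        "[Term]\nid: GO:0000001\nname: root\nnamespace: cellular_component\n\n"
        "[Term]\nid: GO:0000002\nname: child\nnamespace: cellular_component\n"
        "is_a: GO:0000001 ! root\n"
    )
    dag = OntologyDAG.from_obo(obo)
    assert dag.parents["GO:0000002"] == {"GO:0000001"}
    assert dag.roots == {"GO:0000001"}
    assert dag.namespace["GO:0000002"] == "cellular_component"


# -- propagation --------------------------------------------------------------

def test_chain_propagates_to_all_ancestors():
    dag = OntologyDAG({"root": set(), "A": {"root"}, "B": {"A"}})
    annotations = propagate_annotations(dag, {7: {("B", "EXP")}})
    assert annotations.propagated == {"B": {7}, "A": {7}, "root": {7}}


def test_excluded_evidence_filtered_before_propagation():
    dag = OntologyDAG({"root": set(), "A": {"root"}, "B": {"A"}})
    annotations = propagate_annotations(
        dag, {7: {("B", "IEA")}}, excluded_evidence={"IEA"}
    )
    assert all(not genes for genes in annotations.propagated.values())


def test_unknown_term_annotation_skipped_with_warning(caplog):
    dag = OntologyDAG({"root": set()})
    with caplog.at_level("WARNING"):
        annotations = propagate_annotations(dag, {1: {("NOPE", "EXP")}})
    assert annotations.propagated == {"root": set()}
    assert any("unknown term" in r.message for r in caplog.records)


def test_true_path_rule_holds_on_random_dags():
    rng = random.Random(11)
    for _ in range(30):
        parents, direct, _ = make_random_instance(rng, max_genes=20, max_terms=12)
        dag = OntologyDAG(parents)
        annotations = propagate_annotations(dag, direct)
        for term, ps in parents.items():
            for p in ps:
                assert annotations.propagated[term] <= annotations.propagated[p]


def test_propagation_matches_reachability_oracle():
    rng = random.Random(5)
    for _ in range(40):
        parents, direct, _ = make_random_instance(rng, max_genes=25, max_terms=12)
        dag = OntologyDAG(parents)
        ours = propagate_annotations(dag, direct, excluded_evidence={"IEA"})
        theirs = brute_propagate(parents, direct, excluded={"IEA"})
        assert ours.propagated == theirs


# -- the p-value ---------------------------------------------------------------

def test_worked_hypergeometric_example():
    """N=10, K=4, n=5, k=3: p = (C(4,3)C(6,2)+C(4,4)C(6,1))/C(10,5) = 66/252."""
    # single parent whose annotation set is the background of 10 genes
    parents = {"pa": set(), "t": {"pa"}}
    direct = {}
    for g in range(1, 11):
        direct.setdefault(g, set()).add(("pa", "EXP"))
    for g in range(1, 5):  # K = 4 genes on t
        direct[g].add(("t", "EXP"))
    dag = OntologyDAG(parents)
    annotations = propagate_annotations(dag, direct)
    study = {1, 2, 3, 9, 10}  # n = 5 in background, k = 3 on t
    p = pcu_pvalue(dag, annotations, study, "t")
    assert p == pytest.approx(66 / 252, abs=1e-12)
    assert hypergeom_upper_tail_exact(10, 4, 5, 3) == pytest.approx(66 / 252)


def test_no_study_overlap_gives_p_one():
    parents = {"pa": set(), "t": {"pa"}}
    direct = {1: {("t", "EXP")}, 2: {("pa", "EXP")}, 3: {("pa", "EXP")}}
    dag = OntologyDAG(parents)
    annotations = propagate_annotations(dag, direct)
    assert pcu_pvalue(dag, annotations, {2, 3}, "t") == 1.0  # k = 0


def test_term_equal_to_parent_background_gives_p_one():
    parents = {"pa": set(), "t": {"pa"}}
    direct = {g: {("t", "EXP")} for g in range(1, 6)}  # A(t) == A(pa): K == N
    dag = OntologyDAG(parents)
    annotations = propagate_annotations(dag, direct)
    assert pcu_pvalue(dag, annotations, {1, 2}, "t") == 1.0


def test_root_background_is_all_annotated_genes():
    parents = {"root": set()}
    direct = {g: {("root", "EXP")} for g in range(1, 8)}
    dag = OntologyDAG(parents)
    annotations = propagate_annotations(dag, direct)
    assert pcu_pvalue(dag, annotations, {1, 2, 3}, "root") == 1.0  # K == N


def test_pvalue_monotone_in_study_overlap():
    """Adding one study gene annotated to t (background fixed) never
    increases p for t."""
    rng = random.Random(23)
    for _ in range(20):
        parents, direct, study = make_random_instance(rng, max_genes=30)
        dag = OntologyDAG(parents)
        annotations = propagate_annotations(dag, direct)
        for term in parents:
            extra = annotations.propagated[term] - study
            if not extra:
                continue
            p_before = pcu_pvalue(dag, annotations, study, term)
            p_after = pcu_pvalue(dag, annotations, study | {min(extra)}, term)
            if p_before is not None and p_after is not None:
                assert p_after <= p_before + 1e-12


def test_pcu_matches_exact_oracle_on_random_instances():
    """Full ranked enrichment equals the exact-arithmetic brute-force
    ranking (p to 1e-10, identical order) over seeded random instances."""
    rng = random.Random(99)
    for _ in range(60):
        parents, direct, study = make_random_instance(rng)
        dag = OntologyDAG(parents)
        annotations = propagate_annotations(dag, direct)
        ours = go_enrichment(dag, annotations, study, max_groups=10**6)
        theirs = brute_pcu(parents, direct, study)
        assert [r.term for r in ours] == [t for t, _, _ in theirs]
        for r, (_, p, members) in zip(ours, theirs):
            assert r.p_value == pytest.approx(float(p), abs=1e-10)
            assert r.members == members
            assert 0.0 < r.p_value <= 1.0


# -- ranking / truncation -------------------------------------------------------

@pytest.fixture
def small_instance():
    parents = {"root": set(), "A": {"root"}, "B": {"root"}, "C": {"A"}}
    direct = {
        1: {("C", "EXP")}, 2: {("C", "EXP")}, 3: {("A", "EXP")},
        4: {("B", "EXP")}, 5: {("B", "EXP")}, 6: {("root", "EXP")},
    }
    dag = OntologyDAG(parents)
    return dag, propagate_annotations(dag, direct)


def test_max_groups_truncates_after_ranking(small_instance):
    dag, annotations = small_instance
    study = {1, 2, 4}
    full = go_enrichment(dag, annotations, study, max_groups=100)
    top1 = go_enrichment(dag, annotations, study, max_groups=1)
    assert len(top1) == 1
    assert top1[0].term == full[0].term
    ps = [r.p_value for r in full]
    assert ps == sorted(ps)


def test_ties_break_by_term_id(small_instance):
    dag, annotations = small_instance
    results = go_enrichment(dag, annotations, {1, 2, 3, 4, 5, 6}, max_groups=100)
    for a, b in zip(results, results[1:]):
        assert (a.p_value, a.term) <= (b.p_value, b.term)


def test_namespace_filter_and_unknown_namespace():
    dag = OntologyDAG(
        {"GO:1": set(), "GO:2": {"GO:1"}},
        namespace={"GO:1": "cellular_component", "GO:2": "cellular_component"},
    )
    annotations = propagate_annotations(dag, {1: {("GO:2", "EXP")}, 2: {("GO:1", "EXP")}})
    assert go_enrichment(dag, annotations, {1}, namespace="Process") == []
    with pytest.raises(ValidationError):
        go_enrichment(dag, annotations, {1}, namespace="Banana")


# -- MeSH (flat vocabulary) ------------------------------------------------------

def test_mesh_term_annotating_all_genes_gives_p_one():
    term_genes = {"D1": {1, 2, 3}, "D2": {1}}
    results = mesh_enrichment(term_genes, {1, 2}, max_groups=10)
    assert {r.term: r.p_value for r in results}["D1"] == 1.0


def test_mesh_exclusive_term_matches_tail_oracle():
    """Study = exactly the genes with term m: p = 1/C(N, n) scenario."""
    term_genes = {"m": {1, 2}, "other": {3, 4, 5, 6}}
    results = mesh_enrichment(term_genes, {1, 2}, max_groups=10)
    by_term = {r.term: r for r in results}
    expected = hypergeom_upper_tail_exact(6, 2, 2, 2)  # = 1/15
    assert by_term["m"].p_value == pytest.approx(float(expected), abs=1e-12)
    assert by_term["m"].members == [1, 2]


def test_mesh_max_groups_respected():
    term_genes = {f"D{i}": {1, i + 10} for i in range(5)}
    assert len(mesh_enrichment(term_genes, {1}, max_groups=2)) == 2


# -- evidence parameter, service over blob ----------------------------------------

def test_evidence_param_parsing():
    assert parse_evidence_param("_IEA_") == {"IEA"}
    assert parse_evidence_param("_IEA_ISS_") == {"IEA", "ISS"}
    assert parse_evidence_param(None) == set()
    assert parse_evidence_param("") == set()


def test_enrich_service_over_blob(store, fixture_dir):
    out, manifest = fixture_dir
    commit_fixture_blob(store, out)
    annotated = sorted({a["gene_id"] for a in manifest.annotations})
    study = "|".join(str(g) for g in annotated[:6])
    resp = handle(
        ServiceRequest(
            "goEnrichment",
            {
                "species": "9606", "genes": study, "max": "5",
                "evid": "_IEA_", "type": "Component",
            },
        ),
        EnrichService(), store,
    )
    assert 1 <= len(resp.payload) <= 5
    assert all(0 < row["p_value"] <= 1 for row in resp.payload if "p_value" in row)

    mesh_resp = handle(
        ServiceRequest(
            "meshEnrichment", {"species": "9606", "genes": study, "max": "3"}
        ),
        EnrichService(), store,
    )
    assert len(mesh_resp.payload) <= 3


def test_unannotated_study_returns_diagnostic(store, fixture_dir):
    out, _ = fixture_dir
    commit_fixture_blob(store, out)
    resp = handle(
        ServiceRequest(
            "goEnrichment", {"species": "9606", "genes": "999999991", "max": "5"}
        ),
        EnrichService(), store,
    )
    assert resp.payload == [{"diagnostic": "no study gene annotated"}]
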