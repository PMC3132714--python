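"""GO and MeSH term-enrichment service (Parent-Child-Union).

The GO variant tests each candidate term t against the background of
genes annotated to the *union of t's parent terms* rather than against
the whole genome, which corrects for the annotation inheritance imposed
by the true-path rule.  With

    A(t)   = genes annotated to t or any descendant (after propagation),
    A_pa   = union over parents p of t of A(p)  (all annotated genes
             when t is a root),
    K = |A(t)|,  N = |A_pa|,  n = |study ∩ A_pa|,  k = |study ∩ A(t)|,

the group p-value is the upper-tail hypergeometric probability

    p = sum_{i=k}^{min(n, K)} C(K, i) C(N-K, n-i) / C(N, n),

so p = 1 exactly when k = 0 or when K = N.  MeSH terms, which arrive as
a flat vocabulary, are treated as children of a single artificial root,
under which Parent-Child-Union reduces to the ordinary hypergeometric
test against all annotated genes.

Annotations carrying excluded evidence codes (e.g. IEA) are removed
*before* propagation, so no filtered annotation can leak in through an
ancestor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom

from ..errors import ValidationError
from ..service import Payload, parse_gene_list
from ..store import BlobHandle

log = logging.getLogger(__name__)

#: GO namespace labels as they appear in request parameters, mapped to
#: the OBO namespace tags.
NAMESPACES = {
    "Component": "cellular_component",
    "Process": "biological_process",
    "Function": "molecular_function",
}

MESH_ROOT = "MESH:ROOT"


class OntologyDAG:
    """Term DAG with is_a parent links and per-term namespace."""

    def __init__(
        self,
        parents: dict[str, set[str]],
        namespace: dict[str, str] | None = None,
    ):
        self.parents = {t: set(ps) for t, ps in parents.items()}
        self.namespace = dict(namespace or {})
        for term, ps in self.parents.items():
            unknown = ps - self.parents.keys()
            if unknown:
                raise ValidationError(
                    f"term {term} has parents outside the ontology: {sorted(unknown)}"
                )
        graph = nx.DiGraph(
            (child, parent) for child, ps in self.parents.items() for parent in ps
        )
        graph.add_nodes_from(self.parents)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValidationError("ontology contains a cycle")
        self._graph = graph

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    @property
    def roots(self) -> set[str]:
        return {t for t, ps in self.parents.items() if not ps}

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable via parent links (excluding ``term``)."""
        return set(nx.descendants(self._graph, term))

    @classmethod
    def from_obo(cls, path: str | Path) -> "OntologyDAG":
        """Read an OBO 1.2 file, keeping is_a relationships only."""
        graph = obonet.read_obo(path)
        parents: dict[str, set[str]] = {}
        namespace: dict[str, str] = {}
        for node, data in graph.nodes(data=True):
            parents[node] = set(graph.successors(node))  # obonet: child -> parent
            if "namespace" in data:
                namespace[node] = data["namespace"]
        return cls(parents, namespace)


@dataclass
class AnnotationSet:
    """Direct and true-path-propagated gene annotations."""

    direct: dict[int, set[tuple[str, str]]]  # gene -> {(term, evidence)}
    propagated: dict[str, set[int]]          # term -> genes (incl. descendants)

    @property
    def annotated_genes(self) -> set[int]:
        genes: set[int] = set()
        for members in self.propagated.values():
            genes |= members
        return genes


def propagate_annotations(
    dag: OntologyDAG,
    direct: dict[int, set[tuple[str, str]]],
    excluded_evidence: set[str] = frozenset(),
) -> AnnotationSet:
    """Filter by evidence code, then close each gene's terms under
    ancestors (true-path rule).

    Annotations referencing unknown terms are skipped with a warning.
    The result satisfies propagated(t) ⊇ propagated(c) for every child c
    of t."""
    propagated: dict[str, set[int]] = {t: set() for t in dag.terms}
    kept: dict[int, set[tuple[str, str]]] = {}
    for gene, annots in direct.items():
        for term, evidence in annots:
            if evidence in excluded_evidence:
                continue
            if term not in dag.terms:
                log.warning("annotation (%s, %s) references unknown term; skipped", gene, term)
                continue
            kept.setdefault(gene, set()).add((term, evidence))
            propagated[term].add(gene)
            for anc in dag.ancestors(term):
                propagated[anc].add(gene)
    return AnnotationSet(direct=kept, propagated=propagated)


def pcu_pvalue(
    dag: OntologyDAG,
    annotations: AnnotationSet,
    study: set[int],
    term: str,
) -> float | None:
    """Parent-Child-Union p-value for one term, or None if the term must
    be skipped (empty parent background or no study gene in it)."""
    a_t = annotations.propagated.get(term, set())
    parents = dag.parents.get(term, set())
    if parents:
        a_pa: set[int] = set()
        for p in parents:
            a_pa |= annotations.propagated.get(p, set())
    else:
        a_pa = annotations.annotated_genes
    K = len(a_t)
    N = len(a_pa)
    n = len(study & a_pa)
    k = len(study & a_t)
    if N < 1 or n < 1:
        return None
    if k == 0 or K == N:
        return 1.0
    # upper tail: P[X >= k] with X ~ Hypergeom(N, K, n)
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    term: str
    members: list[int]
    p_value: float
    q_value: float | None = None

    def to_row(self) -> dict:
        row = {
            "term": self.term,
            "members": "|".join(str(m) for m in sorted(self.members)),
            "p_value": self.p_value,
        }
        if self.q_value is not None:
            row["q_value"] = self.q_value
        return row


def _rank_and_truncate(
    results: list[EnrichmentResult], max_groups: int, adjust: bool
) -> list[EnrichmentResult]:
    # ties in p break by term ID so truncation is reproducible
    results.sort(key=lambda r: (r.p_value, r.term))
    if adjust and results:
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results[:max_groups]


def go_enrichment(
    dag: OntologyDAG,
    annotations: AnnotationSet,
    study: set[int],
    namespace: str | None = None,
    max_groups: int = 10,
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Ranked Parent-Child-Union enrichment over every qualifying term.

    ``namespace`` is a request-level label (Component/Process/Function)
    or None for all; terms with no study member (k = 0) are not
    reported.  Results are sorted by ascending p (ties by term ID) and
    truncated to ``max_groups``."""
    if namespace is not None:
        if namespace not in NAMESPACES:
            raise ValidationError(
                f"unknown GO type {namespace!r}; expected one of {sorted(NAMESPACES)}"
            )
        wanted = NAMESPACES[namespace]
        terms = [t for t in dag.terms if dag.namespace.get(t) == wanted]
    else:
        terms = list(dag.terms)
    results: list[EnrichmentResult] = []
    for term in sorted(terms):
        members = study & annotations.propagated.get(term, set())
        if not members:
            continue
        p = pcu_pvalue(dag, annotations, study, term)
        if p is None:
            continue
        results.append(EnrichmentResult(term, sorted(members), p))
    return _rank_and_truncate(results, max_groups, adjust)


def flat_dag(terms: set[str]) -> OntologyDAG:
    """Single-root DAG for a flat vocabulary (MeSH): every term's parent
    set is {root}."""
    parents: dict[str, set[str]] = {MESH_ROOT: set()}
    for t in terms:
        parents[t] = {MESH_ROOT}
    return OntologyDAG(parents)


def mesh_enrichment(
    term_genes: dict[str, set[int]],
    study: set[int],
    max_groups: int = 10,
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Enrichment over a flat gene→MeSH mapping.

    Every term hangs off one artificial root, so the Parent-Child-Union
    background is the set of all annotated genes and the test reduces to
    the standard hypergeometric."""
    dag = flat_dag(set(term_genes))
    direct = {
        gene: {(t, "NA")}
        for t, genes in term_genes.items() for gene in genes
    }
    merged: dict[int, set[tuple[str, str]]] = {}
    for t, genes in term_genes.items():
        for gene in genes:
            merged.setdefault(gene, set()).add((t, "NA"))
    annotations = propagate_annotations(dag, merged)
    results: list[EnrichmentResult] = []
    for term in sorted(term_genes):
        members = study & annotations.propagated.get(term, set())
        if not members:
            continue
        p = pcu_pvalue(dag, annotations, study, term)
        if p is None:
            continue
        results.append(EnrichmentResult(term, sorted(members), p))
    return _rank_and_truncate(results, max_groups, adjust)


def load_annotations(path: str | Path) -> dict[int, set[tuple[str, str]]]:
    """Read the GAF-like annotation TSV (gene_id, term, evidence)."""
    df = pd.read_csv(
        path, sep="\t", compression="infer", dtype=str,
        names=["gene_id", "term", "evidence"], comment="#", header=None,
    )
    direct: dict[int, set[tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        direct.setdefault(int(row.gene_id), set()).add((row.term, row.evidence))
    return direct


def parse_evidence_param(raw: str | None) -> set[str]:
    """Parse the underscore-delimited evidence parameter (``_IEA_``)
    into the set of evidence codes to exclude."""
    if not raw:
        return set()
    return {tok for tok in raw.split("_") if tok}


class EnrichService:
    """The goEnrichment / meshEnrichment service over one blob.

    Blob files: ``ontology.obo``, ``annotations.tsv`` (gene, GO term,
    evidence) and ``mesh.tsv`` (gene, MeSH term)."""

    operations = ("goEnrichment", "meshEnrichment")
    ontology_file = "ontology.obo"
    annotation_file = "annotations.tsv"
    mesh_file = "mesh.tsv"

    def __init__(self, adjust: bool = False):
        self.adjust = adjust
        self._loaded: dict[int, tuple[OntologyDAG, dict, dict]] = {}

    def _load(self, blob: BlobHandle):
        cached = self._loaded.get(blob.version_id)
        if cached is not None:
            return cached
        dag = OntologyDAG.from_obo(blob.root_path / self.ontology_file)
        direct = load_annotations(blob.root_path / self.annotation_file)
        mesh: dict[str, set[int]] = {}
        mesh_path = blob.root_path / self.mesh_file
        if mesh_path.exists():
            df = pd.read_csv(
                mesh_path, sep="\t", dtype=str,
                names=["gene_id", "term"], comment="#", header=None,
            )
            for row in df.itertuples(index=False):
                mesh.setdefault(row.term, set()).add(int(row.gene_id))
        self._loaded[blob.version_id] = (dag, direct, mesh)
        return dag, direct, mesh

    def perform(self, operation: str, params: dict[str, str], blob: BlobHandle) -> Payload:
        dag, direct, mesh = self._load(blob)
        study = set(parse_gene_list(params.get("genes", ""), "|"))
        max_groups = int(params.get("max", "10"))
        if operation == "goEnrichment":
            excluded = parse_evidence_param(params.get("evid"))
            annotations = propagate_annotations(dag, direct, excluded)
            results = go_enrichment(
                dag, annotations, study,
                namespace=params.get("type"),
                max_groups=max_groups,
                adjust=self.adjust,
            )
        elif operation == "meshEnrichment":
            results = mesh_enrichment(mesh, study, max_groups, self.adjust)
        else:
            raise ValidationError(f"unhandled operation {operation!r}")
        if not results:
            return [{"diagnostic": "no study gene annotated"}]
        return [r.to_row() for r in results]
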