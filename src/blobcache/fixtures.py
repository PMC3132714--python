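"""Offline test substrate: seeded input generators and an instrumented
mock upstream server.

``generate_fixture`` writes every input format the framework reads —
gzipped gene table, OBO ontology, annotation TSV, interaction TSV,
orthology TSV — as a pure function of a :class:`FixtureSpec`, together
with a ground-truth manifest so tests assert against generated values
rather than hard-coded constants.  ``MockUpstream`` serves those files
over real HTTP with exact hit counting, injectable delays and
fail-after-N fault injection.
"""

from __future__ import annotations

import gzip
import http.server
import json
import random
import string
import threading
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import ValidationError

GENE_HEADER = "tax_id\tGeneID\tSymbol\tchromosome\tstart_position\tdescription"
NAMESPACE_TAGS = ["cellular_component", "biological_process", "molecular_function"]
EVIDENCE_CODES = ["EXP", "IDA", "IMP", "ISS", "TAS"]


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for one deterministic fixture."""

    seed: int = 0
    n_genes: int = 30
    n_terms: int = 12
    dag_depth: int = 4
    annotation_rate: float = 0.8
    iea_fraction: float = 0.3
    n_interactions: int = 20
    n_orthologs: int = 15
    taxon: int = 9606
    target_taxon: int = 10090
    n_namespaces: int = 1

    def validate(self) -> None:
        if not 0 < self.annotation_rate <= 1:
            raise ValidationError("annotation_rate must be in (0, 1]")
        if not 0 <= self.iea_fraction <= 1:
            raise ValidationError("iea_fraction must be in [0, 1]")
        if self.n_terms and self.dag_depth > self.n_terms:
            raise ValidationError("dag_depth cannot exceed n_terms")
        if not 1 <= self.n_namespaces <= 3:
            raise ValidationError("n_namespaces must be 1..3")
        if self.n_terms and self.n_terms < self.n_namespaces:
            raise ValidationError("need at least one term per namespace")


@dataclass
class FixtureManifest:
    """Ground truth for everything generated."""

    genes: list[dict] = field(default_factory=list)
    terms: list[dict] = field(default_factory=list)          # id, namespace, parents
    annotations: list[dict] = field(default_factory=list)    # gene_id, term, evidence
    interactions: list[dict] = field(default_factory=list)   # taxon, gene_a, gene_b
    orthologs: list[dict] = field(default_factory=list)
    mesh: list[dict] = field(default_factory=list)           # gene_id, term

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _symbol(rng: random.Random, used: set[str]) -> str:
    while True:
        sym = "".join(rng.choices(string.ascii_uppercase, k=rng.randint(3, 5))) + str(
            rng.randint(1, 9)
        )
        if sym not in used:
            used.add(sym)
            return sym


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureManifest:
    """Write the full fixture file tree into ``out_dir``.

    Deterministic: the same spec yields byte-identical files.  The gene
    table is gzipped to exercise the decompress-in-staging path.  Every
    cross-file reference (annotation→gene/term, interaction→gene,
    ortholog→gene) resolves within the fixture."""
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    manifest = FixtureManifest()

    # genes ------------------------------------------------------------
    used_symbols: set[str] = set()
    gene_ids = sorted(rng.sample(range(1, 100000), spec.n_genes))
    for gid in gene_ids:
        manifest.genes.append(
            {
                "tax_id": spec.taxon,
                "GeneID": gid,
                "Symbol": _symbol(rng, used_symbols),
                "chromosome": str(rng.randint(1, 22)),
                "start_position": rng.randint(10_000, 200_000_000),
                "description": f"synthetic gene {gid}",
            }
        )
    gene_lines = [GENE_HEADER] + [
        "\t".join(str(g[c]) for c in GENE_HEADER.split("\t"))
        for g in manifest.genes
    ]
    # mtime=0 keeps the gzip container byte-reproducible
    with open(out_dir / "genes.tsv.gz", "wb") as fh:
        with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
            gz.write(("\n".join(gene_lines) + "\n").encode())

    # ontology DAG: one root per namespace, parents drawn among earlier
    # same-namespace terms so the graph is acyclic by construction ------
    namespaces = NAMESPACE_TAGS[: spec.n_namespaces]
    terms_by_ns: dict[str, list[str]] = {ns: [] for ns in namespaces}
    for i in range(spec.n_terms):
        ns = namespaces[i % len(namespaces)]
        term = f"GO:{7000000 + i:07d}"
        earlier = terms_by_ns[ns]
        if not earlier:
            parents: list[str] = []
        else:
            k = min(len(earlier), rng.randint(1, 2))
            parents = sorted(rng.sample(earlier, k))
        terms_by_ns[ns].append(term)
        manifest.terms.append({"id": term, "namespace": ns, "parents": parents})
    obo_lines = ["format-version: 1.2", ""]
    for t in manifest.terms:
        obo_lines += ["[Term]", f"id: {t['id']}", f"name: synthetic term {t['id']}",
                      f"namespace: {t['namespace']}"]
        obo_lines += [f"is_a: {p} ! parent" for p in t["parents"]]
        obo_lines.append("")
    (out_dir / "ontology.obo").write_text("\n".join(obo_lines))

    # annotations -------------------------------------------------------
    if manifest.terms:
        all_terms = [t["id"] for t in manifest.terms]
        for g in manifest.genes:
            if rng.random() >= spec.annotation_rate:
                continue
            for term in rng.sample(all_terms, rng.randint(1, min(3, len(all_terms)))):
                evidence = (
                    "IEA" if rng.random() < spec.iea_fraction
                    else rng.choice(EVIDENCE_CODES)
                )
                manifest.annotations.append(
                    {"gene_id": g["GeneID"], "term": term, "evidence": evidence}
                )
    (out_dir / "annotations.tsv").write_text(
        "".join(f"{a['gene_id']}\t{a['term']}\t{a['evidence']}\n"
                for a in manifest.annotations)
    )

    # flat MeSH-style vocabulary ---------------------------------------
    mesh_terms = [f"D{600 + i:06d}" for i in range(max(spec.n_terms // 2, 0))]
    for g in manifest.genes:
        if mesh_terms and rng.random() < spec.annotation_rate:
            term = rng.choice(mesh_terms)
            manifest.mesh.append({"gene_id": g["GeneID"], "term": term})
    (out_dir / "mesh.tsv").write_text(
        "".join(f"{m['gene_id']}\t{m['term']}\n" for m in manifest.mesh)
    )

    # interactions ------------------------------------------------------
    if spec.n_genes >= 2:
        seen_pairs: set[tuple[int, int]] = set()
        while len(seen_pairs) < min(
            spec.n_interactions, spec.n_genes * (spec.n_genes - 1) // 2
        ):
            a, b = rng.sample(gene_ids, 2)
            pair = (min(a, b), max(a, b))
            if pair not in seen_pairs:
                seen_pairs.add(pair)
                manifest.interactions.append(
                    {"taxon": spec.taxon, "gene_a": pair[0], "gene_b": pair[1]}
                )
    (out_dir / "interactions.tsv").write_text(
        "".join(f"{i['taxon']}\t{i['gene_a']}\t{i['gene_b']}\n"
                for i in manifest.interactions)
    )

    # orthologs ---------------------------------------------------------
    if spec.n_genes:
        for _ in range(spec.n_orthologs):
            src = rng.choice(gene_ids)
            tgt = rng.randint(100000, 200000)
            identity = round(rng.uniform(30.0, 100.0), 2)
            manifest.orthologs.append(
                {
                    "source_taxon": spec.taxon,
                    "source_gene": src,
                    "target_taxon": spec.target_taxon,
                    "target_gene": tgt,
                    "percent_identity": identity,
                }
            )
    (out_dir / "orthologs.tsv").write_text(
        "".join(
            f"{o['source_taxon']}\t{o['source_gene']}\t{o['target_taxon']}"
            f"\t{o['target_gene']}\t{o['percent_identity']}\n"
            for o in manifest.orthologs
        )
    )

    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------
# Instrumented mock upstream


@dataclass
class Route:
    payload: bytes
    status: int = 200
    content_type: str = "application/octet-stream"
    delay: float = 0.0
    fail_after: int | None = None  # serve N successes, then this many 500s... forever


class MockUpstream:
    """Local HTTP server standing in for external web sources.

    ``hit_log`` records one (route, timestamp) entry per served request —
    append-only and exact — so tests can assert precisely how many times
    the proxy reached upstream.  Per-route ``delay`` and ``fail_after``
    knobs drive rollback and interleaving tests."""

    def __init__(self) -> None:
        self.routes: dict[str, Route] = {}
        self.hit_log: list[tuple[str, float]] = []
        self._lock = threading.Lock()
        self._server: http.server.ThreadingHTTPServer | None = None

    # -- route management ----------------------------------------------

    def add_route(
        self,
        path: str,
        payload: bytes,
        status: int = 200,
        content_type: str = "application/octet-stream",
        delay: float = 0.0,
        fail_after: int | None = None,
    ) -> None:
        if not path.startswith("/"):
            path = "/" + path
        self.routes[path] = Route(payload, status, content_type, delay, fail_after)

    def serve_directory(self, directory: str | Path, prefix: str = "/") -> None:
        """Expose every file in ``directory`` at a stable route."""
        directory = Path(directory)
        for p in sorted(directory.iterdir()):
            if p.is_file():
                self.add_route(prefix.rstrip("/") + "/" + p.name, p.read_bytes())

    def hit_count(self, path: str | None = None) -> int:
        with self._lock:
            if path is None:
                return len(self.hit_log)
            if not path.startswith("/"):
                path = "/" + path
            return sum(1 for route, _ in self.hit_log if route == path)

    # -- lifecycle -------------------------------------------------------

    def start(self) -> str:
        upstream = self

        class Handler(http.server.BaseHTTPRequestHandler):
            def log_message(self, *args):  # silence
                pass

            def do_GET(self) -> None:
                path = self.path.split("?", 1)[0]  # query ignored for routing
                route = upstream.routes.get(path)
                with upstream._lock:
                    upstream.hit_log.append((path, time.time()))
                    served = sum(1 for r, _ in upstream.hit_log if r == path)
                if route is None:
                    self.send_error(404)
                    return
                if route.delay:
                    time.sleep(route.delay)
                status = route.status
                if route.fail_after is not None and served > route.fail_after:
                    status = 500
                if status != 200:
                    self.send_error(status)
                    return
                self.send_response(200)
                self.send_header("Content-Type", route.content_type)
                self.send_header("Content-Length", str(len(route.payload)))
                self.end_headers()
                self.wfile.write(route.payload)

        self._server = http.server.ThreadingHTTPServer(("127.0.0.1", 0), Handler)
        threading.Thread(target=self._server.serve_forever, daemon=True).start()
        return self.base_url

    @property
    def base_url(self) -> str:
        assert self._server is not None, "server not started"
        host, port = self._server.server_address[:2]
        return f"http://{host}:{port}"

    def url_for(self, path: str) -> str:
        if not path.startswith("/"):
            path = "/" + path
        return self.base_url + path

    def stop(self) -> None:
        if self._server is not None:
            self._server.shutdown()
            self._server.server_close()
            self._server = None

    def __enter__(self) -> "MockUpstream":
        self.start()
        return self

    def __exit__(self, *exc) -> None:
        self.stop()
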