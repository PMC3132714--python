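# blobcache

Infrastructure for bioinformatics data web services that depend on
upstream resources (NCBI gene tables, GO ontology files, orthology
dumps, dynamic web APIs) which change under them. It addresses two
chronic problems of such services:

1. **Upstream access cost and rate limits.** Repositories like NCBI ban
   IP addresses that exceed a fixed request rate, and a server that
   pools requests from many clients crosses that line easily. The
   `CachingProxy` is a forward proxy that answers repeated requests from
   a persistent local cache (a restart is served entirely from disk) and
   enforces deployer-specified pooled rate limits — a sliding-window log
   per host pattern — on cache misses. A denied call returns a retryable
   failure with a retry hint rather than queueing.

2. **Silently shifting results.** A service whose underlying data is
   re-downloaded periodically returns different answers over time with
   no way to reproduce an earlier response. Here a service answers every
   query from an immutable, version-stamped **data blob**: a read-only
   directory identified by an epoch-millisecond version id, carrying
   per-file provenance (source URL, creation time, size) and a snapshot
   of the configuration metadata in effect when it was built. Rebuilds
   run on a deployer-defined schedule, stage into a hidden directory,
   and become current in one atomic step only if every download and
   computation succeeded; otherwise the previous version is untouched
   and the failure is logged. Every response carries its version id, and
   any retained version can be queried again by `versionIdentifier`,
   byte-for-byte.

Three reference services run on the framework: gene info / symbol /
interactant lookup over NCBI-style gene tables, GO and MeSH term
enrichment, and ortholog lookup with percent identity.

## The enrichment statistic

The GO service uses the Parent-Child-Union test. For a term *t* with
propagated annotation set *A(t)* (true-path rule: a gene annotated to a
term is annotated to all its ancestors), the background is the union of
the parents' annotation sets, A_pa = ∪_{p ∈ parents(t)} A(p) (all
annotated genes when *t* is a root). With K = |A(t)|, N = |A_pa|,
n = |study ∩ A_pa| and k = |study ∩ A(t)|, the group p-value is the
upper-tail hypergeometric probability

```
p = Σ_{i=k}^{min(n,K)}  C(K,i) · C(N−K, n−i) / C(N,n)
```

so p = 1 exactly when k = 0 or K = N. Evidence-code filtering (e.g.
excluding IEA) happens before propagation. MeSH terms are treated as a
flat vocabulary under a single root, which reduces the same test to the
ordinary hypergeometric against all annotated genes. Results are ranked
by ascending p (ties broken by term id) and truncated to the requested
maximum group count.

## Worked example

Generate a synthetic deployment (seeded fixture files served by a local
mock upstream), rebuild a gene-info service through the caching proxy,
and query it:

```python
from blobcache import BlobStore, CachingProxy, RatePolicy, ServiceRequest, handle
from blobcache.fixtures import FixtureSpec, MockUpstream, generate_fixture
from blobcache.scheduler import ServiceConfig, SourceSpec, run_rebuild
from blobcache.schedule import Schedule
from blobcache.services.geneinfo import GeneInfoService

manifest = generate_fixture(FixtureSpec(seed=42), "fixture/")
with MockUpstream() as upstream:
    upstream.serve_directory("fixture/")
    proxy = CachingProxy(policies=[RatePolicy("*", 5, 1.0)])
    store = BlobStore("store/")
    config = ServiceConfig(
        service_name="GeneInfoWS",
        sources=[
            SourceSpec(upstream.url_for("/genes.tsv.gz"), "genes.tsv", decompress=True),
            SourceSpec(upstream.url_for("/interactions.tsv"), "interactions.tsv"),
        ],
        schedule=Schedule.parse("P7D"),
    )
    record = run_rebuild(store, config, lambda staging: None, proxy)
    print(f"committed version {record.version_id} with {len(record.files)} files")

    gene = manifest.genes[0]
    resp = handle(
        ServiceRequest("getInfo", {"sourceSpecies": "9606", "genes": str(gene["GeneID"])}),
        GeneInfoService(), store,
    )
    print(f"version stamp: {resp.version_id}")
    print(resp.payload[0])
```

Output from one run:

```
committed version 1789781783376 with 2 files
version stamp: 1789781783376
{'gene_id': 3279, 'symbol': 'FPVA3', 'taxon': 9606, 'chromosome': '14',
 'start_position': 91345303, 'description': 'synthetic gene 3279'}
```

The version id (epoch milliseconds at commit) stamps every response;
passing `versionIdentifier=1789781783376` in any later request pins the
query to this blob even after newer rebuilds. Deleting the blob store
and rebuilding through the warm proxy cache completes with **zero**
upstream requests — the forced-recovery scenario.

The same services are exposed over HTTP by `blobcache.web.AppServer`
(or `blobcache serve deploy.yaml` from the shell), with query shapes
like:

```
GET /GeneInfoWS?operation=getInfo&sourceSpecies=9606&genes=7157,20,672
GET /EnrichWS?enrichType=goEnrichment&calc=Parent-Child-Union&species=9606
        &genes=1499|7827|2719|5002&max=10&evid=_IEA_&type=Component
GET /ProxyWS/Proxy?url=<absolute upstream URL>
```

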