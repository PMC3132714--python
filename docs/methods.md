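# Methods

## Proxy cache

The forward proxy keys its cache on a normalized URL: the fragment is
removed and everything else — scheme, host, path, query string with its
parameter order and percent-encoding — is preserved byte-for-byte.
Parameter order is deliberately significant: reordering parameters can
change the response of real services, so two orderings are two cache
entries. Normalization is idempotent and rejects relative URLs.

Entries never expire by default. Bulk files of the kind these services
download (weekly gene tables, ontology releases) are refreshed by the
rebuild schedule, not by cache staleness, and an expiring cache would
silently reintroduce upstream traffic on restart. An optional per-host
TTL (`ttl_seconds` on a rate policy) is available for genuinely dynamic
endpoints; `ttl_seconds: 0` forces a refetch on every request.
Failures — upstream errors and rate denials — are never cached, so a
transient outage cannot poison later restarts.

Persistence uses one JSON index plus one body file per entry, named by
the SHA-256 of the cache key. Two small files per entry rather than one
monolithic store means a crash between writes loses at most the entry
being written: a restored index row whose body file is missing is
dropped with a warning, and a missing or corrupt store directory starts
the cache empty instead of failing the service. Eviction, when a
`max_entries` bound is configured, is least-recently-used.

## Rate limiting

Rate limits are enforced with a sliding-window log: one timestamp deque
per policy, an arrival allowed iff every matching policy has strictly
fewer than `max_requests` allowed calls in `(now − window, now]`, and an
allow appended to all matching logs under one lock (so two concurrent
checks cannot both take the last slot). The sliding-window log is exact:
unlike a token bucket it can never admit more than `max_requests` calls
into *any* window of length `window_seconds`, which is the form upstream
bans are expressed in. Denials are surfaced to the client as retryable
failures with a `Retry-After` hint equal to the time until the oldest
in-window call expires — clients retry; nothing is queued server-side.
Denial is decided by the window count, not by whether the hint is
positive: at a window boundary the hint can round to zero in floating
point while the slot is still occupied.

Limits are pooled across all clients of one proxy instance by
construction (one shared log). Two-level caching for a lab sharing an
intranet needs no special code path: a proxy's `fetcher` can be pointed
at another proxy's `fetch`.

## Versioned blob store

A version id is the epoch-millisecond clock reading at commit; if that
would not exceed the previous id (clock skew, two commits within a
millisecond) the id is previous + 1, keeping ids strictly increasing.

The commit sequence is: (1) write the manifest — provenance, metadata
snapshot, per-file SHA-256 checksums — into the staging directory;
(2) `rename(2)` staging to `versions/<id>/`; (3) atomically replace the
small `CURRENT` pointer file. Steps 2 and 3 are atomic on POSIX
filesystems, so a crash anywhere leaves one of exactly three states:
staging only (discarded at next startup), a renamed blob the pointer
never reached (a committed version; `current()` still returns the old
one), or a completed commit. A version directory without a manifest is
by definition partial and is removed at startup. The commit code exposes
a hook between the steps so tests can inject a crash at each boundary
and verify recovery.

Readers pin a version at request start (`resolve()` captures a handle)
and read through that handle for the whole request, so an in-flight
request is unaffected by a concurrent commit or prune — rebuilds never
block the serving path. Pruning (`keep_all`, `keep_last_k`,
`keep_days_d`) skips the current version unconditionally — a retention
rule that nominally excludes it would otherwise take the service down —
and defers pinned versions to a later prune. Metadata is copied by value
into the manifest, so editing the deployment configuration never alters
the history already recorded.

## Scheduler

Schedules are ISO-8601-style durations (`P7D` for the weekly cadence
typical of these deployments, `PT1S` in tests) or 5-field cron
expressions evaluated by scanning minutes in `(last, now]`; the scan is
bounded by the polling interval in practice. A rebuild is due when no
attempt has succeeded yet or the schedule owes one since the last
*attempt* — anchoring on the attempt rather than the success means a
failing upstream is retried at the next scheduled occurrence, not
hammered in a tight loop. Downloads default to going through the proxy,
which is what makes forced recovery (blob store lost, cache warm)
complete with zero upstream requests. Any failure — download, build
routine, commit refusal — aborts the staging area and produces a
structured failure report naming the step and URL; the loop contains
all exceptions and continues.

## Services and the enrichment test

Gene tables are read in two dialects. Genuine NCBI `gene_info` has no
start-coordinate column, so records loaded from it carry an unknown
`start_position` rather than a misreading of `map_location`; the
compact fixture dialect carries the coordinate explicitly. Symbol
lookup is case-insensitive; a symbol mapping to several ids returns all
of them with an ambiguity flag; duplicate (taxon, id) rows keep the last
with a logged warning, and the superseded symbol is unlinked.

The ontology keeps `is_a` parents only (read via obonet), validated
acyclic. True-path propagation runs after evidence filtering, so an
excluded annotation (the `evid=_IEA_` request parameter names codes to
*exclude*, underscore-delimited — the standard enrichment practice)
cannot reach any ancestor. The Parent-Child-Union p-value is the
upper-tail hypergeometric `hypergeom.sf(k−1, N, K, n)` with the
parent-union background; roots use all annotated genes as background,
the standard convention. Terms with an empty background or no study
member in it are skipped; k = 0 and K = N return exactly 1. Raw
p-values are reported by default, matching the "group p-value" contract
of this style of service; Benjamini–Hochberg q-values can be switched
on per service (`EnrichService(adjust=True)`). Ranking is by ascending
p with ties broken by term id, making truncation to `max` reproducible.
MeSH input is a flat gene→term table; hanging every term off one
artificial root makes the same code path compute the ordinary
hypergeometric against all annotated genes.

## Synthetic data

The fixture generator is a pure function of a `FixtureSpec` seed. Its
defaults — 30 genes, 12 ontology terms with one root per namespace and
1–2 parents drawn among earlier same-namespace terms (acyclic by
construction), 80 % of genes annotated with 1–3 terms, 30 % IEA
evidence, 20 interaction pairs, 15 ortholog rows with percent identity
uniform on [30, 100] to two decimals — are sized like a small curated
species slice: large enough to exercise multi-level propagation,
ambiguous and missing lookups, and one-to-many orthology, small enough
that exact-arithmetic oracles stay instant. The gene table is gzipped
(with a fixed mtime, keeping the container byte-reproducible) to
exercise the decompress-in-staging path. A ground-truth manifest of
every generated record accompanies the files, so tests assert against
generated values instead of hard-coded constants.

What the fixtures do not emulate: real NCBI record content and column
quirks beyond the two documented dialects, FTP transport, redirects and
authentication, Gene2MeSH response XML, and annotation biases of real
corpora. Passing tests therefore demonstrate the mechanics — caching,
rate bounds, atomicity, versioned reproducibility, and the correctness
of the statistics on well-formed input — not robustness to every
upstream format drift.

## Numerical and testing choices

The hypergeometric tail is computed in double precision via scipy; the
test oracles recompute it with exact integer binomials (`Fraction`), and
agreement is asserted to 1e-10 — observed deviations are at machine
epsilon for the problem sizes the services handle. Where two terms'
exact p-values differ by less than that tolerance their relative order
under floating point is unspecified, which the acceptance script treats
as a tie. The sliding-window limiter is checked against a brute-force
replay oracle over randomized timestamp sequences, LRU eviction against
a reference list simulation, and propagation against explicit
reachability closure. Timing-based checks (scheduler cadence,
slow-build interleaving) use second-scale schedules so the whole suite
stays fast.

## Known limitations

Serialized state (cache index, manifests, pointer file) assumes a local
POSIX filesystem; the atomicity argument does not transfer to network
filesystems without atomic rename. The proxy only handles GET-style
retrievals — responses of non-idempotent requests are not safely
cacheable. Rate pooling is per proxy instance; several instances in
front of one upstream do not share a window. Cron evaluation is
minute-granular. Only `is_a` ontology edges participate in propagation
(`part_of` is ignored), and only Parent-Child-Union is implemented
among enrichment variants.
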