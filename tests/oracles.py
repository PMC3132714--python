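"""Independent reference implementations used only to check the package.

Each oracle recomputes the quantity from first principles (brute-force
scans, exact rational arithmetic) without touching the code paths it
validates.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def sliding_window_replay(timestamps, max_requests, window_seconds):
    """Replay a timestamp sequence through a brute-force sliding-window
    count: for each arrival, allow iff fewer than ``max_requests``
    previously *allowed* arrivals lie in (t - window, t].  Returns the
    list of booleans (allowed?) per arrival."""
    allowed_times: list[float] = []
    decisions = []
    for t in timestamps:
        in_window = [a for a in allowed_times if t - window_seconds < a <= t]
        ok = len(in_window) < max_requests
        decisions.append(ok)
        if ok:
            allowed_times.append(t)
    return decisions


def window_bound_holds(allowed_times, max_requests, window_seconds):
    """Check every sliding window of length W contains <= r allowed calls
    (windows anchored at each allowed call suffice for the maximum)."""
    times = sorted(allowed_times)
    for i, start in enumerate(times):
        count = sum(1 for t in times if start <= t < start + window_seconds)
        if count > max_requests:
            return False
    return True


def lru_reference(operations, max_entries):
    """Reference LRU: ops are ('put', key) / ('get', key); returns the
    retained key set after evicting down to ``max_entries``."""
    order: list = []  # least recent first
    for op, key in operations:
        if key in order:
            order.remove(key)
            order.append(key)
        elif op == "put":
            order.append(key)
    return set(order[-max_entries:]) if max_entries else set()


def reachable_ancestors(parents, term):
    """Transitive closure over a parents dict, excluding ``term``."""
    seen = set()
    frontier = list(parents.get(term, ()))
    while frontier:
        t = frontier.pop()
        if t not in seen:
            seen.add(t)
            frontier.extend(parents.get(t, ()))
    return seen


def brute_propagate(parents, direct, excluded=frozenset()):
    """Independent true-path propagation: term -> gene set."""
    propagated = {t: set() for t in parents}
    for gene, annots in direct.items():
        for term, evidence in annots:
            if evidence in excluded or term not in parents:
                continue
            propagated[term].add(gene)
            for anc in reachable_ancestors(parents, term):
                propagated[anc].add(gene)
    return propagated


def hypergeom_upper_tail_exact(N, K, n, k):
    """Exact upper-tail hypergeometric via integer binomials."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(n, K) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


def brute_pcu(parents, direct, study, excluded=frozenset()):
    """Independent Parent-Child-Union ranking: (term, p, members) for
    every term with at least one study member, exact arithmetic, sorted
    by (p, term)."""
    propagated = brute_propagate(parents, direct, excluded)
    population = set()
    for members in propagated.values():
        population |= members
    results = []
    for term in parents:
        a_t = propagated[term]
        ps = parents[term]
        a_pa = set()
        if ps:
            for p in ps:
                a_pa |= propagated[p]
        else:
            a_pa = population
        K, N = len(a_t), len(a_pa)
        n = len(study & a_pa)
        k = len(study & a_t)
        members = sorted(study & a_t)
        if not members:
            continue
        if N < 1 or n < 1:
            continue
        if k == 0 or K == N:
            p = Fraction(1)
        else:
            p = hypergeom_upper_tail_exact(N, K, n, k)
        results.append((term, p, members))
    results.sort(key=lambda r: (r[1], r[0]))
    return results
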