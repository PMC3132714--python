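"""Caching, rate-limiting forward proxy for remote data sources.

Repeated requests for the same URL are answered from a persistent local
cache without touching the upstream host; cache misses are subject to
deployer-specified pooled rate limits enforced per host pattern with a
sliding-window log.  Denied calls surface as :class:`RateLimitExceeded`
with a retry hint rather than being queued — clients are expected to
retry.  Failures are never cached.
"""

from __future__ import annotations

import fnmatch
import hashlib
import json
import logging
import threading
import time
import urllib.error
import urllib.parse
import urllib.request
from collections import OrderedDict, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from .errors import RateLimitExceeded, UpstreamError, ValidationError

log = logging.getLogger(__name__)

#: A fetcher maps an absolute URL to (body bytes, content type).
Fetcher = Callable[[str], tuple[bytes, str]]


def normalize_key(url: str) -> str:
    """Normalize ``url`` into a deterministic cache key.

    The fragment is stripped; everything else — including query-parameter
    order and percent-encoding — is preserved byte-for-byte, so two URLs
    that differ only in fragment share a key while reordered parameters
    do not.  Idempotent: normalizing a key returns the key unchanged.

    Raises :class:`ValidationError` for relative or schemeless URLs.
    """
    try:
        parts = urllib.parse.urlsplit(url)
    except ValueError as exc:
        raise ValidationError(f"malformed URL {url!r}: {exc}") from exc
    if not parts.scheme or not parts.netloc:
        raise ValidationError(f"URL must be absolute: {url!r}")
    return urllib.parse.urlunsplit(
        (parts.scheme, parts.netloc, parts.path, parts.query, "")
    )


def host_of(url: str) -> str:
    """Extract the (lowercased) hostname from an absolute URL."""
    host = urllib.parse.urlsplit(url).hostname
    if host is None:
        raise ValidationError(f"URL has no host: {url!r}")
    return host.lower()


@dataclass(frozen=True)
class RatePolicy:
    """Pooled rate constraint: at most ``max_requests`` remote calls to
    hosts matching ``host_pattern`` (a glob) in any sliding window of
    ``window_seconds``, across all clients of this proxy.

    ``ttl_seconds`` optionally expires cached entries for matching hosts;
    the default (``None``) caches indefinitely.
    """

    host_pattern: str
    max_requests: int
    window_seconds: float
    ttl_seconds: float | None = None

    def __post_init__(self) -> None:
        if self.max_requests < 1:
            raise ValidationError("max_requests must be a positive integer")
        if self.window_seconds <= 0:
            raise ValidationError("window_seconds must be positive")

    def matches(self, host: str) -> bool:
        return fnmatch.fnmatch(host.lower(), self.host_pattern.lower())


@dataclass
class CacheEntry:
    """One cached remote response."""

    key: str
    body: bytes
    content_type: str
    fetched_at: float  # UTC epoch seconds
    source_url: str

    @property
    def byte_size(self) -> int:
        return len(self.body)


@dataclass
class ProxyResponse:
    """What the proxy hands back for one request."""

    body: bytes
    content_type: str
    from_cache: bool
    fetched_at: float


class SlidingWindowLimiter:
    """Sliding-window log rate limiter pooled across clients.

    One timestamp deque per policy; an allow atomically consumes a slot
    in every matching policy, so no two concurrent checks can both take
    the last slot.
    """

    def __init__(self, policies: list[RatePolicy]):
        self.policies = list(policies)
        self._logs: dict[int, deque[float]] = {
            i: deque() for i in range(len(self.policies))
        }
        self._lock = threading.Lock()

    def check(self, host: str, now: float) -> None:
        """Consume one slot for ``host`` at time ``now`` or raise
        :class:`RateLimitExceeded` (nothing is consumed on denial)."""
        with self._lock:
            matching = [
                (i, p) for i, p in enumerate(self.policies) if p.matches(host)
            ]
            denied = False
            retry_after = 0.0
            for i, policy in matching:
                window_log = self._logs[i]
                while window_log and window_log[0] <= now - policy.window_seconds:
                    window_log.popleft()
                if len(window_log) >= policy.max_requests:
                    denied = True
                    # time until the oldest in-window call expires
                    retry_after = max(
                        retry_after, window_log[0] + policy.window_seconds - now
                    )
            if denied:
                raise RateLimitExceeded(host, max(retry_after, 0.0))
            for i, _ in matching:
                self._logs[i].append(now)


def _default_fetcher(url: str) -> tuple[bytes, str]:
    try:
        with urllib.request.urlopen(url, timeout=30) as resp:
            body = resp.read()
            ctype = resp.headers.get("Content-Type", "application/octet-stream")
            status = getattr(resp, "status", 200)
    except urllib.error.HTTPError as exc:
        raise UpstreamError(url, f"HTTP {exc.code}", status=exc.code) from exc
    except (urllib.error.URLError, OSError) as exc:
        raise UpstreamError(url, str(exc)) from exc
    if not 200 <= status < 300:
        raise UpstreamError(url, f"HTTP {status}", status=status)
    return body, ctype


class CachingProxy:
    """Forward proxy with persistent LRU cache and pooled rate limiting.

    Parameters
    ----------
    policies:
        Rate (and optional TTL) constraints per upstream host pattern.
    cache_dir:
        If given, the cache is restored from here at construction and
        every stored entry is persisted here immediately (so a restart
        answers previously seen URLs with zero upstream calls).
    max_entries:
        If given, least-recently-used entries are evicted past this size.
    fetcher:
        Injectable upstream accessor, ``url -> (body, content_type)``.
        Defaults to a urllib GET.  Pointing it at another proxy's fetch
        gives two-level caching with no special code path.
    clock:
        Injectable time source (UTC epoch seconds), for tests.
    """

    def __init__(
        self,
        policies: list[RatePolicy] | None = None,
        cache_dir: str | Path | None = None,
        max_entries: int | None = None,
        fetcher: Fetcher = _default_fetcher,
        clock: Callable[[], float] = time.time,
    ):
        self.policies = list(policies or [])
        self.limiter = SlidingWindowLimiter(self.policies)
        self.max_entries = max_entries
        self.fetcher = fetcher
        self.clock = clock
        self._cache: OrderedDict[str, CacheEntry] = OrderedDict()
        self._lock = threading.RLock()
        self.cache_dir = Path(cache_dir) if cache_dir is not None else None
        if self.cache_dir is not None:
            self.restore(self.cache_dir)

    # -- cache mechanics ------------------------------------------------

    def __len__(self) -> int:
        return len(self._cache)

    def __contains__(self, url: str) -> bool:
        return normalize_key(url) in self._cache

    def _ttl_for(self, host: str) -> float | None:
        ttls = [
            p.ttl_seconds
            for p in self.policies
            if p.matches(host) and p.ttl_seconds is not None
        ]
        return min(ttls) if ttls else None

    def rate_check(self, host: str, now: float | None = None) -> None:
        """Consume a rate slot for a cache-miss call to ``host`` or raise
        :class:`RateLimitExceeded`.  Hosts matching no policy are
        unconstrained."""
        self.limiter.check(host, self.clock() if now is None else now)

    def fetch(self, url: str, now: float | None = None) -> ProxyResponse:
        """Return the response for ``url``, from cache when possible.

        A cache hit makes zero remote calls.  A miss consumes a rate slot
        (raising :class:`RateLimitExceeded` on denial), performs the
        remote call, and caches the byte-identical response.  Upstream
        failures propagate as :class:`UpstreamError` and are never cached.
        """
        key = normalize_key(url)
        now = self.clock() if now is None else now
        host = host_of(url)
        with self._lock:
            entry = self._cache.get(key)
            if entry is not None:
                ttl = self._ttl_for(host)
                if ttl is not None and now - entry.fetched_at > ttl:
                    log.info("cache expire key=%s age=%.1fs", key, now - entry.fetched_at)
                    del self._cache[key]
                    entry = None
            if entry is not None:
                self._cache.move_to_end(key)
                log.info("cache hit key=%s bytes=%d", key, entry.byte_size)
                return ProxyResponse(
                    body=entry.body,
                    content_type=entry.content_type,
                    from_cache=True,
                    fetched_at=entry.fetched_at,
                )
        # miss: rate check, then remote call outside the cache lock
        try:
            self.rate_check(host, now)
        except RateLimitExceeded as exc:
            log.warning("rate deny host=%s retry_after=%.3f", host, exc.retry_after)
            raise
        log.info("remote call url=%s", url)
        body, content_type = self.fetcher(url)
        entry = CacheEntry(
            key=key, body=body, content_type=content_type,
            fetched_at=now, source_url=url,
        )
        with self._lock:
            self._cache[key] = entry
            self._cache.move_to_end(key)
            if self.cache_dir is not None:
                self._persist_entry(self.cache_dir, entry)
            if self.max_entries is not None:
                self.evict(self.max_entries)
        return ProxyResponse(
            body=body, content_type=content_type,
            from_cache=False, fetched_at=now,
        )

    def evict(self, max_entries: int) -> list[str]:
        """Drop least-recently-used entries until size <= ``max_entries``;
        returns the removed keys."""
        removed: list[str] = []
        with self._lock:
            while len(self._cache) > max_entries:
                key, _ = self._cache.popitem(last=False)
                removed.append(key)
                log.info("evict key=%s", key)
                if self.cache_dir is not None:
                    self._body_path(self.cache_dir, key).unlink(missing_ok=True)
            if removed and self.cache_dir is not None:
                self._write_index(self.cache_dir)
        return removed

    # -- persistence ----------------------------------------------------
    #
    # Layout: <dir>/index.json (metadata for every entry) plus one body
    # file per entry named by a digest of the key.  Content-addressed
    # bodies keep a crash between the two writes recoverable: an index
    # entry whose body file is missing is dropped with a warning.

    @staticmethod
    def _body_path(directory: Path, key: str) -> Path:
        digest = hashlib.sha256(key.encode("utf-8")).hexdigest()
        return directory / "bodies" / digest

    def _write_index(self, directory: Path) -> None:
        index = [
            {
                "key": e.key,
                "content_type": e.content_type,
                "fetched_at": e.fetched_at,
                "source_url": e.source_url,
                "byte_size": e.byte_size,
            }
            for e in self._cache.values()
        ]
        tmp = directory / "index.json.tmp"
        tmp.write_text(json.dumps(index, indent=1))
        tmp.replace(directory / "index.json")

    def _persist_entry(self, directory: Path, entry: CacheEntry) -> None:
        directory.mkdir(parents=True, exist_ok=True)
        body_path = self._body_path(directory, entry.key)
        body_path.parent.mkdir(parents=True, exist_ok=True)
        body_path.write_bytes(entry.body)
        self._write_index(directory)

    def persist(self, directory: str | Path | None = None) -> None:
        """Write the whole cache (bodies + index) to ``directory``."""
        directory = Path(directory) if directory is not None else self.cache_dir
        if directory is None:
            raise ValidationError("no persistence directory configured")
        directory.mkdir(parents=True, exist_ok=True)
        with self._lock:
            for entry in self._cache.values():
                body_path = self._body_path(directory, entry.key)
                body_path.parent.mkdir(parents=True, exist_ok=True)
                body_path.write_bytes(entry.body)
            self._write_index(directory)

    def restore(self, directory: str | Path) -> int:
        """Load cache state previously written by :meth:`persist`.

        A missing or corrupt store never crashes the service: the cache
        simply starts empty with a logged warning.  Returns the number of
        entries restored."""
        directory = Path(directory)
        index_path = directory / "index.json"
        if not index_path.exists():
            if directory.exists():
                log.warning("cache store %s has no index; starting empty", directory)
            else:
                log.warning("cache store %s does not exist; starting empty", directory)
            return 0
        try:
            index = json.loads(index_path.read_text())
        except (OSError, json.JSONDecodeError) as exc:
            log.warning("cache index %s unreadable (%s); starting empty", index_path, exc)
            return 0
        restored = 0
        with self._lock:
            for meta in index:
                body_path = self._body_path(directory, meta["key"])
                try:
                    body = body_path.read_bytes()
                except OSError:
                    log.warning("cache body missing for key=%s; dropped", meta["key"])
                    continue
                self._cache[meta["key"]] = CacheEntry(
                    key=meta["key"],
                    body=body,
                    content_type=meta["content_type"],
                    fetched_at=meta["fetched_at"],
                    source_url=meta["source_url"],
                )
                restored += 1
        return restored
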