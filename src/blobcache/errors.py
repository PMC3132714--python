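"""Exception hierarchy shared across the framework."""

from __future__ import annotations


class BlobcacheError(Exception):
    """Base class for all framework errors."""


class ValidationError(BlobcacheError):
    """Malformed input (URL, gene list, config value...)."""


class RateLimitExceeded(BlobcacheError):
    """A pooled rate policy denied a remote call; the client should retry.

    ``retry_after`` is the number of seconds until the oldest in-window
    call falls out of the sliding window, i.e. the earliest time a retry
    can succeed.
    """

    def __init__(self, host: str, retry_after: float):
        self.host = host
        self.retry_after = retry_after
        super().__init__(
            f"rate limit exceeded for host {host!r}; retry after {retry_after:.3f}s"
        )


class UpstreamError(BlobcacheError):
    """The remote source was unreachable or returned a non-success status."""

    def __init__(self, url: str, reason: str, status: int | None = None):
        self.url = url
        self.reason = reason
        self.status = status
        super().__init__(f"upstream error for {url}: {reason}")


class BuildInProgressError(BlobcacheError):
    """A second begin_build was attempted while one staging area is active."""


class CommitRefusedError(BlobcacheError):
    """Commit preconditions failed (e.g. a declared file is missing)."""


class VersionNotFoundError(BlobcacheError):
    """An unknown version identifier was requested."""

    def __init__(self, version_id: int, available: list[int]):
        self.version_id = version_id
        self.available = available
        super().__init__(
            f"version {version_id} not found; available: {available}"
        )


class VersionGoneError(BlobcacheError):
    """The requested version existed once but has been pruned."""


class NoCommittedVersionError(BlobcacheError):
    """The service has no committed data blob yet (service unavailable)."""


class UnknownOperationError(BlobcacheError):
    """The request named an operation the service does not implement."""

    def __init__(self, operation: str, supported: list[str]):
        self.operation = operation
        self.supported = sorted(supported)
        super().__init__(
            f"unknown operation {operation!r}; supported: {self.supported}"
        )


class UnsupportedFormatError(BlobcacheError):
    """The requested output format is not configured for this service."""

    def __init__(self, fmt: str, supported: list[str]):
        self.format = fmt
        self.supported = sorted(supported)
        super().__init__(
            f"unsupported format {fmt!r}; supported: {self.supported}"
        )
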