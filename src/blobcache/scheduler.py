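"""Periodic rebuild driver.

A rebuild downloads every declared source into a staging area (through
the caching proxy by default, so a forced recovery after losing the blob
store is satisfied from cache), runs the service's build routine, and
commits the result as a new immutable version — or aborts, logging the
failing source or step and leaving the previous version untouched.
Rebuilds run off the request path: readers keep using their pinned
current version throughout.
"""

from __future__ import annotations

import gzip
import logging
import threading
import time
import traceback
from dataclasses import dataclass, field
from pathlib import PurePosixPath
from typing import Callable

from .errors import ValidationError
from .proxy import CachingProxy, Fetcher, _default_fetcher
from .schedule import Schedule
from .store import BlobStore, FileProvenance, Retention, StagingHandle, VersionRecord

log = logging.getLogger(__name__)

#: A builder receives the staging handle (sources already downloaded) and
#: creates whatever derived files/structures the service needs.  It may
#: return a list of the file names it created; None means "scan staging".
Builder = Callable[[StagingHandle], list[str] | None]


def _check_safe_relative(name: str) -> str:
    p = PurePosixPath(name)
    if p.is_absolute() or ".." in p.parts or name.strip() == "":
        raise ValidationError(f"unsafe relative target name: {name!r}")
    return name


@dataclass(frozen=True)
class SourceSpec:
    """One external data source to download into the blob."""

    url: str
    target_name: str
    via_proxy: bool = True
    decompress: bool = False

    def __post_init__(self) -> None:
        _check_safe_relative(self.target_name)


@dataclass
class ServiceConfig:
    """Declarative configuration for one rebuildable service."""

    service_name: str
    sources: list[SourceSpec]
    schedule: Schedule
    retention: Retention = field(default_factory=Retention.keep_all)
    metadata: dict[str, str] = field(default_factory=dict)
    output_formats: list[str] = field(default_factory=lambda: ["xml", "csv", "tsv", "json"])

    def __post_init__(self) -> None:
        if not self.output_formats:
            raise ValidationError("at least one output format is required")


@dataclass
class FailureReport:
    """Why a rebuild attempt produced no new version."""

    service_name: str
    step: str          # download | build | commit
    detail: str
    url: str | None = None


def due(config: ServiceConfig, last_success: float | None, now: float) -> bool:
    """Is a rebuild due for ``config``?  True when no build has ever
    succeeded, or the schedule says one is owed since ``last_success``."""
    return config.schedule.due(last_success, now)


def run_rebuild(
    store: BlobStore,
    config: ServiceConfig,
    builder: Builder,
    proxy: CachingProxy | None = None,
    fetcher: Fetcher = _default_fetcher,
) -> VersionRecord | FailureReport:
    """Attempt one complete rebuild: download, build, commit.

    All-or-nothing: any failure (download, builder exception, commit
    refusal) aborts the staging area, logs the failing source or step,
    and leaves the current version untouched.  Sources with
    ``via_proxy=True`` go through ``proxy`` (which must then be given),
    so a warm cache rebuilds with zero upstream hits."""
    staging = store.begin_build()
    now = store.clock()
    provenance: list[FileProvenance] = []
    try:
        for src in config.sources:
            if src.via_proxy:
                if proxy is None:
                    raise ValidationError(
                        f"source {src.url} declares via_proxy but no proxy was given"
                    )
                resp = proxy.fetch(src.url)
                body = resp.body
            else:
                body, _ = fetcher(src.url)
            if src.decompress:
                body = gzip.decompress(body)
            staging.write_bytes(src.target_name, body)
            provenance.append(
                FileProvenance(src.target_name, src.url, now, len(body))
            )
    except Exception as exc:
        failing = src.url if config.sources else None
        log.error(
            "rebuild of %s failed during download of %s: %s",
            config.service_name, failing, exc,
        )
        store.abort(staging)
        return FailureReport(config.service_name, "download", str(exc), url=failing)

    try:
        derived = builder(staging)
    except Exception as exc:
        log.error(
            "rebuild of %s failed in build routine: %s\n%s",
            config.service_name, exc, traceback.format_exc(),
        )
        store.abort(staging)
        return FailureReport(config.service_name, "build", str(exc))

    if derived is None:
        declared = {p.file_name for p in provenance}
        derived = sorted(
            str(p.relative_to(staging.root_path))
            for p in staging.root_path.rglob("*")
            if p.is_file() and str(p.relative_to(staging.root_path)) not in declared
        )
    for name in derived:
        provenance.append(
            FileProvenance(
                name, "", store.clock(),
                (staging.root_path / name).stat().st_size,
            )
        )

    try:
        record = store.commit(staging, files=provenance, metadata=config.metadata)
    except Exception as exc:
        log.error("rebuild of %s failed at commit: %s", config.service_name, exc)
        return FailureReport(config.service_name, "commit", str(exc))
    store.prune(config.retention)
    return record


class Scheduler:
    """Background loop evaluating schedules and running rebuilds.

    One daemon thread polls every ``tick_seconds``; each due service is
    rebuilt in-line on that thread (request handling lives elsewhere and
    never blocks on it).  Rebuild failures are contained and logged; a
    failed attempt waits for the next scheduled occurrence rather than
    retrying immediately."""

    def __init__(
        self,
        entries: list[tuple[ServiceConfig, BlobStore, Builder]],
        proxy: CachingProxy | None = None,
        fetcher: Fetcher = _default_fetcher,
        tick_seconds: float = 0.2,
        clock: Callable[[], float] = time.time,
    ):
        self.entries = list(entries)
        self.proxy = proxy
        self.fetcher = fetcher
        self.tick_seconds = tick_seconds
        self.clock = clock
        self.last_success: dict[str, float] = {}
        self.last_attempt: dict[str, float] = {}
        self.failures: list[FailureReport] = []
        self._stop = threading.Event()
        self._thread: threading.Thread | None = None

    def run_due(self) -> int:
        """Run one rebuild for every service that is currently due;
        returns the number of successful commits."""
        committed = 0
        for config, store, builder in self.entries:
            now = self.clock()
            # anchor on the last *attempt*: a failed rebuild waits for the
            # next scheduled occurrence instead of retrying immediately
            anchor = self.last_attempt.get(config.service_name)
            if not due(config, anchor, now):
                continue
            self.last_attempt[config.service_name] = now
            try:
                result = run_rebuild(store, config, builder, self.proxy, self.fetcher)
            except Exception as exc:  # defensive: run_rebuild reports, not raises
                log.error("unexpected scheduler error for %s: %s", config.service_name, exc)
                self.failures.append(
                    FailureReport(config.service_name, "scheduler", str(exc))
                )
                continue
            if isinstance(result, FailureReport):
                self.failures.append(result)
            else:
                self.last_success[config.service_name] = now
                committed += 1
        return committed

    def _loop(self) -> None:
        while not self._stop.is_set():
            try:
                self.run_due()
            except Exception as exc:  # the loop must survive anything
                log.error("scheduler loop error: %s", exc)
            self._stop.wait(self.tick_seconds)

    def start(self) -> None:
        self._stop.clear()
        self._thread = threading.Thread(target=self._loop, daemon=True)
        self._thread.start()

    def stop(self) -> None:
        self._stop.set()
        if self._thread is not None:
            self._thread.join()
            self._thread = None

    def run_for(self, seconds: float) -> None:
        """Run the loop in the foreground for a fixed duration."""
        self.start()
        try:
            time.sleep(seconds)
        finally:
            self.stop()
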