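"""Immutable, version-stamped data-blob store with atomic current swap.

A rebuildable service answers every query from a read-only *data blob*:
a directory of files identified by an epoch-millisecond version id.
Rebuilds stage into a hidden directory and become visible in one atomic
step (directory rename + current-pointer replace, both atomic on POSIX),
so readers always observe some fully committed version.  Older versions
are retained per a deployer retention rule; every blob carries per-file
provenance (source URL, creation time, size) and a by-value snapshot of
the configuration metadata in effect when it was built.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

from .errors import (
    BuildInProgressError,
    CommitRefusedError,
    NoCommittedVersionError,
    VersionGoneError,
    VersionNotFoundError,
)

log = logging.getLogger(__name__)

MANIFEST_NAME = "MANIFEST.json"
CURRENT_NAME = "CURRENT"


@dataclass(frozen=True)
class FileProvenance:
    """Provenance for one file inside a blob.

    ``source_url`` is empty for files derived by the build routine rather
    than downloaded."""

    file_name: str
    source_url: str
    created_at: float
    byte_size: int

    def to_dict(self) -> dict:
        return {
            "file_name": self.file_name,
            "source_url": self.source_url,
            "created_at": self.created_at,
            "byte_size": self.byte_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FileProvenance":
        return cls(d["file_name"], d["source_url"], d["created_at"], d["byte_size"])


@dataclass
class VersionRecord:
    """One committed (or pruned) blob version."""

    version_id: int
    created_at: float
    files: list[FileProvenance]
    metadata: dict[str, str]
    status: str = "committed"  # building | committed | pruned
    checksums: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "version_id": self.version_id,
            "created_at": self.created_at,
            "files": [f.to_dict() for f in self.files],
            "metadata": self.metadata,
            "status": self.status,
            "checksums": self.checksums,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VersionRecord":
        return cls(
            version_id=d["version_id"],
            created_at=d["created_at"],
            files=[FileProvenance.from_dict(f) for f in d["files"]],
            metadata=dict(d["metadata"]),
            status=d.get("status", "committed"),
            checksums=dict(d.get("checksums", {})),
        )


class BlobHandle:
    """A pinned reference to one blob version.

    A request captures its handle once (at request start) and reads
    through it for the whole request, so concurrent commits and prunes
    cannot disturb it.  Usable as a context manager; ``release()`` (or
    exiting the context) unpins."""

    def __init__(self, store: "BlobStore", version_id: int, root_path: Path):
        self._store = store
        self.version_id = version_id
        self.root_path = root_path
        self._released = False

    def path(self, name: str = "") -> Path:
        return self.root_path / name if name else self.root_path

    def read_bytes(self, name: str) -> bytes:
        return (self.root_path / name).read_bytes()

    def record(self) -> VersionRecord:
        return self._store._load_manifest(self.version_id)

    def release(self) -> None:
        if not self._released:
            self._released = True
            self._store._unpin(self.version_id)

    def __enter__(self) -> "BlobHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.release()


class StagingHandle:
    """Writable staging area for a build in progress; invisible to readers."""

    def __init__(self, store: "BlobStore", root_path: Path):
        self._store = store
        self.root_path = root_path
        self.active = True

    def path(self, name: str = "") -> Path:
        return self.root_path / name if name else self.root_path

    def write_bytes(self, name: str, data: bytes) -> Path:
        target = self.root_path / name
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_bytes(data)
        return target


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# Retention rules ------------------------------------------------------

@dataclass(frozen=True)
class Retention:
    """Deployer retention rule: keep all versions, the last k, or those
    younger than d days.  The current version is always kept."""

    kind: str  # keep_all | keep_last_k | keep_days_d
    value: float | None = None

    @classmethod
    def keep_all(cls) -> "Retention":
        return cls("keep_all")

    @classmethod
    def keep_last(cls, k: int) -> "Retention":
        if k < 1:
            raise ValueError("keep_last requires k >= 1")
        return cls("keep_last_k", k)

    @classmethod
    def keep_days(cls, d: float) -> "Retention":
        if d < 0:
            raise ValueError("keep_days requires d >= 0")
        return cls("keep_days_d", d)

    @classmethod
    def parse(cls, text: str) -> "Retention":
        """Parse 'keep_all', 'keep_last_k=3' or 'keep_days_d=30'."""
        text = text.strip()
        if text == "keep_all":
            return cls.keep_all()
        if "=" in text:
            key, _, val = text.partition("=")
            if key.strip() == "keep_last_k":
                return cls.keep_last(int(val))
            if key.strip() == "keep_days_d":
                return cls.keep_days(float(val))
        raise ValueError(f"unrecognized retention rule: {text!r}")


class BlobStore:
    """Filesystem-backed store of immutable version blobs for one service.

    Layout under ``root``::

        versions/<version_id>/...   committed blobs (incl. MANIFEST.json)
        staging/                    the single in-progress build, if any
        CURRENT                     small pointer file naming the current id

    Commit sequence: manifest written into staging -> staging renamed to
    ``versions/<id>`` -> CURRENT atomically replaced.  Both filesystem
    steps are atomic, so recovery after a crash is simply re-opening the
    store: a leftover staging directory is discarded, a renamed-but-not-
    current blob is a committed version the pointer never reached.
    """

    def __init__(self, root: str | Path, clock: Callable[[], float] = time.time):
        self.root = Path(root)
        self.clock = clock
        self.root.mkdir(parents=True, exist_ok=True)
        self.versions_dir = self.root / "versions"
        self.versions_dir.mkdir(exist_ok=True)
        self._lock = threading.RLock()
        self._pins: dict[int, int] = {}
        self._pruned: set[int] = set()
        self._staging: StagingHandle | None = None
        # test hook, called between commit steps; raising simulates a crash
        self._crash_hook: Callable[[str], None] | None = None
        self._recover()

    # -- recovery / directory scanning ---------------------------------

    def _staging_dir(self) -> Path:
        return self.root / "staging"

    def _recover(self) -> None:
        staging = self._staging_dir()
        if staging.exists():
            log.warning("discarding stale staging area from interrupted build")
            shutil.rmtree(staging)
        # a version directory without a manifest is a partial blob: remove
        for d in self.versions_dir.iterdir():
            if d.is_dir() and not (d / MANIFEST_NAME).exists():
                log.warning("removing partial version directory %s", d.name)
                shutil.rmtree(d)

    def _committed_ids(self) -> list[int]:
        ids = []
        for d in self.versions_dir.iterdir():
            if d.is_dir() and (d / MANIFEST_NAME).exists():
                try:
                    ids.append(int(d.name))
                except ValueError:
                    continue
        return sorted(ids)

    def _load_manifest(self, version_id: int) -> VersionRecord:
        path = self.versions_dir / str(version_id) / MANIFEST_NAME
        return VersionRecord.from_dict(json.loads(path.read_text()))

    # -- build lifecycle ------------------------------------------------

    def begin_build(self) -> StagingHandle:
        """Open the (single) writable staging area; a second call before
        commit/abort raises :class:`BuildInProgressError`."""
        with self._lock:
            if self._staging is not None and self._staging.active:
                raise BuildInProgressError("a build is already in progress")
            staging = self._staging_dir()
            if staging.exists():
                shutil.rmtree(staging)
            staging.mkdir()
            self._staging = StagingHandle(self, staging)
            return self._staging

    def abort(self, staging: StagingHandle) -> None:
        """Discard the staging area entirely; committed versions and the
        current pointer are untouched and the build lock is released."""
        with self._lock:
            staging.active = False
            if staging.root_path.exists():
                shutil.rmtree(staging.root_path)
            if self._staging is staging:
                self._staging = None
            log.info("build aborted; staging discarded")

    def _next_version_id(self) -> int:
        ids = self._committed_ids()
        candidate = int(self.clock() * 1000)
        if ids and candidate <= ids[-1]:
            candidate = ids[-1] + 1  # clock skew / sub-ms commits
        return candidate

    def _crash(self, step: str) -> None:
        if self._crash_hook is not None:
            self._crash_hook(step)

    def commit(
        self,
        staging: StagingHandle,
        files: list[FileProvenance] | None = None,
        metadata: dict[str, str] | None = None,
    ) -> VersionRecord:
        """Atomically promote ``staging`` to the new current version.

        ``files`` declares per-file provenance; omitted files get derived
        provenance (empty source) computed by scanning staging.  A
        declared file missing from staging refuses the commit and
        discards staging, leaving the current version unchanged."""
        with self._lock:
            if not staging.active:
                raise CommitRefusedError("staging already committed or aborted")
            present = {
                str(p.relative_to(staging.root_path))
                for p in staging.root_path.rglob("*")
                if p.is_file()
            }
            if files is None:
                now = self.clock()
                files = [
                    FileProvenance(
                        name, "", now,
                        (staging.root_path / name).stat().st_size,
                    )
                    for name in sorted(present)
                ]
            missing = [f.file_name for f in files if f.file_name not in present]
            if missing:
                self.abort(staging)
                raise CommitRefusedError(f"declared files missing from staging: {missing}")

            version_id = self._next_version_id()
            created_at = self.clock()
            checksums = {
                name: _sha256_file(staging.root_path / name)
                for name in sorted(present)
            }
            record = VersionRecord(
                version_id=version_id,
                created_at=created_at,
                files=files,
                metadata=dict(metadata or {}),
                status="committed",
                checksums=checksums,
            )
            # step 1: manifest into staging
            (staging.root_path / MANIFEST_NAME).write_text(
                json.dumps(record.to_dict(), indent=1)
            )
            self._crash("after_manifest")
            # step 2: atomic rename into versions/<id>
            target = self.versions_dir / str(version_id)
            staging.root_path.rename(target)
            self._crash("after_rename")
            # step 3: atomic replace of the current pointer
            self._write_current(version_id)
            staging.active = False
            self._staging = None
            log.info("committed version %d (%d files)", version_id, len(files))
            return record

    def _write_current(self, version_id: int) -> None:
        tmp = self.root / (CURRENT_NAME + ".tmp")
        tmp.write_text(str(version_id))
        tmp.replace(self.root / CURRENT_NAME)

    def _read_current(self) -> int | None:
        path = self.root / CURRENT_NAME
        if not path.exists():
            return None
        try:
            vid = int(path.read_text().strip())
        except ValueError:
            return None
        return vid if (self.versions_dir / str(vid) / MANIFEST_NAME).exists() else None

    # -- read path -------------------------------------------------------

    def _pin(self, version_id: int) -> None:
        self._pins[version_id] = self._pins.get(version_id, 0) + 1

    def _unpin(self, version_id: int) -> None:
        with self._lock:
            n = self._pins.get(version_id, 0) - 1
            if n <= 0:
                self._pins.pop(version_id, None)
            else:
                self._pins[version_id] = n

    def current(self) -> BlobHandle:
        """Pinned handle to the current version; raises
        :class:`NoCommittedVersionError` if nothing is committed yet."""
        with self._lock:
            vid = self._read_current()
            if vid is None:
                ids = self._committed_ids()
                if not ids:
                    raise NoCommittedVersionError("no committed version")
                vid = ids[-1]
            self._pin(vid)
            return BlobHandle(self, vid, self.versions_dir / str(vid))

    def resolve(self, version_id: int | None = None) -> BlobHandle:
        """Pinned handle to ``version_id``; ``None`` means current.

        Unknown ids raise :class:`VersionNotFoundError` listing what is
        available; pruned ids raise :class:`VersionGoneError`."""
        if version_id is None:
            return self.current()
        with self._lock:
            target = self.versions_dir / str(version_id)
            if not (target / MANIFEST_NAME).exists():
                if version_id in self._pruned:
                    raise VersionGoneError(f"version {version_id} has been pruned")
                raise VersionNotFoundError(version_id, self._committed_ids())
            self._pin(version_id)
            return BlobHandle(self, version_id, target)

    def list_versions(self) -> list[VersionRecord]:
        """All committed, unpruned versions, newest first."""
        with self._lock:
            return [self._load_manifest(vid) for vid in reversed(self._committed_ids())]

    # -- retention -------------------------------------------------------

    def prune(self, retention: Retention) -> list[int]:
        """Remove versions outside the retention rule.

        The current version and any version with pinned readers always
        survive (pinned ones are simply deferred to a later prune).
        Returns the pruned version ids."""
        pruned: list[int] = []
        with self._lock:
            ids = self._committed_ids()
            if not ids:
                return pruned
            current_id = self._read_current() or ids[-1]
            if retention.kind == "keep_all":
                candidates: list[int] = []
            elif retention.kind == "keep_last_k":
                keep = int(retention.value)  # newest k survive
                candidates = ids[:-keep] if keep < len(ids) else []
            elif retention.kind == "keep_days_d":
                cutoff = self.clock() - float(retention.value) * 86400.0
                candidates = [
                    vid for vid in ids
                    if self._load_manifest(vid).created_at < cutoff
                ]
            else:
                raise ValueError(f"unknown retention kind {retention.kind!r}")
            for vid in candidates:
                if vid == current_id:
                    continue
                if self._pins.get(vid, 0) > 0:
                    log.info("prune deferred for pinned version %d", vid)
                    continue
                shutil.rmtree(self.versions_dir / str(vid))
                self._pruned.add(vid)
                pruned.append(vid)
                log.info("pruned version %d", vid)
        return pruned
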