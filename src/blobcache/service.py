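"""Request dispatch: parse query-parameter requests, pin a blob version,
invoke the service operation, and serialize version-stamped responses.

Every successful response carries the version id of the blob it was
computed from, so any result can later be reproduced by addressing the
same ``versionIdentifier`` — (request, version) is a pure function as
long as the version is retained.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Any, Protocol

from .errors import (
    UnknownOperationError,
    UnsupportedFormatError,
    ValidationError,
)
from .store import BlobHandle, BlobStore

log = logging.getLogger(__name__)

SUPPORTED_FORMATS = ("xml", "csv", "tsv", "json")
DEFAULT_FORMAT = "xml"

#: A payload is a list of flat records (dicts with scalar values); the
#: column order of the first record fixes the serialization order.
Payload = list[dict[str, Any]]


@dataclass
class ServiceRequest:
    operation: str
    params: dict[str, str] = field(default_factory=dict)
    accept_format: str = DEFAULT_FORMAT

    def __post_init__(self) -> None:
        if not self.operation:
            raise ValidationError("operation must be non-empty")
        vid = self.params.get("versionIdentifier")
        if vid is not None and (not vid.isdigit() or int(vid) <= 0):
            raise ValidationError(
                f"versionIdentifier must be a positive integer, got {vid!r}"
            )

    @property
    def version_id(self) -> int | None:
        vid = self.params.get("versionIdentifier")
        return int(vid) if vid is not None else None


@dataclass
class ServiceResponse:
    payload: Payload
    version_id: int
    format: str
    metadata_echo: dict[str, str] = field(default_factory=dict)

    def body(self) -> bytes:
        return serialize(self.payload, self.format)[0]


class RebuildableService(Protocol):
    """What a registered service must provide: named operations over a
    pinned blob.  ``getVersions`` is handled by the dispatcher."""

    operations: tuple[str, ...]

    def perform(self, operation: str, params: dict[str, str], blob: BlobHandle) -> Payload:
        ...


def handle(
    request: ServiceRequest, service: RebuildableService, store: BlobStore
) -> ServiceResponse:
    """Dispatch one request against one registered service.

    The blob version (``versionIdentifier`` or current) is resolved and
    pinned once, at request start, and used throughout, so an in-flight
    request is undisturbed by concurrent rebuilds or pruning."""
    if request.accept_format not in SUPPORTED_FORMATS:
        raise UnsupportedFormatError(request.accept_format, list(SUPPORTED_FORMATS))
    supported = list(service.operations) + ["getVersions"]
    if request.operation not in supported:
        raise UnknownOperationError(request.operation, supported)
    with store.resolve(request.version_id) as blob:
        if request.operation == "getVersions":
            payload = versions_payload(store)
        else:
            payload = service.perform(request.operation, request.params, blob)
        record = blob.record()
        return ServiceResponse(
            payload=payload,
            version_id=blob.version_id,
            format=request.accept_format,
            metadata_echo=dict(record.metadata),
        )


def versions_payload(store: BlobStore) -> Payload:
    """Provenance listing: one row per file per retained version."""
    rows: Payload = []
    for record in store.list_versions():
        for fp in record.files:
            rows.append(
                {
                    "versionIdentifier": record.version_id,
                    "created_at": record.created_at,
                    "file_name": fp.file_name,
                    "byte_size": fp.byte_size,
                    "source_url": fp.source_url,
                }
            )
        if not record.files:
            rows.append(
                {
                    "versionIdentifier": record.version_id,
                    "created_at": record.created_at,
                    "file_name": "",
                    "byte_size": 0,
                    "source_url": "",
                }
            )
    return rows


def _columns(payload: Payload) -> list[str]:
    cols: list[str] = []
    for row in payload:
        for key in row:
            if key not in cols:
                cols.append(key)
    return cols


def serialize(payload: Payload, fmt: str) -> tuple[bytes, str]:
    """Deterministically serialize a payload; returns (bytes, media type).

    csv/tsv carry one header row; xml wraps one ``<record>`` element per
    row; json is a list of objects with keys in column order."""
    if fmt not in SUPPORTED_FORMATS:
        raise UnsupportedFormatError(fmt, list(SUPPORTED_FORMATS))
    cols = _columns(payload)
    if fmt in ("csv", "tsv"):
        buf = io.StringIO()
        writer = csv.writer(buf, delimiter="," if fmt == "csv" else "\t", lineterminator="\n")
        writer.writerow(cols)
        for row in payload:
            writer.writerow(["" if row.get(c) is None else row.get(c) for c in cols])
        return buf.getvalue().encode("utf-8"), f"text/{fmt};charset=utf-8"
    if fmt == "json":
        text = json.dumps(
            [{c: row.get(c) for c in cols if c in row} for row in payload],
            indent=1,
        )
        return text.encode("utf-8"), "application/json"
    root = ET.Element("results")
    for row in payload:
        rec = ET.SubElement(root, "record")
        for c in cols:
            if c in row:
                child = ET.SubElement(rec, c)
                child.text = "" if row[c] is None else str(row[c])
    return ET.tostring(root, encoding="utf-8", xml_declaration=True), "application/xml"


def parse_gene_list(raw: str, delimiter: str = ",") -> list[int]:
    """Split a gene-ID list parameter on the service's delimiter.

    Tokens are trimmed, validated as non-negative integer IDs, and
    deduplicated preserving first occurrence.  An empty or non-integer
    token raises :class:`ValidationError` naming the token."""
    if delimiter not in (",", "|"):
        raise ValidationError(f"unsupported delimiter {delimiter!r}")
    if not raw:
        raise ValidationError("empty gene list")
    seen: dict[int, None] = {}
    for token in raw.split(delimiter):
        token = token.strip()
        if not token or not token.isdigit():
            raise ValidationError(f"invalid gene ID token {token!r}")
        seen.setdefault(int(token), None)
    return list(seen)


def parse_name_list(raw: str, delimiter: str = ",") -> list[str]:
    """Like :func:`parse_gene_list` but for symbol/name tokens
    (non-empty strings, case-insensitively deduplicated)."""
    if not raw:
        raise ValidationError("empty name list")
    seen: dict[str, str] = {}
    for token in raw.split(delimiter):
        token = token.strip()
        if not token:
            raise ValidationError("empty name token")
        seen.setdefault(token.upper(), token)
    return list(seen.values())


def error_payload(exc: Exception) -> Payload:
    """Errors share the success serialization formats, with an explicit
    error field."""
    row: dict[str, Any] = {"error": type(exc).__name__, "message": str(exc)}
    for attr in ("supported", "available", "retry_after"):
        if hasattr(exc, attr):
            val = getattr(exc, attr)
            row[attr] = ",".join(str(v) for v in val) if isinstance(val, list) else val
    return [row]
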