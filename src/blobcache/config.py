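"""Declarative deployment configuration.

One document describes a deployment: proxy rate policies and cache
location, plus one entry per rebuildable service (sources, schedule,
retention, metadata, output formats).  YAML is the primary syntax; an
XML reader for the same schema is provided as well.  The schema, not
the syntax, is normative.

YAML example::

    proxy:
      cache_dir: /var/cache/blobcache
      max_entries: 10000
      policies:
        - host_pattern: "*.ncbi.nlm.nih.gov"
          max_requests: 3
          window_seconds: 1.0
    services:
      - service_name: geneinfo
        store_dir: /var/lib/blobcache/geneinfo
        schedule: P7D
        retention: keep_last_k=4
        output_formats: [xml, csv, json]
        metadata: {maintainer: someone@example.org}
        sources:
          - url: https://example.org/genes.tsv.gz
            target_name: genes.tsv
            decompress: true
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .proxy import RatePolicy
from .schedule import Schedule
from .scheduler import ServiceConfig, SourceSpec
from .store import Retention

_TRUE = {"true", "yes", "1"}


@dataclass
class ProxyConfig:
    cache_dir: str | None = None
    max_entries: int | None = None
    policies: list[RatePolicy] = field(default_factory=list)


@dataclass
class DeploymentConfig:
    proxy: ProxyConfig
    services: list["ServiceEntry"]


@dataclass
class ServiceEntry:
    config: ServiceConfig
    store_dir: str


def _service_from_mapping(m: dict) -> ServiceEntry:
    try:
        sources = [
            SourceSpec(
                url=s["url"],
                target_name=s["target_name"],
                via_proxy=bool(s.get("via_proxy", True)),
                decompress=bool(s.get("decompress", False)),
            )
            for s in m.get("sources", [])
        ]
        config = ServiceConfig(
            service_name=m["service_name"],
            sources=sources,
            schedule=Schedule.parse(str(m["schedule"])),
            retention=Retention.parse(str(m.get("retention", "keep_all"))),
            metadata={str(k): str(v) for k, v in (m.get("metadata") or {}).items()},
            output_formats=list(m.get("output_formats", ["xml", "csv", "tsv", "json"])),
        )
        return ServiceEntry(config=config, store_dir=str(m["store_dir"]))
    except KeyError as exc:
        raise ValidationError(f"service config missing key {exc}") from exc


def _proxy_from_mapping(m: dict) -> ProxyConfig:
    policies = [
        RatePolicy(
            host_pattern=p["host_pattern"],
            max_requests=int(p["max_requests"]),
            window_seconds=float(p["window_seconds"]),
            ttl_seconds=float(p["ttl_seconds"]) if p.get("ttl_seconds") is not None else None,
        )
        for p in m.get("policies", [])
    ]
    max_entries = m.get("max_entries")
    return ProxyConfig(
        cache_dir=m.get("cache_dir"),
        max_entries=int(max_entries) if max_entries is not None else None,
        policies=policies,
    )


def load_yaml(path: str | Path) -> DeploymentConfig:
    """Read the YAML deployment document."""
    try:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ValidationError(f"unparseable YAML config: {exc}") from exc
    return DeploymentConfig(
        proxy=_proxy_from_mapping(doc.get("proxy") or {}),
        services=[_service_from_mapping(s) for s in doc.get("services", [])],
    )


def load_xml(path: str | Path) -> DeploymentConfig:
    """Read the XML rendering of the same schema.

    Element names mirror the YAML keys::

        <deployment>
          <proxy cache_dir="..." max_entries="...">
            <policy host_pattern="*" max_requests="3" window_seconds="1"/>
          </proxy>
          <service service_name="..." store_dir="..." schedule="P7D"
                   retention="keep_all" output_formats="xml,csv">
            <metadata key="maintainer">someone</metadata>
            <source url="..." target_name="..." decompress="true"/>
          </service>
        </deployment>
    """
    try:
        root = ET.parse(Path(path)).getroot()
    except ET.ParseError as exc:
        raise ValidationError(f"unparseable XML config: {exc}") from exc
    proxy_el = root.find("proxy")
    proxy_map: dict = {}
    if proxy_el is not None:
        proxy_map = dict(proxy_el.attrib)
        proxy_map["policies"] = [dict(p.attrib) for p in proxy_el.findall("policy")]
    services = []
    for s in root.findall("service"):
        m: dict = dict(s.attrib)
        if "output_formats" in m:
            m["output_formats"] = [f.strip() for f in m["output_formats"].split(",")]
        m["metadata"] = {
            el.get("key", ""): (el.text or "") for el in s.findall("metadata")
        }
        m["sources"] = [
            {
                "url": el.get("url"),
                "target_name": el.get("target_name"),
                "via_proxy": el.get("via_proxy", "true").lower() in _TRUE,
                "decompress": el.get("decompress", "false").lower() in _TRUE,
            }
            for el in s.findall("source")
        ]
        services.append(_service_from_mapping(m))
    return DeploymentConfig(proxy=_proxy_from_mapping(proxy_map), services=services)


def load(path: str | Path) -> DeploymentConfig:
    """Read a deployment config, dispatching on file extension."""
    path = Path(path)
    if path.suffix.lower() == ".xml":
        return load_xml(path)
    return load_yaml(path)
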