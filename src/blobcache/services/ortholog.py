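"""Ortholog lookup service over an indexed orthology table.

Blob file ``orthologs.tsv``: five tab-separated columns
(source_taxon, source_gene, target_taxon, target_gene, percent_identity),
one row per ortholog pair; one source gene may map to several targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ..errors import ValidationError
from ..service import Payload, parse_gene_list
from ..store import BlobHandle


@dataclass(frozen=True)
class OrthologRecord:
    source_gene: int
    target_gene: int
    source_taxon: int
    target_taxon: int
    percent_identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )

    def to_row(self) -> dict:
        return {
            "source_gene": self.source_gene,
            "target_gene": self.target_gene,
            "source_taxon": self.source_taxon,
            "target_taxon": self.target_taxon,
            "percent_identity": self.percent_identity,
        }


class OrthologTable:
    """(source_taxon, target_taxon, source_gene) index over the table."""

    def __init__(self, records: list[OrthologRecord]):
        self._index: dict[tuple[int, int, int], list[OrthologRecord]] = {}
        self.taxon_pairs: set[tuple[int, int]] = set()
        for rec in records:
            key = (rec.source_taxon, rec.target_taxon, rec.source_gene)
            self._index.setdefault(key, []).append(rec)
            self.taxon_pairs.add((rec.source_taxon, rec.target_taxon))

    def lookup(
        self, source_taxon: int, target_taxon: int, gene_ids: list[int]
    ) -> list[OrthologRecord]:
        out: list[OrthologRecord] = []
        for gid in gene_ids:
            out.extend(self._index.get((source_taxon, target_taxon, gid), []))
        return out


def load_orthologs(path: str | Path) -> OrthologTable:
    df = pd.read_csv(
        path, sep="\t", compression="infer", comment="#", header=None,
        names=["source_taxon", "source_gene", "target_taxon", "target_gene",
               "percent_identity"],
    )
    records = [
        OrthologRecord(
            source_gene=int(r.source_gene),
            target_gene=int(r.target_gene),
            source_taxon=int(r.source_taxon),
            target_taxon=int(r.target_taxon),
            percent_identity=float(r.percent_identity),
        )
        for r in df.itertuples(index=False)
    ]
    return OrthologTable(records)


class OrthologService:
    """Returns all orthologs (and product percent identity) of the input
    genes for a (source species, target species) pair."""

    operations = ("getOrthologs", "default")
    ortholog_file = "orthologs.tsv"

    def __init__(self) -> None:
        self._loaded: dict[int, OrthologTable] = {}

    def _table(self, blob: BlobHandle) -> OrthologTable:
        cached = self._loaded.get(blob.version_id)
        if cached is None:
            cached = load_orthologs(blob.root_path / self.ortholog_file)
            self._loaded[blob.version_id] = cached
        return cached

    def perform(self, operation: str, params: dict[str, str], blob: BlobHandle) -> Payload:
        table = self._table(blob)
        source = int(params.get("sourceSpecies", "0"))
        target = int(params.get("targetSpecies", "0"))
        ids = parse_gene_list(params.get("genes", ""), ",")
        if (source, target) not in table.taxon_pairs:
            return [{"diagnostic": f"no orthology data for taxon pair ({source}, {target})"}]
        return [r.to_row() for r in table.lookup(source, target, ids)]
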