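"""Gene info/ID/interactant lookup service.

Loads an NCBI gene_info-style table from the blob into in-memory lookup
tables keyed by (taxon, gene id) and (taxon, uppercased symbol), plus an
undirected interaction table, and answers getInfo / getIds /
getInteractants requests.

Two table dialects are read:

* the genuine NCBI gene_info dialect (``#tax_id  GeneID  Symbol ...
  chromosome  map_location  description``) — which carries no start
  coordinate, so ``start_position`` is left unknown rather than misusing
  map_location; and
* a compact fixture dialect (``tax_id  GeneID  Symbol  chromosome
  start_position  description``) with the start coordinate explicit.

Both are gzip-transparent; comment lines start with ``#`` (the genuine
header itself is the last such line).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ..errors import ValidationError
from ..service import Payload, parse_gene_list, parse_name_list
from ..store import BlobHandle

log = logging.getLogger(__name__)

FIXTURE_COLUMNS = ["tax_id", "GeneID", "Symbol", "chromosome", "start_position", "description"]
NCBI_MANDATORY = ["tax_id", "GeneID", "Symbol", "chromosome", "description"]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: int
    symbol: str
    taxon: int
    chromosome: str
    start_position: int | None
    description: str

    def to_row(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "symbol": self.symbol,
            "taxon": self.taxon,
            "chromosome": self.chromosome,
            "start_position": self.start_position,
            "description": self.description,
        }


def _read_table(path: Path) -> pd.DataFrame:
    """Read either gene-table dialect into a normalized frame."""
    # the genuine dialect comments its header ("#tax_id ..."), so sniff
    # the first line before deciding how pandas should parse the rest
    first = pd.read_csv(
        path, sep="\t", nrows=0, compression="infer",
        header=0, dtype=str,
    ).columns.tolist()
    if first and first[0].lstrip("#") == "tax_id":
        df = pd.read_csv(path, sep="\t", compression="infer", dtype=str, comment=None)
        df.columns = [c.lstrip("#") for c in df.columns]
    else:
        raise ValidationError(f"{path.name}: first column must be tax_id, got {first[:1]}")
    missing = [c for c in NCBI_MANDATORY if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing mandatory columns {missing}")
    if "start_position" not in df.columns:
        df["start_position"] = None
    return df


def load_gene_info(path: str | Path) -> "GeneTable":
    """Build the in-memory lookup tables from a gene table file.

    Duplicate (taxon, gene id) rows: last wins, with a logged warning.
    A missing mandatory column fails the load (the build aborts)."""
    path = Path(path)
    df = _read_table(path)
    by_id: dict[tuple[int, int], GeneRecord] = {}
    by_symbol: dict[tuple[int, str], list[int]] = {}
    for row in df.itertuples(index=False):
        taxon = int(row.tax_id)
        gene_id = int(row.GeneID)
        start = row.start_position
        try:
            start = int(start) if start not in (None, "", "-") and not pd.isna(start) else None
        except (TypeError, ValueError):
            start = None
        record = GeneRecord(
            gene_id=gene_id,
            symbol=str(row.Symbol),
            taxon=taxon,
            chromosome=str(row.chromosome),
            start_position=start,
            description=str(row.description),
        )
        if (taxon, gene_id) in by_id:
            log.warning("duplicate gene (%d, %d); last row wins", taxon, gene_id)
            old = by_id[(taxon, gene_id)]
            sym_key = (taxon, old.symbol.upper())
            if sym_key in by_symbol and gene_id in by_symbol[sym_key]:
                by_symbol[sym_key].remove(gene_id)
        by_id[(taxon, gene_id)] = record
        by_symbol.setdefault((taxon, record.symbol.upper()), [])
        if gene_id not in by_symbol[(taxon, record.symbol.upper())]:
            by_symbol[(taxon, record.symbol.upper())].append(gene_id)
    return GeneTable(by_id, by_symbol)


class GeneTable:
    """In-memory (taxon, id) and (taxon, symbol) indexes."""

    def __init__(
        self,
        by_id: dict[tuple[int, int], GeneRecord],
        by_symbol: dict[tuple[int, str], list[int]],
    ):
        self.by_id = by_id
        self.by_symbol = by_symbol

    def __len__(self) -> int:
        return len(self.by_id)

    def get_info(
        self, taxon: int, gene_ids: list[int]
    ) -> tuple[list[GeneRecord], list[int]]:
        """Records for the known IDs in input order, plus the distinct
        not-found list (unknown IDs are never silently dropped)."""
        found, missing = [], []
        for gid in gene_ids:
            rec = self.by_id.get((taxon, gid))
            if rec is None:
                missing.append(gid)
            else:
                found.append(rec)
        return found, missing

    def get_ids(
        self, taxon: int, symbols: list[str]
    ) -> tuple[list[tuple[str, list[int]]], list[str]]:
        """Case-insensitive symbol -> gene id lookup.

        Returns ([(symbol, [ids...]), ...], not_found); a symbol mapping
        to more than one id returns all of them (ambiguity is flagged in
        the service payload)."""
        found, missing = [], []
        for sym in symbols:
            ids = self.by_symbol.get((taxon, sym.upper()))
            if not ids:
                missing.append(sym)
            else:
                found.append((sym, list(ids)))
        return found, missing


def load_interactions(path: str | Path) -> "InteractionTable":
    """Read the 3-column interaction TSV (taxon, gene_a, gene_b)."""
    df = pd.read_csv(
        path, sep="\t", compression="infer", dtype=int,
        names=["taxon", "gene_a", "gene_b"], comment="#", header=None,
    )
    table = InteractionTable()
    for row in df.itertuples(index=False):
        table.add(int(row.taxon), int(row.gene_a), int(row.gene_b))
    return table


class InteractionTable:
    """Symmetric adjacency of interacting gene pairs within a taxon."""

    def __init__(self) -> None:
        self._adj: dict[tuple[int, int], set[int]] = {}

    def add(self, taxon: int, a: int, b: int) -> None:
        self._adj.setdefault((taxon, a), set()).add(b)
        self._adj.setdefault((taxon, b), set()).add(a)

    def partners(self, taxon: int, gene_id: int) -> list[int]:
        return sorted(self._adj.get((taxon, gene_id), ()))


class GeneInfoService:
    """The getInfo / getIds / getInteractants service over one blob.

    Blob files: ``genes.tsv`` (either dialect, optionally gzipped as
    ``genes.tsv.gz``) and optional ``interactions.tsv``."""

    operations = ("getInfo", "getIds", "getInteractants")
    gene_file_candidates = ("genes.tsv", "genes.tsv.gz", "gene_info.tsv")
    interaction_file = "interactions.tsv"

    def __init__(self) -> None:
        self._loaded: dict[int, tuple[GeneTable, InteractionTable]] = {}

    def _tables(self, blob: BlobHandle) -> tuple[GeneTable, InteractionTable]:
        cached = self._loaded.get(blob.version_id)
        if cached is not None:
            return cached
        gene_path = None
        for name in self.gene_file_candidates:
            if (blob.root_path / name).exists():
                gene_path = blob.root_path / name
                break
        if gene_path is None:
            raise ValidationError("blob has no gene table file")
        genes = load_gene_info(gene_path)
        ipath = blob.root_path / self.interaction_file
        interactions = load_interactions(ipath) if ipath.exists() else InteractionTable()
        self._loaded[blob.version_id] = (genes, interactions)
        return genes, interactions

    def perform(self, operation: str, params: dict[str, str], blob: BlobHandle) -> Payload:
        genes, interactions = self._tables(blob)
        taxon = int(params.get("sourceSpecies", "0"))
        if operation == "getInfo":
            ids = parse_gene_list(params.get("genes", ""), ",")
            found, missing = genes.get_info(taxon, ids)
            rows: Payload = [r.to_row() for r in found]
            rows.extend({"gene_id": gid, "not_found": True} for gid in missing)
            return rows
        if operation == "getIds":
            names = parse_name_list(params.get("genes", ""), ",")
            found, missing = genes.get_ids(taxon, names)
            rows = []
            for sym, ids in found:
                for gid in ids:
                    rows.append(
                        {"symbol": sym, "gene_id": gid, "ambiguous": len(ids) > 1}
                    )
            rows.extend({"symbol": s, "not_found": True} for s in missing)
            return rows
        if operation == "getInteractants":
            ids = parse_gene_list(params.get("genes", ""), ",")
            rows = []
            for gid in ids:
                for partner in interactions.partners(taxon, gid):
                    rec = genes.by_id.get((taxon, partner))
                    row = {"query_gene": gid, "gene_id": partner}
                    if rec is not None:
                        row.update(
                            symbol=rec.symbol,
                            chromosome=rec.chromosome,
                            start_position=rec.start_position,
                        )
                    rows.append(row)
            return rows
        raise ValidationError(f"unhandled operation {operation!r}")
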