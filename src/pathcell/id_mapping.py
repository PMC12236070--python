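"""Offline gene-identifier and cross-species matrix conversion.

Mapping tables are local two-column TSVs (source_id, target_id) — no
network lookups, which keeps conversions reproducible and fast.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, UsageError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["IdMap", "MapReport", "read_id_map", "map_ids", "convert_matrix_species"]


@dataclass
class IdMap:
    """Source -> target identifier pairs with direction metadata."""

    pairs: pd.DataFrame  # columns: source, target
    direction: str = ""

    def __post_init__(self) -> None:
        if list(self.pairs.columns) != ["source", "target"]:
            self.pairs = self.pairs.rename(
                columns=dict(zip(self.pairs.columns, ["source", "target"]))
            )
        if self.pairs.empty:
            raise DataError("identifier map is empty")
        before = len(self.pairs)
        self.pairs = self.pairs.drop_duplicates().reset_index(drop=True)
        if len(self.pairs) < before:
            logger.warning("dropped %d duplicate (source, target) pairs",
                           before - len(self.pairs))

    @property
    def multiplicity(self) -> str:
        one_to_one = (
            self.pairs["source"].is_unique and self.pairs["target"].is_unique
        )
        return "one_to_one" if one_to_one else "many_to_many"

    def targets_of(self, source: str) -> list[str]:
        hits = self.pairs.loc[self.pairs["source"] == source, "target"]
        return sorted(hits.tolist())

    def inverted(self) -> "IdMap":
        inv = self.pairs.rename(columns={"source": "target", "target": "source"})
        return IdMap(inv[["source", "target"]], direction=f"inverse({self.direction})")


def read_id_map(path: str | Path, direction: str = "") -> IdMap:
    """Read a two-column TSV mapping table (header row expected)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise DataError(f"{path}: mapping table needs 2 columns")
    df = df.iloc[:, :2]
    df.columns = ["source", "target"]
    return IdMap(df.dropna(), direction=direction or str(path))


@dataclass
class MapReport:
    unmapped: int = 0
    ambiguous: int = 0


def map_ids(ids: list[str], id_map: IdMap, policy: str = "first"
            ) -> tuple[list[str], MapReport]:
    """Map identifiers through a table, order-preserving.

    first: one deterministic target per source (lexicographically first).
    all: expand to every match. drop_ambiguous: sources with several
    targets are removed (counted in the report). Unknown sources are
    omitted and counted.
    """
    if policy not in ("first", "all", "drop_ambiguous"):
        raise UsageError(f"unknown policy {policy!r}")
    lut: dict[str, list[str]] = {}
    for source, target in id_map.pairs.itertuples(index=False):
        lut.setdefault(source, []).append(target)
    for targets in lut.values():
        targets.sort()
    out: list[str] = []
    report = MapReport()
    for i in ids:
        targets = lut.get(i)
        if targets is None:
            report.unmapped += 1
            continue
        if len(targets) > 1:
            report.ambiguous += 1
            if policy == "drop_ambiguous":
                continue
        if policy == "all":
            out.extend(targets)
        else:
            out.append(targets[0])
    return out, report


def convert_matrix_species(expr: ExpressionMatrix, ortholog: IdMap,
                           aggregate: str = "sum") -> ExpressionMatrix:
    """Rename matrix rows through an ortholog map.

    Many-to-one collisions are combined by ``sum`` (count semantics) or
    ``mean`` (suits normalized data); unmapped rows are dropped with a
    logged count. Ambiguous sources (several targets) contribute to each
    target. Cell order is unchanged.
    """
    if aggregate not in ("sum", "mean"):
        raise UsageError(f"unknown aggregate {aggregate!r}")
    lut: dict[str, list[str]] = {}
    for source, target in ortholog.pairs.itertuples(index=False):
        lut.setdefault(source, []).append(target)
    rows: list[np.ndarray] = []
    targets: list[str] = []
    unmapped = 0
    for gi, gene in enumerate(expr.gene_ids):
        hits = lut.get(gene)
        if not hits:
            unmapped += 1
            continue
        for t in sorted(hits):
            rows.append(expr.values[gi])
            targets.append(t)
    if not rows:
        raise DataError("no gene of the matrix is present in the ortholog map")
    if unmapped:
        logger.warning("dropped %d unmapped genes", unmapped)
    df = pd.DataFrame(np.vstack(rows))
    df["__target"] = targets
    agg = df.groupby("__target", sort=True).sum() if aggregate == "sum" \
        else df.groupby("__target", sort=True).mean()
    return ExpressionMatrix(agg.to_numpy(), list(agg.index), list(expr.cell_ids))
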