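"""Expression-table and geneset I/O plus preprocessing.

This module carries everything that happens *before* the pathway statistic:
reading gene-by-sample expression tables (RNA-Seq RPKM or microarray
intensities), collapsing alternative transcripts that map to the same gene
symbol, log2 transformation, reading/writing GMT geneset collections, and
restricting genesets to the measured-gene universe with the 15-500 size
filter conventionally used for GO-BP / KEGG collections.

Conventions
-----------
* Gene identifiers are matched case-sensitively, as exact strings; callers
  supply harmonized symbols.
* Transcript collapse keeps, among rows sharing a gene symbol, the row with
  the maximal mean expression across all samples; ties keep the first row
  in file order.
* Geneset size is counted after intersecting members with the measured
  genes, since the downstream statistic only ever sees measured genes.
  Bounds are inclusive.
* No low-expression filtering is applied anywhere; a pseudocount (default 1)
  handles zeros when log-transforming linear RNA-Seq values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SamplePair",
    "GeneSet",
    "GeneSetCollection",
    "read_expression_table",
    "write_expression_table",
    "collapse_transcripts",
    "log2_transform",
    "make_pair",
    "read_gmt",
    "write_gmt",
    "filter_genesets",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table with a declared scale.

    ``data`` is indexed by gene symbol (duplicates allowed until
    :func:`collapse_transcripts` runs) with one numeric column per sample.
    ``scale`` is ``"linear"`` (e.g. RPKM) or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str  # {"linear", "log2"}

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def has_duplicate_genes(self) -> bool:
        return bool(self.data.index.duplicated().any())

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")


@dataclass
class SamplePair:
    """One case profile and its matched control on a shared gene index.

    The unit of analysis for the single-subject statistic: e.g. one
    knockdown transcriptome paired with its control, both log2.
    """

    pair_id: str
    case: pd.Series
    control: pd.Series

    def __post_init__(self) -> None:
        if not self.case.index.equals(self.control.index):
            raise ValueError("case and control must share an identical gene index")
        if self.case.index.has_duplicates:
            raise ValueError("pair gene index contains duplicates; collapse transcripts first")
        for name, v in (("case", self.case), ("control", self.control)):
            if len(v) and not np.isfinite(v.to_numpy(dtype=float)).all():
                raise ValueError(f"{name} profile contains non-finite values")

    @property
    def genes(self) -> pd.Index:
        return self.case.index

    def swapped(self) -> "SamplePair":
        """The same pair with case and control exchanged (for symmetry checks)."""
        return SamplePair(self.pair_id, self.control.copy(), self.case.copy())


@dataclass
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"geneset {self.set_id} has no members")
        self.members = frozenset(self.members)


@dataclass
class GeneSetCollection:
    """A map of set_id -> GeneSet plus the size bounds it was (or will be) filtered with."""

    sets: dict[str, GeneSet] = field(default_factory=dict)
    min_size: int = 15
    max_size: int = 500

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for gs in self:
            out |= gs.members
        return out


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read a TSV/CSV expression table (first column gene id, header of sample ids).

    Duplicate gene rows are preserved so that :func:`collapse_transcripts`
    can resolve them. Non-numeric cells raise ``ValueError`` naming the
    offending gene row and sample column.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty expression table") from exc
    if raw.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | raw.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}"
        )
    numeric.index = numeric.index.astype(str)
    return ExpressionMatrix(numeric.astype(float), scale)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    matrix.data.to_csv(path, sep=sep, index_label="gene")


def collapse_transcripts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Resolve duplicate gene symbols by keeping the highest-expressed transcript.

    Alternative transcripts mapped to one symbol appear as duplicate rows;
    for each symbol the row with the maximal mean expression across samples
    is kept (ties: first occurrence in file order). A matrix without
    duplicates is returned unchanged (idempotent).
    """
    if not matrix.has_duplicate_genes:
        return matrix
    df = matrix.data
    means = df.mean(axis=1).to_numpy()
    best: dict[str, int] = {}
    for i, gene in enumerate(df.index):
        j = best.get(gene)
        if j is None or means[i] > means[j]:
            best[gene] = i
    keep = sorted(best.values())
    return ExpressionMatrix(df.iloc[keep], matrix.scale)


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount) on a linear-scale matrix."""
    if matrix.scale != "linear":
        raise ValueError("matrix is already log2-scaled")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    values = matrix.data.to_numpy(dtype=float)
    if values.size and values.min() < 0:
        raise ValueError("negative expression values cannot be log2-transformed")
    if values.size and (values + pseudocount <= 0).any():
        raise ValueError("value + pseudocount must be positive; increase the pseudocount")
    return ExpressionMatrix(np.log2(matrix.data + pseudocount), "log2")


def make_pair(matrix: ExpressionMatrix, case: str, control: str, pair_id: str | None = None) -> SamplePair:
    """Extract a case/control :class:`SamplePair` from a collapsed log2 matrix."""
    if matrix.scale != "log2":
        raise ValueError("pairs are built from log2-scale matrices; apply log2_transform first")
    for s in (case, control):
        if s not in matrix.data.columns:
            raise KeyError(f"sample {s!r} not in matrix columns")
    pid = pair_id if pair_id is not None else f"{case}_vs_{control}"
    return SamplePair(pid, matrix.data[case].copy(), matrix.data[control].copy())


# ---------------------------------------------------------------------------
# genesets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, min_size: int = 15, max_size: int = 500) -> GeneSetCollection:
    """Read a GMT file: ``set_id TAB description TAB member1 TAB ...`` per line.

    All sets are loaded unfiltered (apply :func:`filter_genesets` against a
    measured-gene universe afterwards). Members repeated on one line are
    stored once; a repeated set_id across lines is an error.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
            set_id, name, *members = fields
            members = [m for m in members if m]
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate geneset id {set_id!r}")
            sets[set_id] = GeneSet(set_id, name, frozenset(members))
    return GeneSetCollection(sets, min_size=min_size, max_size=max_size)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.members)]) + "\n")


def filter_genesets(
    collection: GeneSetCollection,
    measured_genes: Iterable[str],
    min_size: int | None = None,
    max_size: int | None = None,
) -> GeneSetCollection:
    """Restrict genesets to measured genes and keep sizes in [min_size, max_size].

    The effective size is the count of members that are actually measured;
    bounds are inclusive. Members of retained sets are restricted to the
    measured universe, so filtering is idempotent.
    """
    lo = collection.min_size if min_size is None else min_size
    hi = collection.max_size if max_size is None else max_size
    if lo > hi:
        raise ValueError(f"min_size ({lo}) > max_size ({hi})")
    universe = set(measured_genes)
    if not universe:
        raise ValueError("measured_genes is empty")
    kept: dict[str, GeneSet] = {}
    for gs in collection:
        measured = gs.members & universe
        if lo <= len(measured) <= hi:
            kept[gs.set_id] = GeneSet(gs.set_id, gs.name, frozenset(measured))
    return GeneSetCollection(kept, min_size=lo, max_size=hi)
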