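"""Differential-expression baselines: DEG calling and Fisher-exact enrichment.

These are the conventional comparators for the single-subject pathway
statistic. For a lone sample pair, genes can only be called deregulated by
fold change (no gene-level p-value exists at n = 1); with replicated
groups, genes passing an absolute fold-change filter are tested with a
two-sample t-test and BH-adjusted. Either way, the up- and down-regulated
lists are enriched independently against each geneset with a one-sided
Fisher's exact test on the (DE, All) x (In set, Not in set) table, and
geneset p-values are BH-adjusted across the collection.

All fold thresholds are inclusive and applied on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf, log2
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geneset_io import ExpressionMatrix, GeneSetCollection, SamplePair

__all__ = [
    "DEGList",
    "EnrichmentResult",
    "call_deg_fold_only",
    "call_deg_ttest",
    "fisher_enrichment",
    "odds_ratio",
    "write_deg_list",
    "read_deg_list",
    "enrichment_to_frame",
]


@dataclass
class DEGList:
    """Up- and down-regulated gene lists over a measured-gene universe."""

    up: frozenset[str]
    down: frozenset[str]
    universe: frozenset[str]
    provenance: str  # {"fold_only", "fold_plus_ttest", "external"}
    fold_threshold: float
    fdr_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down DEG lists overlap")
        if not (self.up | self.down) <= self.universe:
            raise ValueError("DEG lists contain genes outside the universe")


@dataclass
class EnrichmentResult:
    """One geneset's 2x2 Fisher outcome against a DEG list.

    Counts: a = DE genes in the set, b = DE genes not in the set,
    c = non-DE set genes, d = the rest; a+b+c+d = |universe|.
    """

    set_id: str
    name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float            # raw ad/bc (inf when bc = 0 and ad > 0)
    odds_ratio_corrected: float  # Haldane-Anscombe +0.5 on every cell
    p_raw: float
    p_fdr: float
    direction_tested: str  # {"up", "down"}
    significant: bool = False


def odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Raw and Haldane-Anscombe-corrected odds ratios for a 2x2 table."""
    if b * c == 0:
        raw = inf if a * d > 0 else np.nan
    else:
        raw = (a * d) / (b * c)
    corrected = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return float(raw), float(corrected)


def call_deg_fold_only(pair: SamplePair, fold: float = 1.5) -> DEGList:
    """Fold-change-only DEG calling for a single pair (log2 scale).

    ``up``: case - control >= log2(fold); ``down``: control - case >=
    log2(fold), inclusive. This is the only gene-level option at n = 1,
    where no per-gene p-value can be computed.
    """
    if fold <= 1:
        raise ValueError("fold threshold must be > 1")
    lfc = pair.case - pair.control
    cut = log2(fold)
    return DEGList(
        up=frozenset(lfc.index[lfc >= cut]),
        down=frozenset(lfc.index[lfc <= -cut]),
        universe=frozenset(pair.genes),
        provenance="fold_only",
        fold_threshold=fold,
    )


def call_deg_ttest(
    case_mat: ExpressionMatrix,
    control_mat: ExpressionMatrix,
    fold: float = 2.0,
    fdr: float = 0.05,
    equal_var: bool = False,
) -> DEGList:
    """Two-step DEG calling for replicated groups (log2 matrices).

    Step 1 keeps genes whose group-mean difference is at least ``log2(fold)``
    in absolute value; step 2 runs a two-sample t-test (Welch by default) on
    those genes only, BH-adjusts over the selected set, and retains genes at
    FDR <= ``fdr``, split into up/down by the sign of the mean difference.
    """
    if fold <= 1:
        raise ValueError("fold threshold must be > 1")
    if case_mat.scale != "log2" or control_mat.scale != "log2":
        raise ValueError("DEG calling expects log2-scale matrices")
    if case_mat.data.shape[1] < 2 or control_mat.data.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group for the t-test")
    if not case_mat.data.index.equals(control_mat.data.index):
        raise ValueError("case and control matrices must share a gene index")

    diff = case_mat.data.mean(axis=1) - control_mat.data.mean(axis=1)
    selected = diff.index[diff.abs() >= log2(fold)]
    universe = frozenset(case_mat.gene_ids)
    if len(selected) == 0:
        return DEGList(frozenset(), frozenset(), universe, "fold_plus_ttest", fold, fdr)

    t, p = stats.ttest_ind(
        case_mat.data.loc[selected].to_numpy(dtype=float),
        control_mat.data.loc[selected].to_numpy(dtype=float),
        axis=1,
        equal_var=equal_var,
    )
    p_adj = multipletests(np.nan_to_num(p, nan=1.0), method="fdr_bh")[1]
    keep = p_adj <= fdr
    kept = selected[keep]
    up = frozenset(g for g in kept if diff[g] > 0)
    down = frozenset(g for g in kept if diff[g] < 0)
    return DEGList(up, down, universe, "fold_plus_ttest", fold, fdr)


def fisher_enrichment(
    deg: DEGList,
    collection: GeneSetCollection,
    direction: str,
    fdr: float = 0.05,
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Fisher-exact over-representation of a DEG list in each geneset.

    Builds the (DE, All) x (In set, Not in set) table per geneset over the
    DEG universe, computes a one-sided (enrichment) exact p by default,
    BH-adjusts across the collection and flags FDR <= ``fdr``. The up and
    down lists are enriched by separate calls, independently.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    universe = set(deg.universe)
    if not universe:
        raise ValueError("DEG universe is empty")
    de = set(deg.up if direction == "up" else deg.down)
    n_univ = len(universe)

    results = []
    for gs in collection:
        members = gs.members & universe
        a = len(de & members)
        b = len(de) - a
        c = len(members) - a
        d = n_univ - a - b - c
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])
        raw_or, corr_or = odds_ratio(a, b, c, d)
        results.append(
            EnrichmentResult(gs.set_id, gs.name, a, b, c, d, raw_or, corr_or, p, np.nan, direction)
        )
    if results:
        p_fdr = multipletests([r.p_raw for r in results], method="fdr_bh")[1]
        for r, q in zip(results, p_fdr):
            r.p_fdr = float(q)
            r.significant = bool(q <= fdr)
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "name": [r.name for r in results],
            "a": [r.a for r in results],
            "b": [r.b for r in results],
            "c": [r.c for r in results],
            "d": [r.d for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "odds_ratio_corrected": [r.odds_ratio_corrected for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_fdr": [r.p_fdr for r in results],
            "direction_tested": [r.direction_tested for r in results],
            "significant": [r.significant for r in results],
        }
    )


def write_deg_list(deg: DEGList, path: str | Path, log2fc: pd.Series | None = None) -> None:
    """Write a DEG list as TSV (gene, log2fc when available, direction)."""
    rows = [(g, "up") for g in sorted(deg.up)] + [(g, "down") for g in sorted(deg.down)]
    with open(path, "w") as fh:
        fh.write(f"# provenance={deg.provenance}\tfold={deg.fold_threshold}\tfdr={deg.fdr_threshold}\n")
        fh.write("gene\tlog2fc\tdirection\n")
        for g, direc in rows:
            fc = "" if log2fc is None else f"{log2fc.get(g, float('nan')):.6g}"
            fh.write(f"{g}\t{fc}\t{direc}\n")


def read_deg_list(path: str | Path, universe: set[str]) -> DEGList:
    """Read an externally supplied DEG TSV (columns gene, direction)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene" not in df.columns or "direction" not in df.columns:
        raise ValueError(f"{path}: DEG table needs 'gene' and 'direction' columns")
    up = frozenset(df.loc[df.direction == "up", "gene"].astype(str))
    down = frozenset(df.loc[df.direction == "down", "gene"].astype(str))
    return DEGList(up, down, frozenset(universe), "external", float("nan"))
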