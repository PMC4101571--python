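"""The single-subject pathway statistic.

One matched pair of transcriptomes (case vs control) is treated as the
entire statistical universe. Each geneset ("mechanism") is scored with a
paired Wilcoxon signed-rank test on the per-gene log2 differences restricted
to its members: the signed rank sums W+ and W- give the deregulation
direction (up if W+ > W-, down if W+ < W-), and a two-sided p-value tests
whether the geneset's genes shift coherently. Per pair, p-values are
adjusted across all tested genesets (Benjamini-Hochberg FDR and Bonferroni)
and mapped to signed Z-scores for cross-sample matrices.

Null distribution
-----------------
Zero differences are dropped (classical signed-rank reduction) and ``|d|``
is ranked with midranks. For ``n_nonzero <= exact_threshold`` (default 25)
the exact null of W+ is computed by convolution over the doubled midranks,
which is identical to enumerating all 2^n sign assignments under the
observed tie structure; above the threshold a normal approximation with
tie-corrected variance and a 0.5 continuity correction is used. The
two-sided p is ``2 P(W <= min(W+, W-))`` capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geneset_io import GeneSet, GeneSetCollection, SamplePair

__all__ = [
    "MechanismScore",
    "PairResult",
    "signed_rank_test",
    "score_geneset",
    "score_pair",
    "select_significant",
    "pvalue_to_z",
    "write_pair_result",
    "read_pair_result",
]

#: p-values are clamped to this floor before the normal-quantile transform,
#: keeping Z finite for vanishingly small adjusted p.
P_FLOOR = 1e-300

CRITERIA = {
    "fdr_05": ("p_fdr", 0.05),
    "bonf_01": ("p_bonf", 0.01),
    "bonf_05": ("p_bonf", 0.05),
}


@dataclass
class MechanismScore:
    """Scores for one geneset in one sample pair."""

    set_id: str
    name: str
    n_genes: int
    n_nonzero: int
    w_plus: float
    w_minus: float
    direction: str  # {"up", "down", "none"}
    p_raw: float
    p_fdr: float = np.nan
    p_bonf: float = np.nan
    z: float = np.nan
    degenerate: bool = False


@dataclass
class PairResult:
    """All geneset scores for one sample pair, with adjusted p-values filled."""

    pair_id: str
    scores: list[MechanismScore]
    z_source: str = "bonf"  # which adjusted p fed pvalue_to_z

    @property
    def universe_size(self) -> int:
        return len(self.scores)

    @property
    def set_ids(self) -> list[str]:
        return [s.set_id for s in self.scores]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set_id": [s.set_id for s in self.scores],
                "name": [s.name for s in self.scores],
                "n_genes": [s.n_genes for s in self.scores],
                "n_nonzero": [s.n_nonzero for s in self.scores],
                "w_plus": [s.w_plus for s in self.scores],
                "w_minus": [s.w_minus for s in self.scores],
                "direction": [s.direction for s in self.scores],
                "p_raw": [s.p_raw for s in self.scores],
                "p_fdr": [s.p_fdr for s in self.scores],
                "p_bonf": [s.p_bonf for s in self.scores],
                "z": [s.z for s in self.scores],
            }
        )


# ---------------------------------------------------------------------------
# the signed-rank null
# ---------------------------------------------------------------------------

def _exact_cdf_at(doubled_ranks: np.ndarray, doubled_w: float) -> float:
    """P(W+ <= w) under the exact sign-flip null for the given midranks.

    Works on doubled ranks so midranks (half-integers) become integers; the
    distribution of W+ is the convolution of independent {0, r_i} terms,
    i.e. exactly the distribution over all 2^n sign assignments.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    k = int(np.floor(doubled_w + 1e-9))
    return float(counts[: k + 1].sum() / counts.sum())


def signed_rank_test(diffs: np.ndarray, exact_threshold: int = 25) -> tuple[float, float, float, int]:
    """Paired Wilcoxon signed-rank test on a vector of differences.

    Returns ``(w_plus, w_minus, p_two_sided, n_nonzero)``. Zeros are
    dropped; fewer than 2 nonzero differences yields p = 1 (degenerate).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < 2:
        if n == 0:
            return 0.0, 0.0, 1.0, 0
        r = 1.0
        wp = r if d[0] > 0 else 0.0
        return wp, r - wp, 1.0, 1
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w_min = min(w_plus, w_minus)
    if n <= exact_threshold:
        doubled = np.rint(2 * ranks).astype(np.int64)
        p = 2.0 * _exact_cdf_at(doubled, 2 * w_min)
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            return w_plus, w_minus, 1.0, n
        # continuity-corrected normal with an Edgeworth kurtosis term: the
        # null of W+ is symmetric (skewness 0), so the leading correction is
        # the 4th cumulant, kappa4 = -sum(r_i^4)/8
        x = (w_min - mu + 0.5) / np.sqrt(var)
        g2 = (-(ranks**4).sum() / 8.0) / var**2
        cdf = stats.norm.cdf(x) - stats.norm.pdf(x) * (g2 / 24.0) * (x**3 - 3 * x)
        p = 2.0 * min(max(cdf, P_FLOOR), 1.0)  # floor keeps p > 0 for huge shifts
    return w_plus, w_minus, float(min(p, 1.0)), n


def score_geneset(pair: SamplePair, geneset: GeneSet, exact_threshold: int = 25) -> MechanismScore:
    """Score one geneset in one pair (unadjusted).

    Differences ``case - control`` over the geneset's measured genes feed
    the signed-rank test; direction comes from comparing W+ and W-.
    """
    genes = [g for g in geneset.members if g in pair.genes]
    d = (pair.case.loc[genes] - pair.control.loc[genes]).to_numpy(dtype=float)
    w_plus, w_minus, p, n_nonzero = signed_rank_test(d, exact_threshold=exact_threshold)
    if w_plus > w_minus:
        direction = "up"
    elif w_plus < w_minus:
        direction = "down"
    else:
        direction = "none"
    return MechanismScore(
        set_id=geneset.set_id,
        name=geneset.name,
        n_genes=len(genes),
        n_nonzero=n_nonzero,
        w_plus=w_plus,
        w_minus=w_minus,
        direction=direction,
        p_raw=p,
        degenerate=n_nonzero < 2,
    )


def score_pair(
    pair: SamplePair,
    collection: GeneSetCollection,
    z_source: str = "bonf",
    exact_threshold: int = 25,
) -> PairResult:
    """Score every geneset of a (size-filtered) collection in one pair.

    Fills BH-FDR and Bonferroni adjusted p-values over all m tested
    genesets and the signed Z (from the ``z_source`` adjusted p, default
    Bonferroni — the default retention criterion downstream).
    """
    if len(collection) == 0:
        raise ValueError("geneset collection is empty")
    if z_source not in ("bonf", "fdr"):
        raise ValueError("z_source must be 'bonf' or 'fdr'")
    scores = [score_geneset(pair, gs, exact_threshold=exact_threshold) for gs in collection]
    p_raw = np.array([s.p_raw for s in scores])
    p_fdr = multipletests(p_raw, method="fdr_bh")[1]
    p_bonf = np.minimum(p_raw * len(p_raw), 1.0)
    for s, pf, pb in zip(scores, p_fdr, p_bonf):
        s.p_fdr = float(pf)
        s.p_bonf = float(pb)
        s.z = pvalue_to_z(pb if z_source == "bonf" else float(pf), s.direction)
    return PairResult(pair.pair_id, scores, z_source=z_source)


def select_significant(result: PairResult, criterion: str = "bonf_01") -> list[MechanismScore]:
    """Mechanisms passing an inclusive adjusted-p threshold, sorted ascending.

    ``criterion`` is one of ``fdr_05`` (BH FDR <= 5%), ``bonf_01``
    (Bonferroni <= 1%, the default retention rule) or ``bonf_05``.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {sorted(CRITERIA)}")
    attr, alpha = CRITERIA[criterion]
    hits = [s for s in result.scores if getattr(s, attr) <= alpha]
    return sorted(hits, key=lambda s: (getattr(s, attr), s.set_id))


def pvalue_to_z(p_adj: float, direction: str) -> float:
    """Map an adjusted two-sided p and a direction to a signed Z-score.

    ``z = sign * Phi^{-1}(1 - p/2)`` with + for up, - for down, 0 for none;
    p is clamped to ``P_FLOOR`` so Z stays finite.
    """
    if not (0 < p_adj <= 1):
        raise ValueError(f"p_adj must be in (0, 1], got {p_adj}")
    if direction == "none":
        return 0.0
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up', 'down' or 'none', got {direction!r}")
    p = max(p_adj, P_FLOOR)
    z = stats.norm.isf(p / 2.0)
    return float(z if direction == "up" else -z)


# ---------------------------------------------------------------------------
# persistence (one TSV per pair)
# ---------------------------------------------------------------------------

def write_pair_result(result: PairResult, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# pair_id={result.pair_id}\tz_source={result.z_source}\n")
        result.to_frame().to_csv(fh, sep="\t", index=False)


def read_pair_result(path: str | Path) -> PairResult:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing pair metadata header line")
        meta = dict(kv.split("=", 1) for kv in header[1:].strip().split("\t"))
        df = pd.read_csv(fh, sep="\t")
    scores = [
        MechanismScore(
            set_id=str(r.set_id),
            name=str(r.name),
            n_genes=int(r.n_genes),
            n_nonzero=int(r.n_nonzero),
            w_plus=float(r.w_plus),
            w_minus=float(r.w_minus),
            direction=str(r.direction),
            p_raw=float(r.p_raw),
            p_fdr=float(r.p_fdr),
            p_bonf=float(r.p_bonf),
            z=float(r.z),
            degenerate=int(r.n_nonzero) < 2,
        )
        for r in df.itertuples()
    ]
    return PairResult(meta.get("pair_id", path.stem), scores, z_source=meta.get("z_source", "bonf"))
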