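"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from nof1pathways import (
    GeneSet,
    GeneSetCollection,
    SamplePair,
)


# ---------------------------------------------------------------------------
# independent oracles (never call package internals)
# ---------------------------------------------------------------------------

def wilcoxon_enumeration_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by brute-force enumeration of all 2^n
    sign assignments under the observed tie structure (midranks)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w_min = min(w_plus, w_minus)
    w_all = [
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in itertools.product([1, -1], repeat=n)
    ]
    p = 2.0 * np.mean([w <= w_min + 1e-9 for w in w_all])
    return float(min(p, 1.0))


def hypergeom_tail_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p by direct hypergeometric pmf summation.

    Table rows (a, b) / (c, d): draws of size a+b from a universe of
    a+b+c+d containing a+c successes; p = P(X >= a).
    """
    n = a + b + c + d
    k_draw = a + b
    k_succ = a + c
    denom = comb(n, k_draw)
    upper = min(k_draw, k_succ)
    return sum(comb(k_succ, x) * comb(n - k_succ, k_draw - x) for x in range(a, upper + 1)) / denom


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140508)


@pytest.fixture
def small_collection() -> GeneSetCollection:
    """Three disjoint genesets over a 60-gene universe."""
    genes = [f"G{i:03d}" for i in range(60)]
    sets = {
        f"SET:{k}": GeneSet(f"SET:{k}", f"set {k}", frozenset(genes[20 * k : 20 * (k + 1)]))
        for k in range(3)
    }
    return GeneSetCollection(sets, min_size=5, max_size=500)


def make_random_pair(rng: np.random.Generator, genes: list[str], pair_id: str = "p") -> SamplePair:
    index = pd.Index(genes, name="gene")
    control = rng.normal(6, 2, size=len(genes))
    case = control + rng.normal(0, 0.5, size=len(genes))
    return SamplePair(pair_id, pd.Series(case, index=index), pd.Series(control, index=index))


@pytest.fixture
def null_pair(rng, small_collection) -> SamplePair:
    genes = sorted(small_collection.all_members())
    return make_random_pair(rng, genes)
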