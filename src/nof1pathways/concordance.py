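"""Agreement between mechanism lists: overlap odds ratios and PR curves.

Two methods (or two studies) each produce a ranked list of significant
mechanisms drawn from a shared universe of testable genesets. Agreement is
quantified two ways:

* a 2x2 overlap table (#shared, #only-in-1) x (#only-in-2, #in-neither)
  with a Fisher-exact p (equivalently a hypergeometric tail) and an odds
  ratio, Haldane-Anscombe-corrected when a cell is zero;
* precision-recall curves against a proxy gold standard, sweeping cutoffs
  down the ranked list. Matching is exact set_id identity, or relaxed to
  ontology relatedness (Jiang ITS >= 0.7) so that a prediction naming a
  closely related GO term still counts as a true positive. ITS matching
  only applies to ontology terms, not to KEGG-style identifiers.

Ties in the ranking key enter a curve as one cutoff group (all-or-none),
so no arbitrary within-tie order influences the curve. For recall, each
gold term is counted at most once however many predictions match it; for
precision, every matching prediction is a true positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import odds_ratio
from .similarity import ICTable, Ontology, jiang_its

__all__ = [
    "MechanismList",
    "OverlapStats",
    "PRPoint",
    "PRCurve",
    "overlap_or",
    "precision_recall",
    "read_external_ranking",
]


@dataclass
class MechanismList:
    """A ranked mechanism list: (set_id, rank_key) pairs, best first.

    ``ascending=True`` means smaller rank_key is better (p-values);
    ``False`` means larger is better (sample counts, NES).
    """

    method_label: str
    entries: list[tuple[str, float]]
    universe: frozenset[str]
    ascending: bool = True

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate set_ids in mechanism list: {dupes[:5]}")

    @property
    def set_ids(self) -> list[str]:
        return [sid for sid, _ in self.entries]

    def ranked(self) -> list[tuple[str, float]]:
        """Entries sorted best-first by rank_key (stable)."""
        return sorted(self.entries, key=lambda e: e[1] if self.ascending else -e[1])


@dataclass
class OverlapStats:
    n_overlap: int
    n_only_1: int
    n_only_2: int
    n_neither: int
    odds_ratio: float
    odds_ratio_corrected: float
    p_value: float
    universe_size: int


@dataclass
class PRPoint:
    cutoff: int
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int


@dataclass
class PRCurve:
    points: list[PRPoint]
    matching: str  # {"exact", "its_0.7"}
    gold_standard_label: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": [p.cutoff for p in self.points],
                "precision": [p.precision for p in self.points],
                "recall": [p.recall for p in self.points],
                "tp": [p.tp for p in self.points],
                "fp": [p.fp for p in self.points],
                "fn": [p.fn for p in self.points],
            }
        )


def overlap_or(
    list1: MechanismList,
    list2: MechanismList,
    universe: set[str],
    alternative: str = "greater",
) -> OverlapStats:
    """Overlap 2x2 between two mechanism lists over a shared universe.

    Cells: (a) in both, (b) only list1, (c) only list2, (d) in neither;
    p from Fisher's exact test (one-sided enrichment by default, which for
    this table equals the hypergeometric tail). Symmetric in its two lists.
    """
    s1, s2 = set(list1.set_ids), set(list2.set_ids)
    if not (s1 | s2) <= set(universe):
        extra = sorted((s1 | s2) - set(universe))[:5]
        raise ValueError(f"universe does not cover both lists (e.g. {extra})")
    a = len(s1 & s2)
    b = len(s1 - s2)
    c = len(s2 - s1)
    d = len(universe) - a - b - c
    raw_or, corr_or = odds_ratio(a, b, c, d)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])
    return OverlapStats(a, b, c, d, raw_or, corr_or, p, len(universe))


def _tie_groups(entries: list[tuple[str, float]]) -> list[list[str]]:
    return [[sid for sid, _ in grp] for _, grp in groupby(entries, key=lambda e: e[1])]


def precision_recall(
    predictions: MechanismList,
    gold: set[str],
    matching: str = "exact",
    its_context: tuple[Ontology, ICTable] | None = None,
    its_threshold: float = 0.7,
    gold_label: str = "gold",
) -> PRCurve:
    """Precision-recall of a ranked mechanism list against a gold standard.

    At each cutoff k down the ranking (tied rank keys enter together), a
    retained prediction is a true positive if it is in the gold set
    (``matching='exact'``) or related to some gold term at ITS >=
    ``its_threshold`` (``matching='its_0.7'``, requires ``its_context``).
    precision = TP/(TP+FP); recall = matched gold terms / |gold|;
    fn = gold terms not matched by any retained prediction.
    """
    if not gold:
        raise ValueError("gold standard is empty")
    if matching not in ("exact", "its_0.7"):
        raise ValueError(f"matching must be 'exact' or 'its_0.7', got {matching!r}")
    if matching == "its_0.7":
        if its_context is None:
            raise ValueError("ITS matching requires (Ontology, ICTable) context")
        ontology, ic = its_context
        unscored = [t for t in list(predictions.set_ids) + sorted(gold) if t not in ic]
        if unscored:
            raise ValueError(
                "ITS matching is only applicable to ontology terms with information "
                f"content; unscored ids (e.g. KEGG pathways): {unscored[:5]}"
            )

    points: list[PRPoint] = []
    tp = fp = 0
    matched_gold: set[str] = set()
    cutoff = 0
    for group in _tie_groups(predictions.ranked()):
        for sid in group:
            if matching == "exact":
                hits = {sid} & gold
            else:
                # recall credits every gold term this prediction is related to
                sims = {g: jiang_its(sid, g, ontology, ic) for g in gold}
                hits = {g for g, s in sims.items() if s >= its_threshold}
            hit = bool(hits)
            if hit:
                tp += 1
                matched_gold |= hits
            else:
                fp += 1
        cutoff += len(group)
        points.append(
            PRPoint(
                cutoff=cutoff,
                precision=tp / (tp + fp) if tp + fp else 0.0,
                recall=len(matched_gold) / len(gold),
                tp=tp,
                fp=fp,
                fn=len(gold) - len(matched_gold),
            )
        )
    return PRCurve(points, matching=matching, gold_standard_label=gold_label)


def read_external_ranking(
    path: str | Path,
    method_label: str,
    set_id_column: str = "set_id",
    rank_column: str = "p_value",
    ascending: bool = True,
    universe: set[str] | None = None,
) -> MechanismList:
    """Ingest an externally produced ranked mechanism table (e.g. GSEA report).

    The TSV must carry a set-id column and a numeric ranking column; the
    caller declares which direction of the ranking key is better.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in (set_id_column, rank_column):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r} (have {list(df.columns)})")
    if df.empty:
        import warnings

        warnings.warn(f"{path}: empty ranking file", stacklevel=2)
    ids = df[set_id_column].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"{path}: duplicate set_ids {dupes[:5]}")
    entries = list(zip(ids, pd.to_numeric(df[rank_column]).astype(float)))
    univ = frozenset(universe) if universe is not None else frozenset(ids)
    return MechanismList(method_label, entries, univ, ascending=ascending)
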