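"""Cross-sample prioritization of mechanisms.

Single-pair results generalize to a cohort by counting, per geneset, the
number of pairs in which it reaches Bonferroni significance (default
alpha 1%). Mechanisms significant in at least one pair are listed from the
most to the least commonly observed; equal counts are ordered by the
magnitude of the mean signed Z (stronger shared signal first), then by
set_id for determinism. The per-pair signed Z matrix is kept alongside for
within- and cross-sample comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import PairResult

__all__ = ["PrioritizedMechanism", "CohortPrioritization", "prioritize", "concordance_matrix",
           "write_prioritization", "read_prioritization"]


@dataclass
class PrioritizedMechanism:
    set_id: str
    name: str
    n_significant_pairs: int
    per_pair_z: dict[str, float]  # pair_id -> signed z (all pairs, significant or not)
    summary_z: float
    rank: int


@dataclass
class CohortPrioritization:
    entries: list[PrioritizedMechanism]
    alpha_bonf: float
    pair_ids: list[str]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def set_ids(self) -> list[str]:
        return [e.set_id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {
                "set_id": e.set_id,
                "name": e.name,
                "n_significant_pairs": e.n_significant_pairs,
                "summary_z": e.summary_z,
                "rank": e.rank,
            }
            row.update({f"z_{pid}": e.per_pair_z[pid] for pid in self.pair_ids})
            rows.append(row)
        cols = ["set_id", "name", "n_significant_pairs", "summary_z", "rank"] + [
            f"z_{pid}" for pid in self.pair_ids
        ]
        return pd.DataFrame(rows, columns=cols)


def _check_universes(results: list[PairResult]) -> list[str]:
    if not results:
        raise ValueError("at least one pair result is required")
    reference = set(results[0].set_ids)
    for r in results[1:]:
        other = set(r.set_ids)
        if other != reference:
            missing = sorted(reference ^ other)[:10]
            raise ValueError(
                f"pair {r.pair_id!r} was scored against a different geneset universe "
                f"(symmetric difference includes {missing})"
            )
    return results[0].set_ids


def prioritize(results: list[PairResult], alpha_bonf: float = 0.01) -> CohortPrioritization:
    """Rank mechanisms by how many pairs reach Bonferroni significance.

    Genesets significant in zero pairs are excluded. Sorting is by count
    descending, then ``|summary_z|`` descending, then set_id; ranks are
    1-based in that order. ``summary_z`` is the unweighted mean of the
    per-pair signed Z-scores over all pairs.
    """
    set_ids = _check_universes(results)
    pair_ids = [r.pair_id for r in results]
    by_pair = [{s.set_id: s for s in r.scores} for r in results]
    names = {s.set_id: s.name for s in results[0].scores}

    entries = []
    for sid in set_ids:
        zs = {pid: by_pair[i][sid].z for i, pid in enumerate(pair_ids)}
        count = sum(1 for i in range(len(results)) if by_pair[i][sid].p_bonf <= alpha_bonf)
        if count >= 1:
            entries.append(
                PrioritizedMechanism(
                    set_id=sid,
                    name=names[sid],
                    n_significant_pairs=count,
                    per_pair_z=zs,
                    summary_z=float(np.mean(list(zs.values()))),
                    rank=0,
                )
            )
    entries.sort(key=lambda e: (-e.n_significant_pairs, -abs(e.summary_z), e.set_id))
    for i, e in enumerate(entries, start=1):
        e.rank = i
    return CohortPrioritization(entries, alpha_bonf=alpha_bonf, pair_ids=pair_ids)


def concordance_matrix(results: list[PairResult], alpha_bonf: float = 0.01) -> pd.DataFrame:
    """Signed-Z matrix (genesets x pairs) for mechanisms significant in >= 1 pair.

    Signs are preserved per pair, so a mechanism up-regulated in one pair
    and down-regulated in another shows opposite signs in its row.
    """
    prio = prioritize(results, alpha_bonf=alpha_bonf)
    data = {pid: [e.per_pair_z[pid] for e in prio.entries] for pid in prio.pair_ids}
    return pd.DataFrame(data, index=pd.Index(prio.set_ids, name="set_id"))


def write_prioritization(prio: CohortPrioritization, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# alpha_bonf={prio.alpha_bonf}\tpairs={','.join(prio.pair_ids)}\n")
        prio.to_frame().to_csv(fh, sep="\t", index=False)


def read_prioritization(path: str | Path) -> pd.DataFrame:
    """Read a prioritization TSV back as a DataFrame (for list comparisons)."""
    return pd.read_csv(path, sep="\t", comment="#")
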