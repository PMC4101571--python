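"""Synthetic paired transcriptomes, cohorts and toy ontologies.

Generators that emulate the data shapes the pipeline consumes, so every
module is testable without downloads: a single case/control pair with
planted coherently-shifted genesets (the 1-vs-1 RNA-Seq design), replicate
cohorts with shared and pair-private planted mechanisms (the 4-KD vs
8-control microarray design), and small annotated ontologies for the
semantic-similarity layer.

Model: control expression is Gaussian on the log2 scale,
``control_g ~ N(baseline_mean, baseline_sd^2)``; the paired case profile
adds independent noise ``eps_g ~ N(0, noise_sd^2)`` and, for genes of a
planted geneset, a coherent shift of +/- ``effect_size`` log2 units.
Heavy-tailed noise (Student t, 3 df, scaled to the same sd) is available to
exercise the rank statistic's robustness. Defaults (baseline 6 +/- 2 log2
units, noise sd 0.5, effect 1 log2 unit, set sizes 15-50) are scaled so
full simulation suites run in seconds.

Everything is reproducible: a fixed seed yields byte-identical written
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geneset_io import ExpressionMatrix, GeneSet, GeneSetCollection, SamplePair
from .similarity import Ontology, propagate_annotations

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_genesets",
    "simulate_pair",
    "simulate_cohort",
    "simulate_replicate_groups",
    "make_toy_ontology",
    "write_obo",
    "write_truth",
]


@dataclass
class SimulationConfig:
    """Knobs for the paired-transcriptome generator (log2 scale throughout)."""

    n_genes: int = 5000
    n_sets: int = 200
    set_size_range: tuple[int, int] = (15, 50)
    n_planted: int = 1
    effect_size: float = 1.0     # coherent log2 shift of planted sets
    noise_sd: float = 0.5        # sd of the paired difference noise
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    n_pairs: int = 1
    seed: int = 0
    heavy_tailed: bool = False   # t(3) noise scaled to noise_sd instead of Gaussian
    planted_fraction: float = 1.0  # fraction of a planted set's genes that shift

    def __post_init__(self) -> None:
        lo, hi = self.set_size_range
        if min(self.n_genes, self.n_sets, lo, hi) <= 0 or lo > hi:
            raise ValueError("counts must be positive and set_size_range ordered")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")
        if not (0 < self.planted_fraction <= 1):
            raise ValueError("planted_fraction must be in (0, 1]")


@dataclass
class GroundTruth:
    """Which genesets were planted, with direction, and in which pairs."""

    planted_sets: dict[str, str]  # set_id -> {"up", "down"}
    per_pair_planting: dict[str, set[str]] = field(default_factory=dict)


def _gene_universe(n_genes: int) -> list[str]:
    width = len(str(n_genes))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def make_genesets(
    config: SimulationConfig, disjoint: bool = False
) -> tuple[GeneSetCollection, list[str]]:
    """Draw a reproducible geneset collection over a synthetic gene universe.

    With ``disjoint=True`` sets share no genes (needed by type-I-error
    suites, where dependence between overlapping sets would distort the
    empirical rejection rate).
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config.n_genes)
    lo, hi = config.set_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_sets)
    sets: dict[str, GeneSet] = {}
    if disjoint:
        if int(sizes.sum()) > config.n_genes:
            raise ValueError(
                f"cannot draw {config.n_sets} disjoint sets (total {int(sizes.sum())} genes) "
                f"from {config.n_genes} genes"
            )
        pool = rng.permutation(config.n_genes)
        start = 0
        for k, size in enumerate(sizes):
            idx = pool[start : start + size]
            start += size
            sid = f"SET:{k + 1:04d}"
            sets[sid] = GeneSet(sid, f"synthetic set {k + 1}", frozenset(genes[i] for i in idx))
    else:
        for k, size in enumerate(sizes):
            idx = rng.choice(config.n_genes, size=size, replace=False)
            sid = f"SET:{k + 1:04d}"
            sets[sid] = GeneSet(sid, f"synthetic set {k + 1}", frozenset(genes[i] for i in idx))
    lo_f, hi_f = min(lo, 15), max(hi, 500)
    return GeneSetCollection(sets, min_size=lo_f, max_size=hi_f), genes


def _noise(rng: np.random.Generator, size: int, config: SimulationConfig) -> np.ndarray:
    if config.heavy_tailed:
        # t(3) has variance 3; rescale to the requested sd
        return rng.standard_t(3, size=size) * (config.noise_sd / np.sqrt(3.0))
    return rng.normal(0.0, config.noise_sd, size=size)


def simulate_pair(
    collection: GeneSetCollection,
    truth: GroundTruth,
    config: SimulationConfig,
    genes: list[str] | None = None,
    rng: np.random.Generator | None = None,
    pair_id: str = "pair1",
) -> SamplePair:
    """One paired profile with the truth's genesets coherently shifted.

    Control values are the gene baselines; the case adds paired noise, plus
    +effect_size (up) or -effect_size (down) on planted genes. With
    ``planted_fraction < 1`` only a random subset of each planted set
    shifts (partial-planting model).
    """
    for sid in truth.planted_sets:
        if sid not in collection:
            raise KeyError(f"planted set {sid!r} not in collection")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if genes is None:
        genes = sorted({g for gs in collection for g in gs.members})
    index = pd.Index(genes, name="gene")
    pos = {g: i for i, g in enumerate(genes)}

    control = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    case = control + _noise(rng, len(genes), config)
    for sid, direction in sorted(truth.planted_sets.items()):
        members = sorted(collection[sid].members)
        if config.planted_fraction < 1.0:
            k = max(1, int(round(config.planted_fraction * len(members))))
            members = list(rng.choice(members, size=k, replace=False))
        shift = config.effect_size if direction == "up" else -config.effect_size
        for g in members:
            case[pos[g]] += shift
    return SamplePair(pair_id, pd.Series(case, index=index), pd.Series(control, index=index))


def simulate_cohort(
    collection: GeneSetCollection,
    shared_sets: dict[str, str],
    private_sets_per_pair: list[dict[str, str]],
    config: SimulationConfig,
    genes: list[str] | None = None,
) -> tuple[list[SamplePair], GroundTruth]:
    """A cohort of pairs with shared and pair-private planted mechanisms.

    ``shared_sets`` (set_id -> direction) are planted in every pair;
    ``private_sets_per_pair[i]`` only in pair i. Shared and private ids
    must not overlap. Emulates a design where a core response is common to
    all samples while some mechanisms are tissue- or sample-specific.
    """
    n_pairs = len(private_sets_per_pair)
    if n_pairs == 0:
        raise ValueError("need at least one pair (pass [{}] for no private sets)")
    all_private = [sid for d in private_sets_per_pair for sid in d]
    if set(shared_sets) & set(all_private):
        raise ValueError("shared and private planted sets overlap")
    if len(all_private) != len(set(all_private)):
        raise ValueError("a private set is planted in more than one pair")

    rng = np.random.default_rng(config.seed)
    pairs: list[SamplePair] = []
    per_pair: dict[str, set[str]] = {}
    for i, private in enumerate(private_sets_per_pair):
        pid = f"pair{i + 1}"
        planted = {**shared_sets, **private}
        truth_i = GroundTruth(planted_sets=planted)
        pairs.append(simulate_pair(collection, truth_i, config, genes=genes, rng=rng, pair_id=pid))
        per_pair[pid] = set(planted)
    truth = GroundTruth(
        planted_sets={**shared_sets, **{k: v for d in private_sets_per_pair for k, v in d.items()}},
        per_pair_planting=per_pair,
    )
    return pairs, truth


def simulate_replicate_groups(
    collection: GeneSetCollection,
    truth: GroundTruth,
    config: SimulationConfig,
    n_case: int = 4,
    n_control: int = 8,
    genes: list[str] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Replicated case/control matrices (log2) for group-level DEG calling.

    Every replicate shares the gene baselines; case replicates carry the
    planted shifts. Mirrors a 4-knockdown vs 8-control design.
    """
    rng = np.random.default_rng(config.seed)
    if genes is None:
        genes = sorted({g for gs in collection for g in gs.members})
    index = pd.Index(genes, name="gene")
    pos = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    shift = np.zeros(len(genes))
    for sid, direction in sorted(truth.planted_sets.items()):
        s = config.effect_size if direction == "up" else -config.effect_size
        for g in collection[sid].members:
            shift[pos[g]] += s

    def _replicates(n: int, shifted: bool, label: str) -> ExpressionMatrix:
        cols = {}
        for j in range(n):
            vals = baseline + _noise(rng, len(genes), config)
            if shifted:
                vals = vals + shift
            cols[f"{label}{j + 1}"] = vals
        return ExpressionMatrix(pd.DataFrame(cols, index=index), "log2")

    control_mat = _replicates(n_control, False, "CTL")
    case_mat = _replicates(n_case, True, "KD")
    return case_mat, control_mat


# ---------------------------------------------------------------------------
# toy ontologies
# ---------------------------------------------------------------------------

def make_toy_ontology(
    depth: int,
    branching: int,
    genes_per_leaf: int,
    seed: int = 0,
    diamond_prob: float = 0.0,
    namespace: str = "biological_process",
) -> tuple[Ontology, dict[str, set[str]]]:
    """A balanced is_a tree with optional diamond edges, plus leaf annotations.

    ``depth`` levels below a single root, ``branching`` children per node:
    e.g. depth 2, branching 2 gives 7 terms and 6 edges. Each leaf gets
    ``genes_per_leaf`` distinct genes (drawn without replacement from a
    shared gene pool), so internal-term annotations arise purely by
    propagation. ``diamond_prob`` adds, per non-root term, a second parent
    drawn from the level above with that probability.
    """
    if depth < 1 or branching < 1 or genes_per_leaf < 1:
        raise ValueError("depth, branching and genes_per_leaf must be >= 1")
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    counter = [0]

    def new_term() -> str:
        counter[0] += 1
        return f"T:{counter[0]:07d}"

    root = new_term()
    g.add_node(root, name="root")
    levels = [[root]]
    for level in range(1, depth + 1):
        current = []
        for parent in levels[-1]:
            for _ in range(branching):
                t = new_term()
                g.add_node(t, name=f"term {t[2:].lstrip('0')}")
                g.add_edge(t, parent)
                current.append(t)
        levels.append(current)
    if diamond_prob > 0:
        for level in range(2, depth + 1):
            for t in levels[level]:
                if rng.random() < diamond_prob:
                    extra = levels[level - 1][int(rng.integers(len(levels[level - 1])))]
                    if not g.has_edge(t, extra):
                        g.add_edge(t, extra)

    leaves = levels[-1]
    n_genes = genes_per_leaf * len(leaves)
    pool = rng.permutation([f"g{i + 1:05d}" for i in range(n_genes)])
    direct: dict[str, set[str]] = {}
    for i, leaf in enumerate(leaves):
        direct[leaf] = set(pool[i * genes_per_leaf : (i + 1) * genes_per_leaf])
    return Ontology(g, namespace=namespace), direct


def write_obo(ontology: Ontology, path: str | Path, namespace: str | None = None) -> None:
    """Serialize an ontology as a minimal OBO 1.2 flat file (deterministic)."""
    ns = namespace or ontology.namespace or "biological_process"
    lines = ["format-version: 1.2", ""]
    for term in sorted(ontology.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {ontology.graph.nodes[term].get('name', term)}")
        lines.append(f"namespace: {ns}")
        for parent in sorted(ontology.parents(term)):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_annotations(direct: dict[str, set[str]], path: str | Path) -> None:
    """Write direct annotations as a 2-column gene TAB term TSV (deterministic)."""
    with open(path, "w") as fh:
        for term in sorted(direct):
            for gene in sorted(direct[term]):
                fh.write(f"{gene}\t{term}\n")


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "planted_sets": dict(sorted(truth.planted_sets.items())),
        "per_pair_planting": {k: sorted(v) for k, v in sorted(truth.per_pair_planting.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
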