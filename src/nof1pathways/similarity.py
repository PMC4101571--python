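"""Information-theoretic similarity between ontology terms.

Mechanism lists from different samples or methods rarely overlap exactly
even when they describe the same biology, because ontology terms at
different granularities name overlapping processes. Jiang's
information-theoretic similarity (ITS) quantifies term relatedness from an
annotation corpus: a term's information content (IC) is the negative log of
its annotation frequency (annotations propagated up the DAG), and the
semantic distance between two terms is

    dist(a, b) = IC(a) + IC(b) - 2 IC(MICA(a, b))

where MICA is the most informative common ancestor. With IC normalized to
[0, 1] by the corpus maximum, ITS = 1 - dist/2 ranges from 0 (no
similarity) to 1 (exact match). A pair with ITS >= 0.7 is treated as
"highly related" throughout the evaluation utilities.

The ontology is held as a networkx DiGraph with child -> parent edges
(``is_a`` and, by default, ``part_of``), read from OBO 1.2 flat files via
obonet; annotations come from GAF 2.x or a 2-column gene/term TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

__all__ = [
    "Ontology",
    "AnnotationCorpus",
    "ICTable",
    "read_obo",
    "read_annotations",
    "propagate_annotations",
    "compute_ic",
    "jiang_its",
    "best_match_related",
]


@dataclass
class Ontology:
    """A namespace-restricted is_a/part_of DAG with child->parent edges."""

    graph: nx.DiGraph
    namespace: str | None = None

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"ontology contains a cycle: {cycle}")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable upward from ``term`` (excluding itself)."""
        return nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        """All terms below ``term`` (excluding itself)."""
        return nx.ancestors(self.graph, term)


@dataclass
class AnnotationCorpus:
    """Direct and DAG-propagated term -> gene maps."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]
    n_skipped: int = 0  # annotations to terms absent from the ontology

    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.direct.values():
            out |= genes
        return frozenset(out)


@dataclass
class ICTable:
    """Normalized information content per term; unannotated terms are unscored."""

    ic: dict[str, float]
    max_raw_ic: float

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __getitem__(self, term: str) -> float:
        if term not in self.ic:
            raise KeyError(f"term {term!r} has no information content (no propagated annotations)")
        return self.ic[term]


def read_obo(
    path: str | Path,
    namespace: str | None = None,
    include_part_of: bool = True,
) -> Ontology:
    """Load an OBO 1.2 ontology as a child->parent DAG.

    Obsolete terms are dropped. ``namespace`` (e.g. ``biological_process``)
    restricts the graph to one sub-ontology; an unknown namespace is an
    error. ``part_of`` relations are treated as hierarchical by default,
    matching how gene annotations are conventionally propagated.
    """
    multi = obonet.read_obo(str(path))  # obonet skips obsolete terms by default
    relations = {"is_a"} | ({"part_of"} if include_part_of else set())
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        if namespace is not None and data.get("namespace") != namespace:
            continue
        g.add_node(node, name=data.get("name", node))
    if namespace is not None and g.number_of_nodes() == 0:
        known = sorted({d.get("namespace") for _, d in multi.nodes(data=True) if d.get("namespace")})
        raise ValueError(f"namespace {namespace!r} not found in {path} (known: {known})")
    for child, parent, key in multi.edges(keys=True):
        if key in relations and child in g and parent in g:
            g.add_edge(child, parent)
    return Ontology(g, namespace=namespace)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read term -> genes annotations from GAF 2.x or a 2-column gene/term TSV.

    GAF lines (>= 15 columns, ``!`` comments) use the gene symbol (col 3)
    and term id (col 5); the plain format is one ``gene TAB term`` per line.
    """
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 15:  # GAF
                gene, term = fields[2], fields[4]
            elif len(fields) == 2:
                gene, term = fields
            else:
                raise ValueError(f"{path}: cannot interpret annotation line with {len(fields)} fields")
            direct.setdefault(term, set()).add(gene)
    return direct


def propagate_annotations(ontology: Ontology, direct: dict[str, set[str]]) -> AnnotationCorpus:
    """Propagate gene annotations up the DAG (true-path rule).

    ``propagated[t]`` is the union of direct annotations over ``t`` and all
    of its descendants, so every term inherits the genes of its children.
    Annotations to terms absent from the ontology are skipped and counted.
    """
    known = {t: frozenset(genes) for t, genes in direct.items() if t in ontology.terms}
    n_skipped = sum(len(genes) for t, genes in direct.items() if t not in ontology.terms)

    propagated: dict[str, set[str]] = {}
    # children precede parents in a topological order of child->parent edges
    for term in nx.topological_sort(ontology.graph):
        acc = set(known.get(term, ()))
        for child in ontology.children(term):
            acc |= propagated[child]
        propagated[term] = acc
    return AnnotationCorpus(
        direct={t: known.get(t, frozenset()) for t in ontology.terms},
        propagated={t: frozenset(g) for t, g in propagated.items()},
        n_skipped=n_skipped,
    )


def compute_ic(ontology: Ontology, corpus: AnnotationCorpus) -> ICTable:
    """Normalized information content from propagated annotation frequencies.

    ``p(t)`` is the propagated annotation count over the corpus total (the
    union of root annotations); ``raw_ic = -ln p``; normalized IC divides
    by the corpus maximum so the rarest annotated term has IC 1 and roots
    have IC 0. Terms with no propagated annotations are left unscored.
    """
    import math

    total_genes: set[str] = set()
    for root in ontology.roots:
        total_genes |= corpus.propagated.get(root, frozenset())
    n_total = len(total_genes)
    if n_total == 0:
        raise ValueError("annotation corpus is empty: no genes reach an ontology root")
    raw = {
        t: -math.log(len(genes) / n_total)
        for t, genes in corpus.propagated.items()
        if len(genes) > 0
    }
    max_raw = max(raw.values())
    if max_raw == 0:  # every annotated term covers the whole corpus
        return ICTable({t: 0.0 for t in raw}, 0.0)
    return ICTable({t: v / max_raw for t, v in raw.items()}, max_raw)


def _common_ancestors(ontology: Ontology, a: str, b: str) -> set[str]:
    return (ontology.ancestors(a) | {a}) & (ontology.ancestors(b) | {b})


def mica(ontology: Ontology, ic: ICTable, a: str, b: str) -> tuple[str | None, float]:
    """Most informative common ancestor and its IC (0 if none is scored)."""
    best_term, best_ic = None, 0.0
    for t in _common_ancestors(ontology, a, b):
        if t in ic and ic[t] >= best_ic:
            if ic[t] > best_ic or best_term is None or t < best_term:
                best_term, best_ic = t, ic[t]
    return best_term, best_ic


def jiang_its(a: str, b: str, ontology: Ontology, ic: ICTable) -> float:
    """Jiang similarity between two scored terms, normalized to [0, 1]."""
    for t in (a, b):
        if t not in ic:
            raise KeyError(f"term {t!r} is unscored (no annotations); cannot compute ITS")
    _, mica_ic = mica(ontology, ic, a, b)
    dist = ic[a] + ic[b] - 2.0 * mica_ic
    its = 1.0 - dist / 2.0
    return float(min(1.0, max(0.0, its)))


def best_match_related(
    term: str,
    reference: set[str],
    ontology: Ontology,
    ic: ICTable,
    threshold: float = 0.7,
) -> tuple[bool, str | None, float]:
    """Is ``term`` related (ITS >= threshold, inclusive) to any reference term?

    Returns ``(related, best_term, best_its)``; an empty reference yields
    ``(False, None, 0.0)``.
    """
    best_term, best_its = None, 0.0
    for ref in sorted(reference):
        s = jiang_its(term, ref, ontology, ic)
        if s > best_its or best_term is None:
            best_term, best_its = ref, s
    if best_term is None:
        return False, None, 0.0
    return best_its >= threshold, best_term, best_its
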