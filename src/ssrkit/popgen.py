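"""Marker utility statistics and phylogeny for SSR genotype panels.

Implements allele-frequency tallies, polymorphic information content
(PIC, Botstein form), Nei's (1983) D_A genetic distance and UPGMA
clustering into an ultrametric tree.

PIC for a marker with allele frequencies p_1..p_n is

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2

and D_A between frequency profiles x and y over L shared markers is

    D_A = 1 - (1/L) sum_l sum_u sqrt(x_lu * y_lu).

Lines (inbred individuals) are treated as taxa: each line's frequency
profile comes from its own calls (a homozygous line has frequency 1 for
its allele, a heterozygous call contributes 1/2 per allele), so D_A
between lines reduces to an allele-sharing measure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .io import MISSING_CALL, GenotypeTable

__all__ = [
    "AlleleFreqs",
    "DistanceMatrix",
    "TreeNode",
    "UltrametricTree",
    "allele_frequencies",
    "line_profiles",
    "pic",
    "expected_heterozygosity",
    "nei_da",
    "distance_matrix",
    "upgma",
    "cut_clusters",
]

Freqs = dict[str, dict[str, float]]  # marker -> allele -> frequency


@dataclass
class AlleleFreqs:
    """Per-marker allele frequency vectors (non-missing calls only)."""

    freqs: Freqs

    @property
    def markers(self) -> list[str]:
        return list(self.freqs)

    def n_alleles(self, marker: str) -> int:
        return len(self.freqs[marker])


def _alleles_of(call: str) -> list[str]:
    if call == MISSING_CALL:
        return []
    return call.split("/") if "/" in call else [call]


def allele_frequencies(table: GenotypeTable) -> AlleleFreqs:
    """Tally allele frequencies per marker across all individuals.

    Heterozygous calls contribute 1/2 per allele; missing calls are
    excluded from the denominator.
    """
    freqs: Freqs = {}
    bad = []
    for marker in table.markers:
        tally: dict[str, float] = {}
        weight = 0.0
        for call in table.calls.loc[marker]:
            alleles = _alleles_of(str(call))
            if not alleles:
                continue
            w = 1.0 / len(alleles)
            for a in alleles:
                tally[a] = tally.get(a, 0.0) + w
            weight += 1.0
        if weight == 0:
            bad.append(marker)
            continue
        freqs[marker] = {a: c / weight for a, c in sorted(tally.items())}
    if bad:
        raise ValueError(f"markers with all calls missing: {bad}")
    return AlleleFreqs(freqs=freqs)


def line_profiles(table: GenotypeTable) -> dict[str, AlleleFreqs]:
    """Per-line frequency profiles ('line mode'): each line's own calls
    define its frequencies; markers missing in a line are omitted from
    that line's profile."""
    profiles: dict[str, AlleleFreqs] = {}
    for ind in table.individuals:
        freqs: Freqs = {}
        for marker in table.markers:
            alleles = _alleles_of(str(table.calls.loc[marker, ind]))
            if alleles:
                w = 1.0 / len(alleles)
                tally: dict[str, float] = {}
                for a in alleles:
                    tally[a] = tally.get(a, 0.0) + w
                freqs[marker] = tally
        profiles[ind] = AlleleFreqs(freqs=freqs)
    return profiles


def pic(frequencies) -> float:
    """Polymorphic information content (Botstein et al. form)."""
    p = np.asarray(list(frequencies), dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    sq = p**2
    cross = (sq.sum() ** 2 - (sq**2).sum())  # 2 * sum_{i<j} p_i^2 p_j^2
    return float(1.0 - sq.sum() - cross)


def expected_heterozygosity(frequencies) -> float:
    """1 - sum p_i^2 (gene diversity); not PIC, provided for comparison."""
    p = np.asarray(list(frequencies), dtype=float)
    return float(1.0 - (p**2).sum())


def nei_da(x: AlleleFreqs, y: AlleleFreqs) -> float:
    """Nei's (1983) D_A distance over the markers shared by both profiles."""
    shared = [m for m in x.freqs if m in y.freqs]
    if not shared:
        raise ValueError("no shared markers between profiles")
    total = 0.0
    for m in shared:
        xf, yf = x.freqs[m], y.freqs[m]
        total += sum(math.sqrt(xf[a] * yf[a]) for a in xf if a in yf)
    return 1.0 - total / len(shared)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        for i in range(n):
            if self.values[i][i] != 0.0:
                raise ValueError("nonzero diagonal")
            for j in range(n):
                d = self.values[i][j]
                if math.isnan(d):
                    raise ValueError("NaN distance")
                if d != self.values[j][i]:
                    raise ValueError("asymmetric matrix")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def distance_matrix(table: GenotypeTable) -> DistanceMatrix:
    """Pairwise line-mode D_A over pairwise-available markers."""
    profiles = line_profiles(table)
    labels = tuple(table.individuals)
    n = len(labels)
    m = [[0.0] * n for _ in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        d = nei_da(profiles[labels[i]], profiles[labels[j]])
        m[i][j] = m[j][i] = d
    return DistanceMatrix(labels=labels, values=tuple(tuple(r) for r in m))


@dataclass(frozen=True)
class TreeNode:
    height: float
    label: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]


@dataclass(frozen=True)
class UltrametricTree:
    root: TreeNode

    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()


def upgma(D: DistanceMatrix) -> UltrametricTree:
    """Size-weighted average-linkage clustering (UPGMA).

    Node height is half the merge distance; ties are broken by the
    smallest (row, column) index pair in the current cluster ordering, so
    the output is fully deterministic.
    """
    n = len(D.labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    nodes: list[TreeNode] = [TreeNode(0.0, label=l) for l in D.labels]
    sizes: list[int] = [1] * n
    dist: list[list[float]] = [list(row) for row in D.values]
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                d = dist[i][j]
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = TreeNode(
            height=d / 2.0, children=(nodes[i], nodes[j])
        )
        # average linkage weighted by cluster sizes
        for k in active:
            if k in (i, j):
                continue
            new_d = (
                sizes[i] * dist[i][k] + sizes[j] * dist[j][k]
            ) / (sizes[i] + sizes[j])
            dist[i][k] = dist[k][i] = new_d
        nodes[i] = merged
        sizes[i] += sizes[j]
        active.remove(j)
    return UltrametricTree(root=nodes[active[0]])


def cut_clusters(tree: UltrametricTree, n: int) -> list[set[str]]:
    """Partition the leaves into n groups by splitting the highest nodes."""
    clusters: list[TreeNode] = [tree.root]
    while len(clusters) < n:
        internal = [c for c in clusters if not c.is_leaf]
        if not internal:
            raise ValueError(f"tree has fewer than {n} leaves")
        tallest = max(internal, key=lambda c: c.height)
        clusters.remove(tallest)
        clusters.extend(tallest.children)
    return [set(c.leaf_labels()) for c in clusters]
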