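"""Canonical motif classification under rotation and reverse complement.

Motifs that are cyclic rotations of one another, or of each other's reverse
complement, describe the same repeat tract read from either strand and at
any phase, so they are pooled into one "classified type".  The class label
is "X/Y" where X is the lexicographically least representative (A<C<G<T)
and Y its reverse complement, e.g. AAT/ATT, CCG/CGG, AT/AT.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

from .scan import PerfectSSR, minimal_period

__all__ = [
    "MotifClass",
    "MotifSpectrum",
    "canonicalize",
    "enumerate_classes",
    "spectrum",
    "species_specific",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class MotifClass:
    """Equivalence class of a motif under rotation + reverse complement."""

    canonical: str

    @property
    def k(self) -> int:
        return len(self.canonical)

    @property
    def label(self) -> str:
        return f"{self.canonical}/{revcomp(self.canonical)}"


def _rotations(motif: str):
    return (motif[i:] + motif[:i] for i in range(len(motif)))


def canonicalize(motif: str) -> MotifClass:
    """Map a motif to its class: least string over the 2k strand/phase variants."""
    if not motif or len(motif) > 6 or set(motif) - set("ACGT"):
        raise ValueError(f"motif must be 1-6 bp over ACGT, got {motif!r}")
    if minimal_period(motif) != len(motif):
        raise ValueError(
            f"{motif!r} has period {minimal_period(motif)}; "
            "report it under the shorter motif"
        )
    rc = revcomp(motif)
    canonical = min(itertools.chain(_rotations(motif), _rotations(rc)))
    return MotifClass(canonical=canonical)


def enumerate_classes(k: int) -> set[MotifClass]:
    """The complete class universe for motif length k (brute force over 4^k)."""
    if not 1 <= k <= 6:
        raise ValueError("k must be in 1..6")
    classes: set[MotifClass] = set()
    for bases in itertools.product("ACGT", repeat=k):
        motif = "".join(bases)
        if minimal_period(motif) != k:
            continue
        classes.add(canonicalize(motif))
    return classes


@dataclass
class MotifSpectrum:
    """Locus counts per motif class plus per-motif-length totals."""

    counts: dict[MotifClass, int]
    k_totals: dict[int, int]

    def percentage_within_k(self, cls: MotifClass) -> float:
        total = self.k_totals.get(cls.k, 0)
        return 100.0 * self.counts.get(cls, 0) / total if total else 0.0

    @property
    def classes(self) -> set[MotifClass]:
        return set(self.counts)


def spectrum(ssrs: list[PerfectSSR]) -> MotifSpectrum:
    """Fold loci onto canonical classes and tally per class and per length."""
    counts: Counter[MotifClass] = Counter()
    k_totals: Counter[int] = Counter()
    for ssr in ssrs:
        cls = canonicalize(ssr.motif)
        counts[cls] += 1
        k_totals[cls.k] += 1
    return MotifSpectrum(counts=dict(counts), k_totals=dict(k_totals))


def species_specific(
    spectra: dict[str, set[MotifClass]]
) -> dict[str, set[MotifClass]]:
    """Classes present in one species and absent from every other."""
    if len(spectra) < 2:
        raise ValueError("need at least 2 species")
    out: dict[str, set[MotifClass]] = {}
    for species, classes in spectra.items():
        others: set[MotifClass] = set()
        for other, other_classes in spectra.items():
            if other != species:
                others |= other_classes
        out[species] = classes - others
    return out
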