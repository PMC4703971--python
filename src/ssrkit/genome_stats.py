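"""Per-genome summary statistics for SSR surveys.

Counts by motif length, density (loci per Mbp), cumulative SSR fraction of
the genome, repeat-number histograms, genic/intergenic location breakdown
and fixed-width window tracks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io import AnnotationFeature
from .scan import PerfectSSR, SSRUnit, count_compound_loci

__all__ = [
    "GenomeSummary",
    "LocationBreakdown",
    "WindowTrack",
    "summarize",
    "repeat_histogram",
    "classify_location",
    "location_breakdown",
    "window_counts",
    "DEFAULT_REPEAT_BINS",
]

DEFAULT_REPEAT_BINS = ((1, 10), (11, 20), (21, None))


@dataclass(frozen=True)
class GenomeSummary:
    counts_by_k: dict[int, int]
    total: int
    compound_loci: int
    cumulative_bp: int
    cumulative_fraction: float
    density: float  # loci per Mbp


def summarize(
    ssrs: list[PerfectSSR], units: list[SSRUnit], genome_bp: int
) -> GenomeSummary:
    """Headline numbers for one genome.

    cumulative_bp sums perfect-locus bases only; compound interruption
    bases are not SSR sequence and are excluded.
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    counts_by_k = Counter(s.k for s in ssrs)
    cumulative_bp = sum(s.length for s in ssrs)
    return GenomeSummary(
        counts_by_k=dict(counts_by_k),
        total=len(ssrs),
        compound_loci=count_compound_loci(units),
        cumulative_bp=cumulative_bp,
        cumulative_fraction=cumulative_bp / genome_bp,
        density=len(ssrs) / (genome_bp / 1e6),
    )


def repeat_histogram(
    ssrs: list[PerfectSSR],
    bins: tuple[tuple[int, int | None], ...] = DEFAULT_REPEAT_BINS,
) -> dict[tuple[int, int | None], int]:
    """Tally loci into repeat-count bins; each locus lands in exactly one."""
    hist = {b: 0 for b in bins}
    for ssr in ssrs:
        for lo, hi in bins:
            if ssr.repeats >= lo and (hi is None or ssr.repeats <= hi):
                hist[(lo, hi)] += 1
                break
        else:
            raise ValueError(f"repeat count {ssr.repeats} falls in no bin")
    return hist


def _overlaps(ssr: PerfectSSR, feat: AnnotationFeature) -> bool:
    return ssr.start <= feat.end and feat.start <= ssr.end


def classify_location(
    ssr: PerfectSSR, features: list[AnnotationFeature]
) -> str:
    """CDS if >=1 bp overlap with any CDS, else genic_non_CDS on gene
    overlap, else intergenic."""
    same = [f for f in features if f.seq_id == ssr.seq_id]
    if any(f.kind == "CDS" and _overlaps(ssr, f) for f in same):
        return "CDS"
    if any(f.kind == "gene" and _overlaps(ssr, f) for f in same):
        return "genic_non_CDS"
    return "intergenic"


@dataclass(frozen=True)
class LocationBreakdown:
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def proportion(self, label: str) -> float:
        return self.counts.get(label, 0) / self.total if self.total else 0.0


def location_breakdown(
    ssrs: list[PerfectSSR], features: list[AnnotationFeature]
) -> LocationBreakdown:
    counts = Counter(classify_location(s, features) for s in ssrs)
    for label in ("CDS", "genic_non_CDS", "intergenic"):
        counts.setdefault(label, 0)
    return LocationBreakdown(counts=dict(counts))


@dataclass
class WindowTrack:
    """Per-window SSR-unit counts per unit_type on each sequence.

    counts[seq_id][window_index][unit_type]; windows tile each sequence
    left to right (the last window may be short); units are assigned by
    their start coordinate.
    """

    window_bp: int
    seq_lengths: dict[str, int]
    counts: dict[str, list[dict[str, int]]] = field(default_factory=dict)

    def n_windows(self, seq_id: str) -> int:
        L = self.seq_lengths[seq_id]
        return (L + self.window_bp - 1) // self.window_bp


def window_counts(
    units: list[SSRUnit], seq_lengths: dict[str, int], window_bp: int = 1_000_000
) -> WindowTrack:
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    track = WindowTrack(window_bp=window_bp, seq_lengths=dict(seq_lengths))
    for sid, L in seq_lengths.items():
        n = (L + window_bp - 1) // window_bp
        track.counts[sid] = [{} for _ in range(n)]
    for u in units:
        idx = (u.start - 1) // window_bp
        bucket = track.counts[u.seq_id][idx]
        bucket[u.unit_type] = bucket.get(u.unit_type, 0) + 1
    return track
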