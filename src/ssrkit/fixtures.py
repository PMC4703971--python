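"""Deterministic synthetic fixtures: genomes with planted SSRs and truth
tables, duplicated-region genomes for uniqueness testing, annotation sets
and genotype panels with known group structure.

Every generator is a pure function of its arguments and seed; truth tables
are validated against the generated sequence before being returned.  The
backgrounds emulate intergenic plant DNA only as an i.i.d. base stream at a
chosen GC content — no repeat families, gene models or isochores — so
passing tests demonstrate correctness of the algorithms, not performance on
the long-range structure of real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeTable, SequenceRecord
from .motifs import MotifClass, canonicalize
from .scan import PerfectSSR, ScanConfig, SSRUnit, minimal_period, scan_perfect

__all__ = [
    "PlantSpec",
    "TruthTable",
    "make_genome",
    "make_duplicated_genome",
    "make_uniqueness_benchmark",
    "simulate_genotypes",
    "ssr_free_background",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def ssr_free_background(
    length: int,
    gc: float,
    rng: np.random.Generator,
    config: ScanConfig | None = None,
    max_rounds: int = 60,
) -> str:
    """Random DNA guaranteed to contain no qualifying SSR.

    Draws an i.i.d. sequence, scans it, and breaks every detected run by
    mutating its central base; repeats until the scan is clean (each round
    at least halves every run, so convergence is fast).
    """
    config = config or ScanConfig()
    s = list(_random_dna(length, gc, rng))
    for _ in range(max_rounds):
        loci = scan_perfect(SequenceRecord("bg", "".join(s)), config)
        if not loci:
            return "".join(s)
        for locus in loci:
            mid = (locus.start + locus.end) // 2 - 1  # 0-based
            current = s[mid]
            neighbours = {s[mid - 1] if mid > 0 else "", s[mid + 1] if mid + 1 < len(s) else ""}
            choices = [b for b in "ACGT" if b != current and b not in neighbours]
            s[mid] = choices[int(rng.integers(len(choices)))]
    raise RuntimeError("background sanitization did not converge")


def _fix_boundary(
    bg: str,
    rng: np.random.Generator,
    first_not: str | None = None,
    last_not: str | None = None,
) -> str:
    """Stop a background chunk from extending a neighbouring repeat run.

    A planted run can only extend left if the base before it equals the
    motif's last base, and right if the base after it equals the motif's
    first base, so masking those two boundary characters suffices.
    """
    chars = list(bg)
    forbidden_first = {first_not} | ({last_not} if len(chars) == 1 else set())
    if chars and chars[0] in forbidden_first:
        options = [b for b in "ACGT" if b not in forbidden_first]
        chars[0] = options[int(rng.integers(len(options)))]
    if last_not and len(chars) > 1 and chars[-1] == last_not:
        options = [b for b in "ACGT" if b != last_not]
        chars[-1] = options[int(rng.integers(len(options)))]
    return "".join(chars)


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for a genome with planted SSRs.

    plants is a list of (motif, repeats, gap_to_next) tuples; gap_to_next
    is the exact number of background bases before the next plant (None =
    a neutral spacer of spacer_bp, which must exceed the compound
    threshold so unconnected plants never merge).
    """

    plants: tuple[tuple[str, int, int | None], ...]
    gc: float = 0.42
    flank_bp: int = 600
    spacer_bp: int = 600
    seq_id: str = "chr1"

    def __post_init__(self) -> None:
        for motif, repeats, gap in self.plants:
            if minimal_period(motif) != len(motif):
                raise ValueError(f"plant motif {motif!r} is not minimal-period")
            if gap is not None and gap < 0:
                raise ValueError("gap_to_next must be >= 0")


@dataclass
class TruthTable:
    """Ground truth for a generated genome."""

    loci: list[PerfectSSR]
    units: list[SSRUnit]
    classes: dict[MotifClass, int] = field(default_factory=dict)


def _truth_units(loci: list[PerfectSSR], config: ScanConfig) -> list[SSRUnit]:
    """Chain truth loci by the pairwise gap rule (independent of merge_units)."""
    units: list[SSRUnit] = []
    i = 0
    while i < len(loci):
        members = [loci[i]]
        gaps: list[int] = []
        while i + 1 < len(loci):
            gap = loci[i + 1].start - loci[i].end - 1
            if gap > config.max_interruption:
                break
            members.append(loci[i + 1])
            gaps.append(gap)
            i += 1
        units.append(SSRUnit(tuple(members), tuple(gaps)))
        i += 1
    return units


def make_genome(
    spec: PlantSpec,
    seed: int = 0,
    config: ScanConfig | None = None,
    max_attempts: int = 20,
) -> tuple[SequenceRecord, TruthTable]:
    """Build a genome whose only qualifying SSRs are the planted ones.

    The assembled sequence is re-scanned and must match the truth table
    exactly (a junction between background and a plant can in rare cases
    create or extend a run; such draws are rejected and regenerated).
    """
    config = config or ScanConfig()
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        parts: list[str] = []
        loci: list[PerfectSSR] = []
        pos = 1
        lead = _fix_boundary(
            ssr_free_background(spec.flank_bp, spec.gc, rng, config),
            rng,
            last_not=spec.plants[0][0][-1],
        )
        parts.append(lead)
        pos += len(lead)
        for idx, (motif, repeats, gap) in enumerate(spec.plants):
            tract = motif * repeats
            loci.append(
                PerfectSSR(
                    seq_id=spec.seq_id,
                    motif=motif,
                    repeats=repeats,
                    start=pos,
                    end=pos + len(tract) - 1,
                )
            )
            parts.append(tract)
            pos += len(tract)
            if idx < len(spec.plants) - 1:
                fill = gap if gap is not None else spec.spacer_bp
                if fill:
                    bg = _fix_boundary(
                        ssr_free_background(fill, spec.gc, rng, config),
                        rng,
                        first_not=motif[0],
                        last_not=spec.plants[idx + 1][0][-1],
                    )
                    parts.append(bg)
                    pos += fill
        tail = _fix_boundary(
            ssr_free_background(spec.flank_bp, spec.gc, rng, config),
            rng,
            first_not=spec.plants[-1][0][0],
        )
        parts.append(tail)
        record = SequenceRecord(spec.seq_id, "".join(parts))
        if scan_perfect(record, config) == loci:
            classes: dict[MotifClass, int] = {}
            for locus in loci:
                cls = canonicalize(locus.motif)
                classes[cls] = classes.get(cls, 0) + 1
            truth = TruthTable(
                loci=loci, units=_truth_units(loci, config), classes=classes
            )
            return record, truth
    raise RuntimeError("could not realize plant spec without junction artifacts")


def make_duplicated_genome(
    base: SequenceRecord,
    copies: int = 1,
    mismatch_rate: float = 0.0,
    seed: int = 0,
    spacer_bp: int = 1000,
    gc: float = 0.42,
) -> tuple[SequenceRecord, list[list[int]]]:
    """Concatenate ``copies`` copies of a base sequence with neutral
    spacers; copies after the first are mutated at mismatch_rate.

    Returns the genome and, per copy, the 0-based positions (within the
    copy) that were mutated.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    mutated_positions: list[list[int]] = []
    for c in range(copies):
        seq = base.residues
        positions: list[int] = []
        if c > 0 and mismatch_rate > 0:
            arr = list(seq)
            mask = rng.random(len(arr)) < mismatch_rate
            for i in np.flatnonzero(mask):
                alt = [b for b in "ACGT" if b != arr[i]]
                arr[i] = alt[int(rng.integers(3))]
                positions.append(int(i))
            seq = "".join(arr)
        parts.append(seq)
        mutated_positions.append(positions)
        parts.append(ssr_free_background(spacer_bp, gc, rng))
    return SequenceRecord(base.id + "_dup", "".join(parts)), mutated_positions


_BENCH_MOTIFS = (
    ("AT", 8),
    ("GAT", 5),
    ("AAG", 6),
    ("AATC", 4),
    ("AACTG", 4),
    ("AATCGC", 4),
    ("A", 10),
)


def make_uniqueness_benchmark(
    n_unique: int = 14,
    n_duplicated: int = 6,
    n_oversized: int = 2,
    spacer_bp: int = 95_000,
    window_bp: int = 700,
    seed: int = 0,
    config: ScanConfig | None = None,
    max_attempts: int = 20,
) -> tuple[SequenceRecord, dict[tuple[int, int], str]]:
    """A genome with known unique / duplicated / oversized SSR templates.

    Plants n_unique + n_duplicated designable SSR units separated by long
    SSR-free spacers, plus n_oversized mononucleotide runs that fail the
    size filter; then appends, behind 1 kb spacers, a verbatim copy of a
    window_bp-flanked window around each "duplicated" plant, so any primer
    designed for those templates (and for their appended copies) maps
    twice.  Returns the genome and the expected pipeline status per locus
    span {(start, end): "unique" | "non_unique" | "size_filtered"},
    validated against a scan of the assembled sequence.
    """
    config = config or ScanConfig()
    designable = [
        _BENCH_MOTIFS[i % len(_BENCH_MOTIFS)]
        for i in range(n_unique + n_duplicated)
    ]
    plants = [(m, r, None) for m, r in designable]
    plants += [("A", 15, None)] * n_oversized
    spec = PlantSpec(
        plants=tuple(plants), spacer_bp=spacer_bp, flank_bp=2 * window_bp
    )
    rng = np.random.default_rng(seed)
    base, truth = make_genome(spec, seed=int(rng.integers(2**31)), config=config)
    dup_indices = list(range(n_unique, n_unique + n_duplicated))
    for _ in range(max_attempts):
        parts = [base.residues]
        offset = base.length
        expected: dict[tuple[int, int], str] = {}
        for i, locus in enumerate(truth.loci):
            if i < n_unique:
                expected[(locus.start, locus.end)] = "unique"
            elif i in dup_indices:
                expected[(locus.start, locus.end)] = "non_unique"
            else:
                expected[(locus.start, locus.end)] = "size_filtered"
        for i in dup_indices:
            locus = truth.loci[i]
            spacer = ssr_free_background(1000, spec.gc, rng, config)
            window = base.residues[locus.start - window_bp - 1 : locus.end + window_bp]
            parts.append(spacer)
            offset += len(spacer)
            copy_start = offset + window_bp + 1
            copy_end = copy_start + locus.length - 1
            expected[(copy_start, copy_end)] = "non_unique"
            parts.append(window)
            offset += len(window)
        genome = SequenceRecord(base.id, "".join(parts))
        found = scan_perfect(genome, config)
        if sorted((l.start, l.end) for l in found) == sorted(expected):
            return genome, expected
        # junction artifact: redraw the appended spacers and try again
    raise RuntimeError("could not assemble benchmark without junction artifacts")


def simulate_genotypes(
    groups: int = 3,
    lines_per_group: tuple[int, ...] = (9, 6, 6),
    markers: int = 65,
    divergence: float = 0.5,
    seed: int = 0,
) -> tuple[GenotypeTable, dict[str, int]]:
    """Genotype panel of inbred lines in diverged groups.

    With probability ``divergence`` a marker is diagnostic: its allele
    pool is partitioned into disjoint per-group sub-pools.  Otherwise all
    groups share one pool and one frequency vector.  Per-marker allele
    counts stay within 2-6 (the range typical of SSR markers); lines are
    homozygous.  Returns the table and the true line->group map.
    """
    if groups < 2:
        raise ValueError("need >= 2 groups")
    if len(lines_per_group) != groups:
        raise ValueError("lines_per_group length must equal groups")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    line_ids = [
        f"G{g + 1}_L{i + 1}"
        for g in range(groups)
        for i in range(lines_per_group[g])
    ]
    truth = {
        lid: g for g, count in enumerate(lines_per_group)
        for lid in line_ids[sum(lines_per_group[:g]) : sum(lines_per_group[: g + 1])]
    }
    rows = {}
    for m in range(markers):
        diagnostic = rng.random() < divergence
        calls = []
        if diagnostic:
            # one 2-6 allele pool split into disjoint per-group sub-pools
            n_alleles = int(rng.integers(max(groups, 2), 7))
            labels = [str(100 + 2 * a) for a in range(n_alleles)]
            rng.shuffle(labels)
            cuts = 1 + np.sort(
                rng.choice(n_alleles - 1, size=groups - 1, replace=False)
            )
            bounds = [0, *cuts.tolist(), n_alleles]
            pools = [labels[bounds[g] : bounds[g + 1]] for g in range(groups)]
            freqs = [rng.dirichlet(np.ones(len(p))) for p in pools]
        else:
            n_alleles = int(rng.integers(2, 7))
            pool = [str(100 + 2 * a) for a in range(n_alleles)]
            pools = [pool] * groups
            f = rng.dirichlet(np.ones(n_alleles))
            freqs = [f] * groups
        for lid in line_ids:
            g = truth[lid]
            allele = pools[g][int(rng.choice(len(pools[g]), p=freqs[g]))]
            calls.append(allele)
        rows[f"SSR{m + 1:03d}"] = calls
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=line_ids)
    frame.index.name = "marker"
    return GenotypeTable(calls=frame), truth
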