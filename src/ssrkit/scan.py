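"""Detection of perfect microsatellites and merging into compound units.

A perfect SSR is a maximal exact tandem repetition of a 1-6 bp motif.  The
scanner applies MISA-style minimum repeat-count thresholds per motif length
(10 for mononucleotides, 6 for dinucleotides, 4 for tri- through
hexanucleotides by default) plus a global 10 bp minimum locus length, and
merges adjacent loci separated by at most ``max_interruption`` bases
(default 100) into compound units.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScanConfig",
    "PerfectSSR",
    "SSRUnit",
    "scan_perfect",
    "merge_units",
    "count_compound_loci",
    "minimal_period",
]

DEFAULT_MIN_REPEATS = {1: 10, 2: 6, 3: 4, 4: 4, 5: 4, 6: 4}


@dataclass(frozen=True)
class ScanConfig:
    """Search criteria for SSR detection.

    min_repeats maps motif length k (1..6) to the minimum number of full
    motif copies; max_interruption is the largest number of bases allowed
    between two adjacent SSRs that still join one compound unit;
    min_length_bp is the minimum total locus span in bp.
    """

    min_repeats: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    max_interruption: int = 100
    min_length_bp: int = 10

    def __post_init__(self) -> None:
        for k, n in self.min_repeats.items():
            if k not in (1, 2, 3, 4, 5, 6):
                raise ValueError(f"motif length {k} outside 1..6")
            if n < 2:
                raise ValueError(f"min_repeats[{k}]={n} must be >= 2")
        if self.max_interruption < 0:
            raise ValueError("max_interruption must be >= 0")


@dataclass(frozen=True)
class PerfectSSR:
    """One maximal perfect tandem repeat locus (1-based inclusive coords)."""

    seq_id: str
    motif: str
    repeats: int
    start: int
    end: int

    @property
    def k(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def notation(self) -> str:
        return f"({self.motif}){self.repeats}"

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif) * self.repeats:
            raise ValueError(
                f"span {self.start}..{self.end} inconsistent with "
                f"({self.motif}){self.repeats}"
            )


@dataclass(frozen=True)
class SSRUnit:
    """A perfect SSR or a compound chain of them.

    unit_type is ``p<k>`` for a single member of motif length k, ``c*`` for
    a compound whose members are all directly adjacent (every gap 0), and
    ``c`` for a compound with at least one positive gap.
    """

    members: tuple[PerfectSSR, ...]
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("unit needs at least one member")
        if len(self.gaps) != len(self.members) - 1:
            raise ValueError("need exactly members-1 gaps")

    @property
    def seq_id(self) -> str:
        return self.members[0].seq_id

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return self.members[-1].end

    @property
    def size_bp(self) -> int:
        """Envelope span in bp, interruption bases included."""
        return self.end - self.start + 1

    @property
    def unit_type(self) -> str:
        if len(self.members) == 1:
            return f"p{self.members[0].k}"
        return "c*" if all(g == 0 for g in self.gaps) else "c"

    @property
    def notation(self) -> str:
        parts = [self.members[0].notation]
        for gap, member in zip(self.gaps, self.members[1:]):
            if gap > 0:
                parts.append(f"n{gap}")
            parts.append(member.notation)
        return "".join(parts)


def minimal_period(motif: str) -> int:
    """Length of the shortest string whose repetition generates ``motif``."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return d
    return k


def _candidate_positions(s: str, config: ScanConfig) -> np.ndarray:
    """Positions that can possibly start a qualifying run.

    For period k a run of n copies means s[j] == s[j+k] along the first
    (n-1)*k offsets, so a boolean self-match profile per k plus a
    windowed-all reduction screens out almost every position of a random
    sequence; the exact per-position check still decides.
    """
    g = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    L = len(g)
    ok = np.zeros(L, dtype=bool)
    for k, rep in config.min_repeats.items():
        n_min = max(rep, math.ceil(config.min_length_bp / k))
        w = (n_min - 1) * k
        if L < n_min * k:
            continue
        mk = g[: L - k] == g[k:]
        cs = np.concatenate(([0], np.cumsum(mk)))
        full = cs[w:] - cs[:-w] == w  # all-true windows of length w
        ok[: len(full)] |= full
    return np.flatnonzero(ok)


def scan_perfect(seq, config: ScanConfig | None = None) -> list[PerfectSSR]:
    """Find all perfect SSR loci in a sequence record.

    Scans left to right; at each position the smallest motif length whose
    run meets its repeat threshold (and the minimum locus length) wins, the
    maximal run is emitted and scanning resumes after it.  Only complete
    motif copies count; N terminates any run and never appears in a motif.
    """
    config = config or ScanConfig()
    s = seq.residues
    sid = seq.id
    L = len(s)
    min_rep = config.min_repeats
    min_len = config.min_length_bp
    ks = sorted(min_rep)
    out: list[PerfectSSR] = []
    resume = 0
    for i in _candidate_positions(s, config):
        i = int(i)
        if i < resume or s[i] == "N":
            continue
        emitted = False
        for k in ks:
            if i + k > L:
                break
            motif = s[i : i + k]
            if "N" in motif:
                break  # larger k windows contain the same N
            if minimal_period(motif) != k:
                continue
            # cheap pre-check: need at least one more copy
            if s[i + k : i + 2 * k] != motif:
                continue
            n = 2
            pos = i + 2 * k
            while s[pos : pos + k] == motif:
                n += 1
                pos += k
            if n >= min_rep[k] and k * n >= min_len:
                out.append(
                    PerfectSSR(
                        seq_id=sid,
                        motif=motif,
                        repeats=n,
                        start=i + 1,
                        end=i + k * n,
                    )
                )
                resume = i + k * n
                emitted = True
                break
        if not emitted:
            resume = i + 1
    return out


def merge_units(
    ssrs: list[PerfectSSR], config: ScanConfig | None = None
) -> list[SSRUnit]:
    """Chain sorted SSRs with gaps <= max_interruption into compound units.

    Chaining is greedy and transitive: every consecutive pair whose gap
    qualifies joins the same unit, so chains may exceed two members.
    """
    config = config or ScanConfig()
    for a, b in itertools.pairwise(ssrs):
        if (a.seq_id, a.start) > (b.seq_id, b.start):
            raise ValueError("input loci must be sorted by (seq_id, start)")
        if a.seq_id == b.seq_id and b.start <= a.end:
            raise ValueError(
                f"overlapping loci at {a.seq_id}:{a.start}..{a.end} "
                f"and {b.start}..{b.end}"
            )
    units: list[SSRUnit] = []
    members: list[PerfectSSR] = []
    gaps: list[int] = []
    for ssr in ssrs:
        if members:
            prev = members[-1]
            gap = ssr.start - prev.end - 1
            if ssr.seq_id == prev.seq_id and gap <= config.max_interruption:
                members.append(ssr)
                gaps.append(gap)
                continue
            units.append(SSRUnit(tuple(members), tuple(gaps)))
            members, gaps = [], []
        members.append(ssr)
    if members:
        units.append(SSRUnit(tuple(members), tuple(gaps)))
    return units


def count_compound_loci(units: list[SSRUnit]) -> int:
    """Number of perfect loci that sit inside multi-member (compound) units."""
    return sum(len(u.members) for u in units if len(u.members) > 1)
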