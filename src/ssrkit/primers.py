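"""Unique SSR-primer workflow.

Given detected SSR units on a reference genome the pipeline (i) discards
units too large for a 100-500 bp amplicon, (ii) cuts a template of the unit
plus 500 bp flanks, (iii) searches the flanks for primer pairs satisfying
length, melting-temperature, composition and product-size constraints with
the SSR unit as the amplified target, (iv) maps both primers back to the
genome allowing mismatches, and (v) calls a pair unique when each primer
has a single admissible placement, or when the best placement beats the
second best by a mismatch margin.

Melting temperatures use nearest-neighbor thermodynamics at fixed
PCR-typical conditions (50 mM Na+, 1.5 mM Mg2+, 0.2 mM dNTPs, 250 nM
oligo, Owczarzy salt correction); a Wallace-rule mode exists for
cross-checking.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from .io import SequenceRecord
from .motifs import revcomp
from .scan import SSRUnit

log = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "PrimerParams",
    "Template",
    "PrimerPair",
    "Hit",
    "UniquenessVerdict",
    "size_filter",
    "build_template",
    "design_primers",
    "melting_temp",
    "map_primer",
    "assess_uniqueness",
    "insilico_pcr",
    "read_external_hits",
    "run_pipeline",
    "PipelineResult",
]


@dataclass(frozen=True)
class FilterConfig:
    """Size filtering ahead of primer design.

    Mononucleotide units are kept only up to max_mono_repeats repeats; all
    other unit types must span at most max_unit_bp.  flank_bp is the
    template flank cut on each side of the unit.
    """

    max_mono_repeats: int = 10
    max_unit_bp: int = 60
    flank_bp: int = 500

    def __post_init__(self) -> None:
        if min(self.max_mono_repeats, self.max_unit_bp, self.flank_bp) <= 0:
            raise ValueError("all FilterConfig fields must be positive")


@dataclass(frozen=True)
class PrimerParams:
    product_min: int = 100
    product_max: int = 500
    len_min: int = 18
    len_opt: int = 20
    len_max: int = 25
    tm_min: float = 57.0
    tm_max: float = 62.0
    returns: int = 2
    # composition guards beyond the size/Tm constraints (switchable off
    # for a strict minimal mode)
    gc_min: float = 0.30
    gc_max: float = 0.70
    max_homopolymer: int = 4
    composition_guards: bool = True
    tm_method: str = "nn"  # "nn" or "wallace"

    def __post_init__(self) -> None:
        if not self.len_min <= self.len_opt <= self.len_max:
            raise ValueError("need len_min <= len_opt <= len_max")
        if self.product_min > self.product_max:
            raise ValueError("empty product range")


@dataclass(frozen=True)
class Template:
    """Flank-expanded primer-design template for one SSR unit.

    central_start/central_end locate the SSR unit within the template
    (1-based); genome position = template position + genome_offset - 1.
    """

    unit: SSRUnit
    residues: str
    central_start: int
    central_end: int
    genome_offset: int  # genome coordinate of template position 1

    def to_genome(self, template_pos: int) -> int:
        return template_pos + self.genome_offset - 1


@dataclass(frozen=True)
class PrimerPair:
    forward: str  # 5'->3' on the plus strand
    reverse: str  # 5'->3' on the minus strand
    forward_start: int  # template coords, 1-based, leftmost base
    reverse_end: int  # template coord of the rightmost product base
    product_bp: int
    tm_forward: float
    tm_reverse: float

    @property
    def gc_forward(self) -> float:
        return _gc(self.forward)

    @property
    def gc_reverse(self) -> float:
        return _gc(self.reverse)


@dataclass(frozen=True)
class Hit:
    """One placement of a primer on the genome (position of its 5'-most
    base on the plus strand; for '-' hits the primer matches the reverse
    complement of the plus-strand window starting there)."""

    seq_id: str
    position: int  # 1-based plus-strand coordinate of the window start
    strand: str  # '+' or '-'
    mismatches: int


@dataclass(frozen=True)
class UniquenessVerdict:
    status: str  # unique, non_unique, unmapped
    reason: str
    hits_forward: tuple[Hit, ...]
    hits_reverse: tuple[Hit, ...]


def size_filter(
    units: list[SSRUnit], cfg: FilterConfig | None = None
) -> list[SSRUnit]:
    """Keep units small enough for amplicon design; log per-type accounting."""
    cfg = cfg or FilterConfig()
    kept: list[SSRUnit] = []
    tallies: Counter[tuple[str, bool]] = Counter()
    for u in units:
        if u.unit_type == "p1":
            keep = u.members[0].repeats <= cfg.max_mono_repeats
        else:
            keep = u.size_bp <= cfg.max_unit_bp
        tallies[(u.unit_type, keep)] += 1
        if keep:
            kept.append(u)
    for unit_type in sorted({t for t, _ in tallies}):
        k, d = tallies[(unit_type, True)], tallies[(unit_type, False)]
        log.info("size_filter %-3s kept=%d discarded=%d", unit_type, k, d)
    return kept


def build_template(
    genome: SequenceRecord, unit: SSRUnit, cfg: FilterConfig | None = None
) -> Template:
    """Cut unit +/- flank_bp from the genome, truncating at sequence ends."""
    cfg = cfg or FilterConfig()
    if unit.start < 1 or unit.end > genome.length:
        raise ValueError(
            f"unit {unit.start}..{unit.end} outside genome {genome.id} "
            f"(length {genome.length})"
        )
    t_start = max(1, unit.start - cfg.flank_bp)
    t_end = min(genome.length, unit.end + cfg.flank_bp)
    return Template(
        unit=unit,
        residues=genome.residues[t_start - 1 : t_end],
        central_start=unit.start - t_start + 1,
        central_end=unit.end - t_start + 1,
        genome_offset=t_start,
    )


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


_HOMOPOLYMER = {n: re.compile(r"(.)\1{%d,}" % n) for n in range(1, 11)}


def melting_temp(seq: str, method: str = "nn") -> float:
    if method == "wallace":
        return float(_mt.Tm_Wallace(seq))
    return float(
        _mt.Tm_NN(seq, Na=50, Mg=1.5, dNTPs=0.2, dnac1=250, dnac2=0, saltcorr=7)
    )


def _primer_ok(seq: str, params: PrimerParams) -> bool:
    if "N" in seq:
        return False
    if params.composition_guards:
        if not params.gc_min <= _gc(seq) <= params.gc_max:
            return False
        if _HOMOPOLYMER[params.max_homopolymer].search(seq):
            return False
    return True


def _candidate_primers(
    region: str, region_offset: int, is_forward: bool, anchor: int,
    params: PrimerParams, cap: int = 50,
) -> list[tuple[float, int, int, str, float]]:
    """Enumerate valid primers in one flank region.

    region_offset is the template coordinate of region[0]; anchor is the
    template coordinate the primer should sit close to (the central-SSR
    edge).  Candidates are explored closest-to-optimal-length first, then
    closest to the anchor, and capped for tractability (deterministic).
    Returns (len_dev, start, end, primer_seq, tm) tuples.
    """
    out = []
    lengths = sorted(
        range(params.len_min, params.len_max + 1),
        key=lambda ln: (abs(ln - params.len_opt), ln),
    )
    n = len(region)
    for ln in lengths:
        starts = range(0, n - ln + 1)
        # nearest the central SSR first: maximal start for the left flank,
        # minimal for the right flank
        ordered = sorted(
            starts,
            key=lambda s: (
                abs((region_offset + s + (ln - 1 if is_forward else 0)) - anchor),
                s,
            ),
        )
        for s in ordered:
            window = region[s : s + ln]
            primer = window if is_forward else revcomp(window)
            if not _primer_ok(primer, params):
                continue
            tm = melting_temp(primer, params.tm_method)
            if not params.tm_min <= tm <= params.tm_max:
                continue
            out.append(
                (abs(ln - params.len_opt), region_offset + s, region_offset + s + ln - 1, primer, tm)
            )
            if len(out) >= cap:
                return out
    return out


def design_primers(
    template: Template, params: PrimerParams | None = None
) -> list[PrimerPair]:
    """Find up to ``params.returns`` primer pairs flanking the central SSR.

    Primers never overlap the central span; the product always contains
    it.  Pairs are ranked deterministically by summed length deviation
    from the optimum, then summed Tm deviation from the range midpoint,
    then product-size distance from the product-range midpoint.
    """
    params = params or PrimerParams()
    s = template.residues
    left = s[: template.central_start - 1]
    right = s[template.central_end :]
    fwd = _candidate_primers(
        left, 1, True, template.central_start - 1, params
    )
    rev = _candidate_primers(
        right, template.central_end + 1, False, template.central_end + 1, params
    )
    if not fwd or not rev:
        log.info("no primer candidates for unit at %s:%d", template.unit.seq_id, template.unit.start)
        return []
    tm_mid = (params.tm_min + params.tm_max) / 2
    prod_mid = (params.product_min + params.product_max) / 2
    scored = []
    for fdev, fs, fe, fseq, ftm in fwd:
        for rdev, rs, re_, rseq, rtm in rev:
            product = re_ - fs + 1
            if not params.product_min <= product <= params.product_max:
                continue
            scored.append(
                (
                    fdev + rdev,
                    abs(ftm - tm_mid) + abs(rtm - tm_mid),
                    abs(product - prod_mid),
                    fs,
                    re_,
                    PrimerPair(
                        forward=fseq,
                        reverse=rseq,
                        forward_start=fs,
                        reverse_end=re_,
                        product_bp=product,
                        tm_forward=ftm,
                        tm_reverse=rtm,
                    ),
                )
            )
    scored.sort(key=lambda t: t[:5])
    return [t[5] for t in scored[: params.returns]]


def map_primer(
    primer: str, genome: list[SequenceRecord], max_mismatches: int = 0
) -> list[Hit]:
    """All placements of a primer on both strands with <= max_mismatches
    substitutions (no indels), ordered by (seq_id, position, strand)."""
    if len(primer) < 12:
        raise ValueError("primer must be >= 12 nt")
    hits: list[Hit] = []
    k = len(primer)
    probes = {"+": primer, "-": revcomp(primer)}
    for rec in sorted(genome, key=lambda r: r.id):
        g = np.frombuffer(rec.residues.encode("ascii"), dtype=np.uint8)
        n = len(g)
        if n < k:
            continue
        for strand, probe in probes.items():
            p = np.frombuffer(probe.encode("ascii"), dtype=np.uint8)
            mism = np.zeros(n - k + 1, dtype=np.int32)
            for j in range(k):
                mism += g[j : j + n - k + 1] != p[j]
            for pos in np.flatnonzero(mism <= max_mismatches):
                hits.append(
                    Hit(rec.id, int(pos) + 1, strand, int(mism[pos]))
                )
    hits.sort(key=lambda h: (h.seq_id, h.position, h.strand))
    return hits


def insilico_pcr(
    pair: PrimerPair,
    hits_f: list[Hit],
    hits_r: list[Hit],
    params: PrimerParams | None = None,
) -> list[tuple[str, int, int]]:
    """All products (seq_id, start, end) formed by admissible hit pairs.

    A product needs the two primers on opposite strands, pointing at each
    other, with an implied size inside the product range.
    """
    params = params or PrimerParams()
    lf, lr = len(pair.forward), len(pair.reverse)
    products = []
    for hf in hits_f:
        for hr in hits_r:
            if hf.seq_id != hr.seq_id or hf.strand == hr.strand:
                continue
            if hf.strand == "+":  # forward on +, reverse on -
                start, end = hf.position, hr.position + lr - 1
            else:  # swapped orientation
                start, end = hr.position, hf.position + lf - 1
            size = end - start + 1
            if size >= max(lf, lr) and params.product_min <= size <= params.product_max:
                products.append((hf.seq_id, start, end))
    return sorted(set(products))


def _mismatch_gap(hits: list[Hit], max_mismatches: int) -> int:
    """Best-vs-second-best mismatch separation; a lone hit counts as
    maximally separated."""
    counts = sorted(h.mismatches for h in hits)
    if len(counts) < 2:
        return max_mismatches + 10
    return counts[1] - counts[0]


def assess_uniqueness(
    pair: PrimerPair,
    hits_f: list[Hit],
    hits_r: list[Hit],
    params: PrimerParams | None = None,
    margin: int | None = 3,
    max_mismatches: int = 0,
) -> UniquenessVerdict:
    """Unique iff each primer has exactly one admissible placement, or
    (margin rule) each primer's best placement beats its second best by
    >= margin mismatches.  margin=None disables the margin rule."""
    params = params or PrimerParams()
    hf, hr = tuple(hits_f), tuple(hits_r)
    if not hf or not hr:
        missing = [n for n, h in (("forward", hf), ("reverse", hr)) if not h]
        return UniquenessVerdict(
            "unmapped", f"no hits for {'+'.join(missing)} primer", hf, hr
        )
    products = insilico_pcr(pair, hits_f, hits_r, params)
    adm_f = {
        h for h in hits_f for p in products
        if h.seq_id == p[0] and h.position in (p[1], p[2] - len(pair.forward) + 1)
    }
    adm_r = {
        h for h in hits_r for p in products
        if h.seq_id == p[0] and h.position in (p[1], p[2] - len(pair.reverse) + 1)
    }
    if len(products) == 1 and len(adm_f) == 1 and len(adm_r) == 1:
        return UniquenessVerdict("unique", "single admissible placement", hf, hr)
    if margin is not None:
        if (
            _mismatch_gap(hits_f, max_mismatches) >= margin
            and _mismatch_gap(hits_r, max_mismatches) >= margin
        ):
            return UniquenessVerdict(
                "unique", f"best placement >= {margin} mismatches clear", hf, hr
            )
    return UniquenessVerdict(
        "non_unique",
        f"{len(products)} admissible products; "
        f"{len(hits_f)}/{len(hits_r)} forward/reverse hits",
        hf,
        hr,
    )


def read_external_hits(path) -> dict[str, list[Hit]]:
    """Load primer placements produced by an external aligner.

    TSV columns: query_id, seq_id, position (1-based), strand (+/-),
    mismatches.  Lets the uniqueness rule run on hits from any mapping
    tool the user prefers over the built-in matcher.
    """
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"query_id", "seq_id", "position", "strand", "mismatches"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"hits table missing columns: {sorted(missing)}")
    hits: dict[str, list[Hit]] = {}
    for row in frame.itertuples():
        if row.strand not in "+-":
            raise ValueError(f"bad strand {row.strand!r} for {row.query_id}")
        hits.setdefault(str(row.query_id), []).append(
            Hit(str(row.seq_id), int(row.position), row.strand, int(row.mismatches))
        )
    for lst in hits.values():
        lst.sort(key=lambda h: (h.seq_id, h.position, h.strand))
    return hits


@dataclass
class PipelineResult:
    """Per-unit outcomes plus conservative accounting.

    records maps each input unit index to one of: size_filtered, no_primer,
    and for designed pairs the uniqueness status (unique / non_unique /
    unmapped) together with the top-ranked pair and its verdict.
    """

    statuses: list[str]
    pairs: dict[int, PrimerPair] = field(default_factory=dict)
    verdicts: dict[int, UniquenessVerdict] = field(default_factory=dict)

    @property
    def accounting(self) -> dict[str, int]:
        acc = Counter(self.statuses)
        acc["total"] = len(self.statuses)
        for key in ("size_filtered", "no_primer", "unmapped", "non_unique", "unique"):
            acc.setdefault(key, 0)
        return dict(acc)


def run_pipeline(
    genome: list[SequenceRecord],
    units: list[SSRUnit],
    filter_cfg: FilterConfig | None = None,
    params: PrimerParams | None = None,
    max_mismatches: int = 0,
    margin: int | None = 3,
) -> PipelineResult:
    """Run size filter -> template -> design -> map -> uniqueness for every
    unit, keeping the top-ranked pair per unit for the mapping step."""
    filter_cfg = filter_cfg or FilterConfig()
    params = params or PrimerParams()
    by_id = {rec.id: rec for rec in genome}
    kept = set(id(u) for u in size_filter(units, filter_cfg))
    statuses: list[str] = []
    result = PipelineResult(statuses=statuses)
    for i, unit in enumerate(units):
        if id(unit) not in kept:
            statuses.append("size_filtered")
            continue
        template = build_template(by_id[unit.seq_id], unit, filter_cfg)
        pairs = design_primers(template, params)
        if not pairs:
            statuses.append("no_primer")
            continue
        pair = pairs[0]
        result.pairs[i] = pair
        hits_f = map_primer(pair.forward, genome, max_mismatches)
        hits_r = map_primer(pair.reverse, genome, max_mismatches)
        verdict = assess_uniqueness(
            pair, hits_f, hits_r, params, margin=margin, max_mismatches=max_mismatches
        )
        result.verdicts[i] = verdict
        statuses.append(verdict.status)
    log.info("pipeline accounting: %s", result.accounting)
    return result
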