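"""Primer workflow: size filter, templates, design constraints, mapping
and uniqueness verdicts, each against independent checks."""

import re

import pytest

from ssrkit import (
    FilterConfig,
    PerfectSSR,
    PrimerParams,
    SequenceRecord,
    assess_uniqueness,
    build_template,
    design_primers,
    insilico_pcr,
    make_duplicated_genome,
    make_genome,
    map_primer,
    merge_units,
    run_pipeline,
    scan_perfect,
    size_filter,
)
from ssrkit.fixtures import PlantSpec, ssr_free_background
from ssrkit.motifs import revcomp
from ssrkit.primers import melting_temp

from helpers import oracle_map, random_dna


def _unit(motif, reps, start, seq_id="chr1", chain=()):
    members = [PerfectSSR(seq_id, motif, reps, start, start + len(motif) * reps - 1)]
    gaps = []
    for gap, (m2, r2) in chain:
        prev = members[-1]
        s2 = prev.end + gap + 1
        members.append(PerfectSSR(seq_id, m2, r2, s2, s2 + len(m2) * r2 - 1))
        gaps.append(gap)
    from ssrkit.scan import SSRUnit

    return SSRUnit(tuple(members), tuple(gaps))


class TestSizeFilter:
    def test_mono_over_repeat_cap_discarded(self):
        assert size_filter([_unit("A", 15, 1)]) == []

    def test_mono_at_cap_kept(self):
        u = _unit("A", 10, 1)
        assert size_filter([u]) == [u]

    def test_dinucleotide_under_60bp_kept(self):
        u = _unit("AT", 14, 1)  # 28 bp
        assert size_filter([u]) == [u]

    def test_compound_over_60bp_discarded(self):
        u = _unit("AT", 7, 1, chain=((32, ("AAG", 5)),))  # envelope 75 bp
        assert u.size_bp > 60 and size_filter([u]) == []

    def test_boundary_60bp_kept(self):
        u = _unit("AT", 30, 1)  # exactly 60 bp
        assert u.size_bp == 60 and size_filter([u]) == [u]


class TestBuildTemplate:
    def test_central_span_arithmetic(self, rng):
        genome = SequenceRecord("chr1", random_dna(rng, 1_000_000))
        unit = _unit("AT", 6, 10_000)
        # widen to a 31 bp envelope like a compound would have
        unit = _unit("AT", 6, 10_000, chain=((7, ("GAT", 4)),))
        assert unit.size_bp == 31
        t = build_template(genome, unit)
        assert len(t.residues) == 1031
        assert (t.central_start, t.central_end) == (501, 531)

    def test_left_truncation(self, rng):
        genome = SequenceRecord("chr1", random_dna(rng, 5000))
        unit = _unit("AT", 6, 50)
        t = build_template(genome, unit)
        assert t.genome_offset == 1 and t.central_start == 50

    def test_out_of_range_unit(self, rng):
        genome = SequenceRecord("chr1", random_dna(rng, 100))
        with pytest.raises(ValueError):
            build_template(genome, _unit("AT", 6, 200))

    def test_coordinate_round_trip(self, rng):
        genome = SequenceRecord("chr1", random_dna(rng, 20_000))
        for _ in range(100):
            start = int(rng.integers(1, genome.length - 12))
            unit = _unit("AT", 6, start)
            if unit.end > genome.length:
                continue
            t = build_template(genome, unit)
            for template_pos in (1, t.central_start, len(t.residues)):
                g = t.to_genome(template_pos)
                assert genome.residues[g - 1] == t.residues[template_pos - 1]


def _check_pair_constraints(pair, template, params):
    """Post-hoc verification of every design constraint."""
    for seq, tm in ((pair.forward, pair.tm_forward), (pair.reverse, pair.tm_reverse)):
        assert params.len_min <= len(seq) <= params.len_max
        assert params.tm_min <= tm <= params.tm_max
        assert tm == pytest.approx(melting_temp(seq), abs=1e-9)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert params.gc_min <= gc <= params.gc_max
        assert not re.search(r"(.)\1{%d,}" % params.max_homopolymer, seq)
    assert params.product_min <= pair.product_bp <= params.product_max
    # primers flank, never overlap, the central SSR
    f_end = pair.forward_start + len(pair.forward) - 1
    r_start = pair.reverse_end - len(pair.reverse) + 1
    assert f_end < template.central_start
    assert r_start > template.central_end
    # the primers are genuine template substrings in the right orientation
    s = template.residues
    assert s[pair.forward_start - 1 : f_end] == pair.forward
    assert revcomp(s[r_start - 1 : pair.reverse_end]) == pair.reverse


class TestDesignPrimers:
    def test_constraints_verified_posthoc(self, planted_genome):
        record, truth = planted_genome
        params = PrimerParams()
        kept = size_filter(truth.units)
        assert kept, "fixture should contain designable units"
        designed = 0
        for unit in kept:
            template = build_template(record, unit)
            pairs = design_primers(template, params)
            assert len(pairs) <= params.returns
            for pair in pairs:
                _check_pair_constraints(pair, template, params)
            designed += bool(pairs)
        assert designed > 0

    def test_too_short_template_infeasible(self, rng):
        genome = SequenceRecord("chr1", random_dna(rng, 80))
        unit = _unit("AT", 6, 35)
        t = build_template(genome, unit)
        assert design_primers(t) == []

    def test_homopolymer_flanks_infeasible(self):
        seq = "A" * 500 + "GAT" * 4 + "A" * 500
        genome = SequenceRecord("chr1", seq)
        unit = _unit("GAT", 4, 501)
        assert design_primers(build_template(genome, unit)) == []

    def test_deterministic(self, planted_genome):
        record, truth = planted_genome
        unit = size_filter(truth.units)[0]
        t = build_template(record, unit)
        assert design_primers(t) == design_primers(t)


class TestMapPrimer:
    def test_exact_single_hit(self, rng):
        seq = random_dna(rng, 5000)
        primer = seq[1000:1020]
        hits = map_primer(primer, [SequenceRecord("c", seq)], 0)
        plus = [h for h in hits if h.strand == "+"]
        assert any(h.position == 1001 and h.mismatches == 0 for h in plus)

    def test_both_strands_reported(self, rng):
        core = "ATTGCGGCTAAGCTATCGAC"
        seq = random_dna(rng, 300) + core + random_dna(rng, 300) + revcomp(core) + random_dna(rng, 300)
        hits = map_primer(core, [SequenceRecord("c", seq)], 0)
        assert sorted(h.strand for h in hits) == ["+", "-"]

    def test_matches_quadratic_oracle(self, rng):
        seq = random_dna(rng, 20_000)
        probe = seq[7000:7020]
        for max_mm in (0, 1, 2):
            got = [
                (h.position, h.strand, h.mismatches)
                for h in map_primer(probe, [SequenceRecord("c", seq)], max_mm)
            ]
            assert sorted(got) == oracle_map(probe, seq, max_mm)

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            map_primer("ACGTACGTACG", [SequenceRecord("c", "ACGT" * 100)], 0)


@pytest.fixture(scope="module")
def designed_template():
    spec = PlantSpec(plants=(("GAT", 5, None),))
    record, truth = make_genome(spec, seed=21)
    (unit,) = truth.units
    template = build_template(record, unit)
    (pair, *_) = design_primers(template)
    return record, template, pair


class TestUniqueness:
    def test_single_copy_unique(self, designed_template):
        record, _, pair = designed_template
        hf = map_primer(pair.forward, [record], 0)
        hr = map_primer(pair.reverse, [record], 0)
        v = assess_uniqueness(pair, hf, hr)
        assert v.status == "unique"
        assert len(insilico_pcr(pair, hf, hr)) == 1

    def test_verbatim_duplicate_non_unique(self, designed_template):
        record, _, pair = designed_template
        dup, _ = make_duplicated_genome(record, copies=2, mismatch_rate=0.0, seed=3)
        hf = map_primer(pair.forward, [dup], 0)
        hr = map_primer(pair.reverse, [dup], 0)
        assert assess_uniqueness(pair, hf, hr).status == "non_unique"
        assert len(insilico_pcr(pair, hf, hr)) == 2

    def test_unmapped_when_primer_absent(self, designed_template):
        record, _, pair = designed_template
        hf = map_primer(pair.forward, [record], 0)
        assert assess_uniqueness(pair, hf, []).status == "unmapped"

    def _mutated_copy_genome(self, record, template, pair):
        """Second copy carrying exactly 3 mismatches inside each primer site."""
        f_g = template.to_genome(pair.forward_start) - 1  # 0-based
        r_g = template.to_genome(pair.reverse_end - len(pair.reverse) + 1) - 1
        copy = list(record.residues)
        for site, ln in ((f_g, len(pair.forward)), (r_g, len(pair.reverse))):
            for off in (2, ln // 2, ln - 3):
                copy[site + off] = {"A": "C", "C": "A", "G": "T", "T": "G"}[copy[site + off]]
        spacer = "CTAG" * 300
        return SequenceRecord("dup", record.residues + spacer + "".join(copy))

    def test_margin_rule_fires(self, designed_template):
        record, template, pair = designed_template
        genome = self._mutated_copy_genome(record, template, pair)
        hf = map_primer(pair.forward, [genome], 3)
        hr = map_primer(pair.reverse, [genome], 3)
        assert sorted(h.mismatches for h in hf) == [0, 3]
        v = assess_uniqueness(pair, hf, hr, margin=3, max_mismatches=3)
        assert v.status == "unique" and "mismatch" in v.reason

    def test_margin_disabled_goes_non_unique(self, designed_template):
        record, template, pair = designed_template
        genome = self._mutated_copy_genome(record, template, pair)
        hf = map_primer(pair.forward, [genome], 3)
        hr = map_primer(pair.reverse, [genome], 3)
        assert assess_uniqueness(pair, hf, hr, margin=None).status == "non_unique"


class TestExternalHits:
    def test_round_trip_and_assessment(self, tmp_path, designed_template):
        record, _, pair = designed_template
        hf = map_primer(pair.forward, [record], 0)
        hr = map_primer(pair.reverse, [record], 0)
        rows = ["query_id\tseq_id\tposition\tstrand\tmismatches"]
        for q, hits in (("u1_F", hf), ("u1_R", hr)):
            rows += [f"{q}\t{h.seq_id}\t{h.position}\t{h.strand}\t{h.mismatches}" for h in hits]
        p = tmp_path / "hits.tsv"
        p.write_text("\n".join(rows) + "\n")
        from ssrkit import read_external_hits

        loaded = read_external_hits(p)
        assert loaded["u1_F"] == hf and loaded["u1_R"] == hr
        v = assess_uniqueness(pair, loaded["u1_F"], loaded["u1_R"])
        assert v.status == "unique"

    def test_missing_columns_rejected(self, tmp_path):
        from ssrkit import read_external_hits

        p = tmp_path / "bad.tsv"
        p.write_text("query_id\tposition\n a\t1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_external_hits(p)


class TestPipeline:
    def test_accounting_conservation_and_determinism(self):
        spec = PlantSpec(
            plants=(("GAT", 5, None), ("AT", 8, None), ("A", 15, None), ("AATC", 4, None))
        )
        record, truth = make_genome(spec, seed=5)
        units = merge_units(scan_perfect(record))
        res = run_pipeline([record], units)
        acc = res.accounting
        assert acc["total"] == len(units)
        assert acc["total"] == (
            acc["size_filtered"] + acc["no_primer"] + acc["unmapped"]
            + acc["non_unique"] + acc["unique"]
        )
        assert acc["size_filtered"] == 1  # the (A)15 mono unit
        res2 = run_pipeline([record], units)
        assert res.statuses == res2.statuses and res.pairs == res2.pairs
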