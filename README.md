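# ssrkit

A toolkit for genome-wide microsatellite (simple sequence repeat, SSR)
surveys and SSR marker development, aimed at plant genomics groups who
want to go from a genome assembly to a table of PCR-ready, genome-unique
SSR primer pairs, and from a marker genotyping panel to marker utility
statistics and a dendrogram.

It covers the whole workflow:

- **Detection** — all perfect 1–6 bp tandem repeats satisfying MISA-style
  thresholds (≥10 repeats for mono-, ≥6 for di-, ≥4 for tri- through
  hexanucleotides; ≥10 bp), with adjacent loci separated by ≤100 bp merged
  into compound units (`c`, or `c*` when the interruption is 0 bp).
- **Classification** — motifs folded into canonical classes under cyclic
  rotation and reverse complement, labelled `X/Y` (AAT/ATT, CCG/CGG, …);
  the class universes for k = 1..6 are 2, 4, 10, 33, 102 and 350.
- **Statistics** — per-genome counts by motif length, density (loci/Mbp),
  cumulative SSR fraction, repeat-number histograms, genic/CDS/intergenic
  assignment against GFF3 annotation, and 1 Mb window tracks.
- **Primer pipeline** — size filtering, 500 bp flank templates, a
  deterministic constraint search for primer pairs (18–25 nt, 57–62 °C
  nearest-neighbour Tm, 100–500 bp product containing the SSR), exhaustive
  mismatch-tolerant mapping of both primers back to the genome, and a
  uniqueness verdict per unit.
- **Marker statistics** — allele frequencies, polymorphic information
  content PIC = 1 − Σp_i² − Σ_{i<j}2p_i²p_j², Nei's (1983) distance
  D_A = 1 − (1/L)Σ_lΣ_u√(x_lu·y_lu), and a deterministic UPGMA tree
  written as Newick.
- **Synthetic fixtures** — seeded generators for genomes with planted
  SSRs and exact truth tables, duplicated-region genomes for uniqueness
  testing, and genotype panels with known group structure.

See `docs/methods.md` for the underlying definitions and design choices.

## Worked example

Generate a small fixture genome with planted SSRs and a genotype panel,
then run the chain:

```sh
ssrkit simulate --seed 7 --out-dir demo
ssrkit detect demo/fixture_genome.fasta --out-dir demo
cat demo/ssr_units.tsv
```

```
seq_id  unit_index  unit_type  ssr_notation  size_bp  start  end
chr1    1           p3         (GAT)5        15       601    615
chr1    2           p2         (AT)8         16       1216   1231
chr1    3           p1         (A)12         12       1832   1843
```

Three planted loci are recovered coordinate-exactly: a trinucleotide
(GAT)5, a dinucleotide (AT)8 and a mononucleotide (A)12, each reported as
a single `p` unit (no two are within 100 bp, so nothing is compounded).

```sh
ssrkit classify demo/ssr_units.tsv --out-dir demo
ssrkit primers demo/fixture_genome.fasta demo/ssr_units.tsv --out-dir demo
```

The spectrum folds each motif onto its canonical class (`(GAT)5` →
ATC/GAT). The primer run logs the pipeline accounting

```
INFO pipeline accounting: {'unique': 2, 'size_filtered': 1, 'total': 3, ...}
```

— the (A)12 mono unit exceeds the 10-repeat cap and is size-filtered; the
other two get primer pairs that map back to a single admissible genomic
placement, e.g.

```
unit_index  unit_type  ssr_notation  status  forward               reverse               product_bp  tm_forward  tm_reverse
1           p3         (GAT)5        unique  CTTCTCCGACGTATTCAGAG  TTTAATCCCGTGACTACTGC  241         59.38       59.40
```

Both primers are 20-mers with nearest-neighbour Tm ≈ 59.4 °C (inside the
57–62 °C window) bracketing the SSR in a 241 bp product. Finally, marker
statistics and the tree from the simulated 21-line, 65-marker panel:

```sh
ssrkit pic demo/fixture_genotypes.tsv --out-dir demo
ssrkit tree demo/fixture_genotypes.tsv --out-dir demo
```

```
marker  n_alleles  pic
SSR001  4          0.4647
SSR002  5          0.6972
```

`demo/upgma.nwk` holds the UPGMA dendrogram; with the default moderate
group divergence its three deepest clades are exactly the three simulated
groups.

The same functionality is available as a library (`import ssrkit`):
`scan_perfect`, `merge_units`, `canonicalize`, `run_pipeline`, `pic`,
`nei_da`, `upgma`, the fixture generators, and friends.

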