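# Methods

`ssrkit` implements a genome-wide microsatellite (SSR) survey and marker
development workflow: detection of perfect 1–6 bp tandem repeats, merging
into compound units, canonical motif classification, summary statistics,
flanking-primer design with an in-silico uniqueness screen, and SSR-marker
statistics (PIC, Nei 1983 D_A, UPGMA). This note records the models,
parameter choices, numerical conventions and known limitations.

## SSR detection

A perfect SSR is a maximal exact tandem repetition of a motif of length
k ∈ {1..6} with minimal period k (an (ATAT)n tract is a dinucleotide run,
never a tetranucleotide one). Default acceptance thresholds are the
MISA-style criteria widely used in plant SSR surveys: at least 10 repeats
for mononucleotides, 6 for dinucleotides and 4 for tri- through
hexanucleotides, plus an explicit 10 bp minimum locus length. The length
floor is redundant under the default repeat thresholds but keeps custom
thresholds consistent with the 10 bp definition of a microsatellite locus.

The scanner moves left to right. At each position it tests periods in
increasing order; the smallest period whose run meets its threshold wins,
the maximal run (complete motif copies only — a trailing partial copy
neither counts toward the repeat number nor extends the end coordinate) is
emitted, and scanning resumes at the base after the run. This "one locus
per run, smallest motif wins" policy makes the per-type counts mutually
exclusive. `N` terminates every run and never occurs inside a motif;
soft-masked (lowercase) sequence is uppercased on input and scanned like
any other sequence; organelle genomes are treated as linear strings (no
wrap-around repeats across the origin).

For speed on megabase inputs, a vectorised prefilter marks positions
i where the period-k self-match profile s[i] == s[i+k] holds across the
minimal qualifying window for some k; only those candidates reach the
exact per-position check. The prefilter can produce false positives but
no false negatives, so the output is identical to the plain scan — a
property the test suite asserts against an independent regex-based
brute-force finder.

Two adjacent SSRs separated by at most 100 interruption bases
(`max_interruption`) join one compound unit; chaining is transitive, so
units may have more than two members. A compound whose members are all
directly adjacent (every gap 0) is typed `c*`, any other compound `c`, and
singletons `p1`–`p6` by motif length. A unit's reported `size_bp` is its
envelope (interruptions included); per-member spans are kept separately,
and cumulative SSR length in genome summaries counts perfect-locus bases
only.

## Motif classification

Motifs that are cyclic rotations of one another or of each other's reverse
complement describe the same tract read at any phase from either strand,
and are folded into one class for all motif lengths, mononucleotides
included. The class representative is the lexicographically least string
(A<C<G<T) among the 2k variants; the label is
`canonical/revcomp(canonical)` (AAT/ATT, CCG/CGG, AT/AT, ...). Exhaustive
enumeration over all 4^k minimal-period motifs gives class universes of
2, 4, 10, 33, 102 and 350 for k = 1..6; the first four match the counts
observed in published whole-genome surveys (every possible mono-, di- and
tri- class occurs in real plant genomes), and the k = 5, 6 sizes are kept
as frozen regression constants. Observed class counts in a given genome
are always reported separately from the theoretical universe.

## Genome statistics

Density is loci per Mbp; the cumulative fraction is total perfect-SSR bp
over genome bp. Repeat-number histograms default to the bins ≤10, 11–20,
>20. Location assignment uses any-overlap (≥1 bp) with priority
CDS > genic (non-CDS) > intergenic, against gene spans by default (exon
spans would classify intronic SSRs differently; callers can pass whatever
feature set they consider "genic"). Window tracks (default 1 Mb windows)
assign each unit to the window containing its start coordinate so units
spanning a boundary are not double-counted.

## Primer workflow

Units pass a size filter before design: mononucleotide units with more
than 10 repeats are discarded, and all other unit types must span at most
60 bp — tracts near or above the product ceiling cannot be bracketed by a
100–500 bp amplicon. Each kept unit is expanded by 500 bp of genomic flank
per side (truncated at sequence ends) into a design template whose central
span is the SSR unit.

The constraint search enumerates forward candidates in the left flank and
reverse candidates (reverse-complemented) in the right flank with length
18–25 (optimum 20), melting temperature 57–62 °C, and two composition
guards that are on by default but switchable off: GC fraction within
0.30–0.70 and no homopolymer longer than 4. Melting temperatures come from
nearest-neighbour thermodynamics (Biopython `Tm_NN`) at fixed PCR-typical
conditions — 50 mM Na+, 1.5 mM Mg2+, 0.2 mM dNTPs, 250 nM oligo, Owczarzy
salt correction — under which 18–25-mers of moderate GC fall inside the
57–62 °C window; a Wallace-rule mode exists for cross-checking. Primers
never overlap the central span and every product contains it. Pairs are
ranked deterministically: summed length deviation from the optimum, then
summed Tm deviation from the range midpoint, then product-size distance
from the range midpoint, then coordinates. Candidate enumeration explores
optimal lengths and positions nearest the central SSR first and caps at 50
Tm-valid candidates per side; identical inputs always yield byte-identical
tables. Up to `returns` (default 2) pairs are reported and the top-ranked
pair is the one mapped in the pipeline.

Mapping is exhaustive short-oligo matching on both strands with up to
`max_mismatches` substitutions (no indels), vectorised over the genome; a
quadratic position-by-position oracle checks it in the tests. A pair is
**unique** when each primer has exactly one admissible placement — the two
placements on opposite strands, pointing at each other, implying a product
inside the product range — or, under the margin rule, when each primer's
best placement has at least `margin` (default 3) fewer mismatches than its
second best. The margin rule is the mismatch-space analogue of requiring
the secondary alignment of a BLAST-style screen to be several-fold worse
than the primary one; an adapter accepting external tabular alignment hits
preserves tool-specific scoring when users bring their own aligner. A
primer with zero placements gives `unmapped`. Pipeline accounting is
conservative by construction: every input unit ends in exactly one of
{size_filtered, no_primer, unmapped, non_unique, unique}.

Note one quirk implemented as configured rather than resolved: a
mononucleotide repeat filter of "≤ 10 repeats" combined with a detection
floor of "≥ 10 repeats" retains only exactly-10-repeat mono units; the cap
is a parameter (`max_mono_repeats`) for users who want a looser rule.

## Marker statistics and phylogeny

Allele frequencies per marker are tallied over non-missing calls, with
heterozygous calls contributing half per allele. PIC uses the Botstein
form

    PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²,

which is 0 for monomorphic markers and approaches 1 − 1/n for n
equifrequent alleles; plain expected heterozygosity 1 − Σ p_i² is exposed
under its own name to avoid confusion. Nei's (1983) D_A distance is

    D_A = 1 − (1/L) Σ_l Σ_u √(x_lu · y_lu)

over the L markers shared by both profiles (markers missing on either side
are dropped and L adjusted pairwise). Panels of inbred lines are treated
in "line mode": each line's own calls define its frequency profile, so
D_A between two homozygous lines is the fraction of shared markers with
different alleles. D_A is symmetric with zero self-distance but is not a
metric; no triangle inequality is assumed anywhere.

UPGMA merges the closest pair under size-weighted average linkage, with
node height half the merge distance and ties broken by the smallest
(row, column) index pair, making the tree deterministic; the test suite
cross-checks cophenetic distances against scipy's average-linkage
implementation and verifies ultrametricity to 1e-9. Trees serialise to
standard Newick (labels quoted when they contain metacharacters) and
round-trip through dendropy.

## Synthetic fixtures

The generators produce every input the toolkit consumes, deterministically
under a seed, and validate their own truth tables against the generated
sequence before returning.

*Genomes.* Backgrounds are i.i.d. bases at a chosen GC content (default
0.42, a typical plant nuclear value) that are scan-repaired until free of
qualifying SSRs; planted tracts are inserted with boundary bases adjusted
so a run can neither extend left (previous base equal to the motif's last
base) nor right (next base equal to the motif's first base). A final
re-scan must reproduce the truth table exactly or the draw is rejected.
The uniqueness benchmark plants ~20 designable SSRs plus oversized mono
runs in a ~2 Mb genome and appends verbatim copies of 700 bp-flanked
windows around a subset, so the expected pipeline verdict of every
template (unique / non_unique / size_filtered) is known by construction.
These backgrounds have no repeat families, gene models or isochores, so
passing tests demonstrate algorithmic correctness, not robustness to the
repetitive structure of real plant genomes — on a real pepper-sized
genome, a far larger share of primers is expected to fail the uniqueness
screen.

*Genotypes.* Panels default to 21 inbred lines in 3 groups (9, 6, 6) typed
at 65 markers, matching the scale at which SSR panels are commonly
validated. Each marker carries 2–6 alleles. With probability `divergence`
(default 0.5, "moderate") a marker is diagnostic: its allele pool is
partitioned into disjoint per-group sub-pools; otherwise all groups share
one pool and one frequency vector, so divergence 0 makes groups
exchangeable and divergence 1 forces between-group D_A of exactly 1.
Recovery is scored as the UPGMA tree's 3-cluster partition (splitting the
highest nodes) equalling the true groups exactly.

## Problem sizes and numerical conventions

The test suite and the acceptance script use: exhaustive enumeration up to
4^6 motifs; 100–200 random 5 kb sequences for scanner/oracle identity; a
~2 Mb uniqueness benchmark (28 templates); and 100 seeds of the 3×21×65
genotype simulation. Frequencies must sum to 1 within 1e-6 for PIC;
ultrametricity is asserted to 1e-9; external coordinates are 1-based
inclusive everywhere, with conversion only at the I/O boundary.

## Limitations

Only perfect repeats are detected (no mismatch-tolerant SSRs, no periods
above 6). Primer design checks composition and thermodynamic range but not
hairpins, self-dimers or cross-dimers, and does not reproduce any specific
external design tool's candidate ranking. Uniqueness mapping counts
substitutions only; an indel-containing second site would be missed.
Chloroplast LSC/SSC/IR partitioning is out of scope, and bootstrap support
values are not computed.
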