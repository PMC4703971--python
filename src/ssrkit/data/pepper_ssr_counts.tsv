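genome	genome_type	total_ssr_loci
N1	nuclear	876580
N2	nuclear	859515
M1	mitochondrial	44
M2	mitochondrial	47
C1	chloroplast	29
C2	chloroplast	31
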