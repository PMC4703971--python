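"""Published pepper SSR survey counts bundled for comparison.

Genome-wide totals of SSR loci reported for the two pepper nuclear
assemblies (Zunla-1 = N1, Chiltepin = N2), the two mitochondrial genomes
(M1, M2) and the two chloroplast genomes (C1, C2), so users can compare
their own scans against the published survey without re-downloading the
assemblies.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["pepper_ssr_counts", "mean_counts_by_genome_type"]


def pepper_ssr_counts() -> pd.DataFrame:
    """Per-genome published SSR totals (genome, genome_type, total_ssr_loci)."""
    with resources.files("ssrkit.data").joinpath("pepper_ssr_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def mean_counts_by_genome_type() -> dict[str, float]:
    """Arithmetic mean SSR count per genome type (nuclear/mito/chloroplast)."""
    frame = pepper_ssr_counts()
    return frame.groupby("genome_type")["total_ssr_loci"].mean().to_dict()
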