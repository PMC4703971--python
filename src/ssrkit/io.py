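"""Readers and writers for every external format the toolkit touches.

FASTA genomes (via Biopython), GFF3 feature tables, SSR unit tables
(MISA-compatible TSV layout), genotype tables, primer tables and Newick
trees.  All external genomic coordinates are 1-based inclusive; conversion
to anything else happens only past this boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .scan import PerfectSSR, SSRUnit

log = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "AnnotationFeature",
    "GenotypeTable",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "write_ssr_table",
    "read_ssr_table",
    "read_gff_features",
    "write_newick",
    "read_genotype_table",
    "write_genotype_table",
]

MISSING_CALL = "-"

_VALID = set("ACGTN")


class FormatError(ValueError):
    """A file violates the format contract (naming the offending record)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A DNA sequence: id (first header token) and uppercase residues."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AnnotationFeature:
    """One GFF3 feature row, 1-based inclusive coordinates."""

    seq_id: str
    kind: str  # gene, CDS, exon or other
    start: int
    end: int
    strand: str


@dataclass
class GenotypeTable:
    """Marker x individual allele calls.

    calls is a DataFrame indexed by marker id with individual ids as
    columns; a cell holds one allele label, a heterozygous pair "A/B", or
    the missing code "-".
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if self.calls.shape[0] < 1 or self.calls.shape[1] < 2:
            raise FormatError("need at least 1 marker and 2 individuals")
        if self.calls.index.has_duplicates:
            raise FormatError("duplicate marker ids")

    @property
    def markers(self) -> list[str]:
        return list(self.calls.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.columns)


def _clean_residues(raw: str, rec_id: str) -> str:
    s = raw.upper()
    bad = set(s) - _VALID
    if bad:
        log.warning(
            "record %s: %d non-ACGTN characters mapped to N (%s)",
            rec_id,
            sum(s.count(c) for c in bad),
            ",".join(sorted(bad)),
        )
        s = re.sub(f"[^{''.join(sorted(_VALID))}]", "N", s)
    return s


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into SequenceRecords, in file order."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = _clean_residues(str(rec.seq), rec.id)
        if not residues:
            raise FormatError(f"zero-length sequence {rec.id!r} in {path}")
        records.append(SequenceRecord(id=rec.id, residues=residues))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i : i + width] + "\n")


SSR_TABLE_COLUMNS = [
    "seq_id",
    "unit_index",
    "unit_type",
    "ssr_notation",
    "size_bp",
    "start",
    "end",
]


def write_ssr_table(units: list[SSRUnit], path: str | Path, header_comment: str | None = None) -> None:
    """Write SSR units as TSV (MISA-compatible layout), 1-based inclusive."""
    keys = [(u.seq_id, u.start) for u in units]
    if keys != sorted(keys):
        raise ValueError("units must be sorted by (seq_id, start)")
    rows = [
        {
            "seq_id": u.seq_id,
            "unit_index": i + 1,
            "unit_type": u.unit_type,
            "ssr_notation": u.notation,
            "size_bp": u.size_bp,
            "start": u.start,
            "end": u.end,
        }
        for i, u in enumerate(units)
    ]
    frame = pd.DataFrame(rows, columns=SSR_TABLE_COLUMNS)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep="\t", index=False)


_NOTATION_RE = re.compile(r"\(([ACGT]+)\)(\d+)|n(\d+)")


def parse_ssr_notation(notation: str, seq_id: str, start: int) -> SSRUnit:
    """Rebuild an SSRUnit from its notation, e.g. ``(AT)7n12(AAG)5``."""
    members: list[PerfectSSR] = []
    gaps: list[int] = []
    pos = start
    consumed = 0
    pending_gap: int | None = None
    for m in _NOTATION_RE.finditer(notation):
        consumed = m.end()
        if m.group(3) is not None:
            pending_gap = int(m.group(3))
            continue
        motif, reps = m.group(1), int(m.group(2))
        if members:
            gaps.append(pending_gap or 0)
            pos = members[-1].end + 1 + (pending_gap or 0)
        pending_gap = None
        members.append(
            PerfectSSR(seq_id=seq_id, motif=motif, repeats=reps, start=pos, end=pos + len(motif) * reps - 1)
        )
    if not members or consumed != len(notation):
        raise FormatError(f"cannot parse SSR notation {notation!r}")
    return SSRUnit(tuple(members), tuple(gaps))


def read_ssr_table(path: str | Path) -> list[SSRUnit]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SSR_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"SSR table missing columns: {sorted(missing)}")
    units = []
    for row in frame.itertuples():
        unit = parse_ssr_notation(row.ssr_notation, row.seq_id, int(row.start))
        if unit.end != int(row.end) or unit.size_bp != int(row.size_bp):
            raise FormatError(
                f"inconsistent row for {row.seq_id}:{row.start} ({row.ssr_notation})"
            )
        units.append(unit)
    return units


_GFF_KINDS = {"gene": "gene", "cds": "CDS", "exon": "exon"}


def read_gff_features(path: str | Path) -> list[AnnotationFeature]:
    """Parse GFF3 rows into features; non gene/CDS/exon types become 'other'."""
    features: list[AnnotationFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: expected >= 8 GFF3 columns")
            seq_id, _source, ftype, start, end, _score, strand, *_ = fields
            start_i, end_i = int(start), int(end)
            if start_i < 1 or start_i > end_i:
                raise FormatError(
                    f"{path}:{lineno}: invalid feature span {start}..{end}"
                )
            features.append(
                AnnotationFeature(
                    seq_id=seq_id,
                    kind=_GFF_KINDS.get(ftype.lower(), "other"),
                    start=start_i,
                    end=end_i,
                    strand=strand if strand in "+-." else ".",
                )
            )
    return features


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


def _newick_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node, parent_height: float) -> str:
    bl = parent_height - node.height
    if node.is_leaf:
        return f"{_newick_label(node.label)}:{bl:.6g}"
    inner = ",".join(_newick_node(c, node.height) for c in node.children)
    return f"({inner}):{bl:.6g}"


def write_newick(tree, path: str | Path) -> None:
    """Serialize an ultrametric tree as Newick with branch lengths."""
    root = tree.root
    if root.is_leaf:
        text = f"{_newick_label(root.label)}:0.0;"
    else:
        inner = ",".join(_newick_node(c, root.height) for c in root.children)
        text = f"({inner});"
    with open(path, "w") as fh:
        fh.write(text + "\n")


def read_genotype_table(path: str | Path) -> GenotypeTable:
    """Genotype TSV: first column marker id, header row of individual ids."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    frame.index = frame.index.astype(str)
    if frame.isna().any().any():
        raise FormatError(f"empty cells in genotype table {path}")
    return GenotypeTable(calls=frame)


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    table.calls.to_csv(path, sep="\t", index_label="marker")
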