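"""Readers and writers for the external formats the toolkit touches.

All coordinates are 0-based half-open internally; conversion to 1-based
happens only in human-readable report output.  Sequences are uppercased on
input and restricted to the DNA alphabet ``ACGTN``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (uppercase, alphabet ACGTN)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)} "
                "(expected A/C/G/T/N)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CoverageTrack:
    """Dense per-base read depth for one chromosome (0-based positions)."""

    chrom: str
    depth: np.ndarray  # int array, one entry per base

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise FormatError(f"{self.chrom}: negative depth values")

    def __len__(self) -> int:
        return len(self.depth)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Sequences are uppercased; record order is preserved.  Duplicate ids and
    characters outside ACGTN raise :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=str(rec.seq).upper(),
                description=rec.description[len(rec.id):].strip(),
            )
        )
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records as FASTA with fixed line wrapping (round-trip stable)."""
    bio = []
    for r in records:
        b = _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        bio.append(b)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_fastq(path) -> list[SequenceRecord]:
    """Read a FASTQ file, discarding qualities."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper()))
    return out


def write_fastq(records, path, quality: int = 30) -> None:
    """Write records as FASTQ with a constant placeholder quality."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{chr(quality + 33) * len(r.seq)}\n")


def read_coverage(path, chrom_length: int, chrom: str | None = None) -> CoverageTrack:
    """Read per-base coverage from bedGraph or a 2-column (pos, depth) TSV.

    bedGraph intervals are 0-based half-open and must not overlap; positions
    not covered by any line get depth 0.  ``end > chrom_length`` is an error.
    """
    depth = np.zeros(chrom_length, dtype=np.int64)
    name = chrom
    covered = np.zeros(chrom_length, dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) == 4:
                c, start, end, d = parts
                start, end, d = int(start), int(end), int(float(d))
                if name is None:
                    name = c
                elif c != name:
                    raise FormatError(f"line {lineno}: multiple chromosomes ({name!r}, {c!r})")
                if end > chrom_length:
                    raise FormatError(f"line {lineno}: end {end} > chrom length {chrom_length}")
                if start < 0 or start >= end:
                    raise FormatError(f"line {lineno}: bad interval [{start}, {end})")
                if covered[start:end].any():
                    raise FormatError(f"line {lineno}: overlapping bedGraph intervals")
                covered[start:end] = True
                depth[start:end] = d
            elif len(parts) == 2:
                pos, d = int(parts[0]), int(float(parts[1]))
                if pos < 0 or pos >= chrom_length:
                    raise FormatError(f"line {lineno}: position {pos} outside [0, {chrom_length})")
                depth[pos] = d
            else:
                raise FormatError(f"line {lineno}: expected 2 (pos, depth) or 4 (bedGraph) columns")
    return CoverageTrack(chrom=name or "unknown", depth=depth)


def write_coverage(track: CoverageTrack, path) -> None:
    """Write a coverage track as run-length-encoded bedGraph."""
    with open(path, "w") as fh:
        d = track.depth
        start = 0
        for i in range(1, len(d) + 1):
            if i == len(d) or d[i] != d[start]:
                if d[start] != 0:
                    fh.write(f"{track.chrom}\t{start}\t{i}\t{int(d[start])}\n")
                start = i


def read_gene_table(path) -> pd.DataFrame:
    """Read a TSV gene table (gene_id, length_bp, count/fpkm columns).

    gene_id must be unique; numeric columns are parsed as numbers.  Returns
    a DataFrame indexed by gene_id.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing gene_id column")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"{path}: duplicate gene_id {dups}")
    df = df.set_index("gene_id")
    if "length_bp" in df.columns and (df["length_bp"] < 1).any():
        raise FormatError(f"{path}: length_bp must be >= 1")
    return df


def write_gene_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="gene_id")


def write_report(report, path) -> None:
    """Write a report object (DataFrame or dataclass with .to_frame()) as TSV."""
    if hasattr(report, "to_frame") and not isinstance(report, pd.DataFrame):
        frame = report.to_frame()
    else:
        frame = report
    if isinstance(frame, pd.Series):
        frame = frame.to_frame()
    frame.to_csv(path, sep="\t")


def read_bed(path) -> pd.DataFrame:
    """Read a minimal BED file (chrom, start, end[, name]); 0-based half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0 or start >= end:
                raise FormatError(f"line {lineno}: bad BED interval [{start}, {end})")
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            rows.append((chrom, start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_vcf_minimal(path) -> pd.DataFrame:
    """Read CHROM/POS/REF/ALT from a plain-text VCF (POS converted to 0-based)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise FormatError(f"line {lineno}: VCF data line needs >= 5 columns")
            chrom, pos, _id, ref, alt = parts[:5]
            rows.append((chrom, int(pos) - 1, ref.upper(), alt.upper()))
    return pd.DataFrame(rows, columns=["chrom", "pos0", "ref", "alt"])
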