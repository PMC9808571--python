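"""Readers and writers for the formats at the pipeline boundary.

Coordinate conventions
----------------------
Genomic intervals are 0-based half-open on disk (BED / narrowPeak) and every
point coordinate held in memory -- a transcription start site (TSS), a peak
summit, a cleavage position, a piRNA 5' end -- is 1-based.  The conversions
are performed exactly once, here, so the science modules can do arithmetic
without dialect bookkeeping.

Sequences are normalized to the RNA alphabet {A, C, G, U} on read: input is
uppercased and T is mapped to U.  Any other symbol is a hard error naming the
offending record; the downstream pairing logic relies on a closed alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

GENE_CLASSES = frozenset(
    {"pachytene_piRNA", "piRNA_biogenesis", "other_coding", "other_noncoding"}
)
CONSERVATION_CLASSES = frozenset({"eutherian", "murine", "mouse_only"})


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to the point that matters here: its TSS.

    ``tss`` is 1-based; for a + strand gene it is the interval start + 1, for
    a − strand gene the interval end (the last base of the 0-based half-open
    interval, which is position ``end`` in 1-based coordinates).
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    gene_class: str = "other_coding"

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise FormatError(f"gene {self.gene_id}: tss must be >= 1, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.gene_class not in GENE_CLASSES:
            raise FormatError(
                f"gene {self.gene_id}: unknown gene_class {self.gene_class!r}"
            )


@dataclass(frozen=True)
class PeakCall:
    """A called peak with its summit as a 1-based point coordinate."""

    chrom: str
    start: int  # 0-based half-open on disk
    end: int
    summit: int  # 1-based
    score: float = 0.0
    factor: str | None = None  # e.g. TCFL5 / A-MYB
    assay: str | None = None  # CUTRUN / CHIP
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise FormatError(
                f"peak {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )
        if not (self.start <= self.summit - 1 < self.end):
            raise FormatError(
                f"peak {self.chrom}:{self.start}-{self.end}: summit {self.summit} "
                "(1-based) falls outside the interval"
            )
        if self.replicate < 1:
            raise FormatError(f"replicate must be >= 1, got {self.replicate}")


@dataclass
class PrecursorTranscript:
    """A piRNA-gene precursor transcript (RNA alphabet, 5'→3')."""

    transcript_id: str
    sequence: str
    source_gene: str | None = None
    conservation: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise FormatError(
                f"transcript {self.transcript_id}: non-ACGU symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_rna(seq: str, record_id: str = "<sequence>") -> str:
    """Uppercase, map T→U, and reject anything outside {A,C,G,U}."""
    out = seq.upper().replace("T", "U")
    bad = set(out) - RNA_ALPHABET
    if bad:
        raise FormatError(f"record {record_id!r}: non-ACGTU symbols {sorted(bad)}")
    return out


def read_fasta(path: str | Path) -> list[PrecursorTranscript]:
    """Read a FASTA file of transcripts, normalizing to the RNA alphabet.

    Order is preserved; duplicate ids and empty sequences are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[PrecursorTranscript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"record {rec.id!r}: empty sequence in {path}")
        out.append(PrecursorTranscript(rec.id, normalize_rna(seq, rec.id)))
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out


def write_fasta(transcripts: Iterable[PrecursorTranscript], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def _parse_int(field: str, what: str, lineno: int, path: Path) -> int:
    try:
        return int(field)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer {what} {field!r}") from None


def read_peaks(
    path: str | Path,
    dialect: str,
    factor: str | None = None,
    assay: str | None = None,
    replicate: int = 1,
) -> list[PeakCall]:
    """Read peaks from ``narrowPeak`` or summit-less BED6 (SEACR-style).

    narrowPeak carries a summit offset in column 10 (0-based, relative to
    start); the in-memory summit is ``start + offset + 1`` (1-based).  A
    summit-less BED6 peak gets the interval midpoint, floor((start+end)/2)
    in 0-based coordinates, as its summit.
    """
    path = Path(path)
    if dialect not in ("narrowPeak", "bed6_summitless"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    peaks: list[PeakCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            minc = 10 if dialect == "narrowPeak" else 6
            if len(f) < minc:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {minc} columns, got {len(f)}"
                )
            start = _parse_int(f[1], "start", lineno, path)
            end = _parse_int(f[2], "end", lineno, path)
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end {end} <= start {start}")
            try:
                score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 0.0
            except ValueError:
                score = 0.0
            if dialect == "narrowPeak":
                offset = _parse_int(f[9], "summit offset", lineno, path)
                if offset < 0 or offset >= end - start:
                    raise FormatError(
                        f"{path}:{lineno}: summit offset {offset} outside peak "
                        f"of length {end - start}"
                    )
                summit = start + offset + 1
            else:
                summit = (start + end) // 2 + 1
            peaks.append(
                PeakCall(
                    chrom=f[0],
                    start=start,
                    end=end,
                    summit=summit,
                    score=score,
                    factor=factor,
                    assay=assay,
                    replicate=replicate,
                )
            )
    return peaks


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED6(+1) gene file; optional column 7 is the gene class.

    TSS: interval start + 1 for + strand, interval end for − strand.
    """
    path = Path(path)
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 columns")
            start = _parse_int(f[1], "start", lineno, path)
            end = _parse_int(f[2], "end", lineno, path)
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: bad interval {start}-{end}")
            strand = f[5]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            gene_id = f[3]
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            tss = start + 1 if strand == "+" else end
            gene_class = f[6] if len(f) > 6 and f[6] else "other_coding"
            genes.append(GeneAnnotation(gene_id, f[0], tss, strand, gene_class))
    return genes


def write_gene_annotations(
    genes: Iterable[GeneAnnotation], path: str | Path, gene_length: int = 5000
) -> None:
    """Write genes as BED6+class, inverting the TSS convention exactly."""
    with open(path, "w") as fh:
        for g in genes:
            if g.strand == "+":
                start, end = g.tss - 1, g.tss - 1 + gene_length
            else:
                start, end = max(0, g.tss - gene_length), g.tss
            fh.write(
                f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\t{g.gene_class}\n"
            )


def write_table(records, path: str | Path) -> None:
    """Write records as a tab-separated table with a header row.

    Accepts a DataFrame or a sequence of dataclass-like records sharing a
    schema.  Floats keep full precision (well above the 6 significant digits
    the downstream comparisons need); output is UTF-8, newline-terminated.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = list(records)
        if rows and hasattr(rows[0], "__dataclass_fields__"):
            df = pd.DataFrame([vars(r) for r in rows])
        else:
            df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
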