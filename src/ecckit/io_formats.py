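"""Coordinate conventions, eccDNA-name parsing, and readers/writers.

All internal coordinates are 0-based half-open. The two places where 1-based
inclusive coordinates exist in the wild — canonical eccDNA names such as
``chr12_20609533_20610693`` and GFF3 — are converted at the boundary and never
leak further in.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from pyfaidx import Fasta

logger = logging.getLogger("ecckit")

_ECC_NAME_RE = re.compile(r"^(?P<chrom>.+)_(?P<start1>\d+)_(?P<end1>\d+)$")


class EccError(Exception):
    """Base class for ecckit errors."""


class ParseError(EccError):
    pass


class CoordinateError(EccError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A locus: chromosome + 0-based half-open [start, end) + strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise CoordinateError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class EccRecord:
    """One eccDNA locus, with its canonical 1-based-inclusive name."""

    interval: GenomicInterval
    name: str
    tissue: str = ""
    score: float | None = None

    @property
    def length(self) -> int:
        return self.interval.length()


def format_ecc_name(interval: GenomicInterval) -> str:
    """0-based half-open interval -> canonical ``chrom_start1_end1`` name."""
    return f"{interval.chrom}_{interval.start + 1}_{interval.end}"


def parse_ecc_name(name: str, tissue: str = "", score: float | None = None) -> EccRecord:
    """Parse a canonical eccDNA name (1-based inclusive) into an EccRecord.

    >>> parse_ecc_name("chr12_20609533_20610693").length
    1161
    """
    m = _ECC_NAME_RE.match(name)
    if m is None:
        raise ParseError(f"malformed eccDNA name {name!r}: expected <chrom>_<int>_<int>")
    chrom = m.group("chrom")
    start1 = int(m.group("start1"))
    end1 = int(m.group("end1"))
    if start1 < 1:
        raise ParseError(f"malformed eccDNA name {name!r}: start {start1} < 1")
    if start1 > end1:
        raise CoordinateError(
            f"eccDNA name {name!r}: start {start1} > end {end1}"
        )
    interval = GenomicInterval(chrom, start1 - 1, end1)
    return EccRecord(interval=interval, name=name, tissue=tissue, score=score)


# ---------------------------------------------------------------------------
# FASTA access
# ---------------------------------------------------------------------------


def open_genome(path: str | Path) -> Fasta:
    """Open an indexed FASTA (builds the .fai sidecar if absent)."""
    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def fetch_sequence(
    genome: Fasta, interval: GenomicInterval, flank: int = 0
) -> tuple[str, GenomicInterval]:
    """Fetch uppercase sequence of [start-flank, end+flank), clipped to the
    chromosome; returns (sequence, actual clipped interval)."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if interval.chrom not in genome:
        raise KeyError(f"chromosome {interval.chrom!r} not in genome")
    chrom_len = len(genome[interval.chrom])
    lo = max(0, interval.start - flank)
    hi = min(chrom_len, interval.end + flank)
    seq = str(genome[interval.chrom][lo:hi]).upper()
    return seq, GenomicInterval(interval.chrom, lo, hi, interval.strand)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# BED / TSV / GFF3
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[EccRecord]:
    """Read 3- or 4-column BED (0-based half-open). The 4th column, when
    present and canonical, is kept as the record name; otherwise the name is
    re-derived from coordinates."""
    records: list[EccRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            iv = GenomicInterval(chrom, start, end)
            name = parts[3] if len(parts) >= 4 and parts[3] not in (".", "") else format_ecc_name(iv)
            score = float(parts[4]) if len(parts) >= 5 and parts[4] != "." else None
            records.append(EccRecord(interval=iv, name=name, score=score))
    if not records:
        logger.warning("no intervals read from %s", path)
    return records


def write_bed(records: Iterable[EccRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            score = "." if r.score is None else f"{r.score:.6g}"
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\t{r.name}\t{score}\n"
            )


ECC_TSV_COLUMNS = ["name", "chrom", "start", "end", "tissue", "score"]


def read_ecc_tsv(path: str | Path) -> list[EccRecord]:
    """Read the named-eccDNA TSV dialect (header: name/chrom/start/end/tissue/score,
    coordinates 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "tissue": str})
    if df.empty:
        logger.warning("no records read from %s", path)
        return []
    records = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(str(row.chrom), int(row.start), int(row.end))
        score = None if pd.isna(row.score) else float(row.score)
        tissue = "" if pd.isna(row.tissue) else str(row.tissue)
        records.append(EccRecord(interval=iv, name=str(row.name), tissue=tissue, score=score))
    return records


def write_ecc_tsv(records: Iterable[EccRecord], path: str | Path) -> None:
    rows = [
        {
            "name": r.name,
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "tissue": r.tissue,
            "score": r.score,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ECC_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Gff3Feature:
    interval: GenomicInterval
    feature_type: str
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def gene_id(self) -> str | None:
        for key in ("ID", "Parent", "gene_id"):
            if key in self.attributes:
                return self.attributes[key]
        return None


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    """Read GFF3 features; 1-based inclusive coordinates converted to the
    internal 0-based half-open convention."""
    features: list[Gff3Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = parts
            attributes = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attributes[k.strip()] = v.strip()
            iv = GenomicInterval(
                chrom, int(start1) - 1, int(end1), strand if strand in "+-" else "."
            )
            features.append(Gff3Feature(iv, ftype, attributes))
    if not features:
        logger.warning("no features read from %s", path)
    return features


def write_gff3(features: Iterable[Gff3Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                f"{f.interval.chrom}\tecckit\t{f.feature_type}\t"
                f"{f.interval.start + 1}\t{f.interval.end}\t.\t"
                f"{f.interval.strand}\t.\t{attrs}\n"
            )


def validate_records(
    records: Sequence[EccRecord], chrom_lengths: dict[str, int]
) -> list[str]:
    """Return human-readable problems (unknown chromosome, coordinate
    overflow); an empty list means the set is valid for the genome."""
    problems = []
    for i, r in enumerate(records):
        iv = r.interval
        if iv.chrom not in chrom_lengths:
            problems.append(f"record {i} ({r.name}): unknown chromosome {iv.chrom}")
        elif iv.end > chrom_lengths[iv.chrom]:
            problems.append(
                f"record {i} ({r.name}): end {iv.end} beyond chromosome "
                f"length {chrom_lengths[iv.chrom]}"
            )
    return problems


# ---------------------------------------------------------------------------
# Minimal SAM
# ---------------------------------------------------------------------------


from functools import lru_cache


@lru_cache(maxsize=8192)
def _parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    return tuple(
        (m.group(2), int(m.group(1)))
        for m in re.finditer(r"(\d+)([MIDNSHP=X])", cigar)
    )


@dataclass(frozen=True)
class MinimalAlignment:
    """The slice of a SAM record the junction caller needs.

    pos is 0-based; cigar is the raw string; sa is the SA tag value or None.
    """

    qname: str
    flag: int
    chrom: str
    pos: int
    mapq: int
    cigar: str
    seq: str = "*"
    sa: str | None = None

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & 0x1)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & 0x40)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & 0x800)

    def cigar_ops(self) -> tuple[tuple[str, int], ...]:
        return _parse_cigar(self.cigar)

    @property
    def matched_length(self) -> int:
        """Reference-consuming aligned length (M/=/X)."""
        return sum(n for op, n in self.cigar_ops() if op in "M=X")

    @property
    def reference_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar_ops() if op in "MDN=X")


def read_sam(path: str | Path) -> tuple[list[MinimalAlignment], dict[str, int]]:
    """Read a SAM file into MinimalAlignment records plus @SQ lengths."""
    alignments: list[MinimalAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        chrom_lengths = dict(zip(sam.references, sam.lengths))
        for rec in sam:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            sa = rec.get_tag("SA") if rec.has_tag("SA") else None
            alignments.append(
                MinimalAlignment(
                    qname=rec.query_name,
                    flag=rec.flag,
                    chrom=rec.reference_name,
                    pos=rec.reference_start,
                    mapq=rec.mapping_quality,
                    cigar=rec.cigarstring or "*",
                    seq=rec.query_sequence or "*",
                    sa=sa,
                )
            )
    return alignments, chrom_lengths


def write_sam(
    alignments: Iterable[MinimalAlignment],
    chrom_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Emit unsorted SAM with @SQ headers via pysam."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": l} for c, l in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for a in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = a.qname
            rec.flag = a.flag
            rec.reference_name = a.chrom
            rec.reference_start = a.pos
            rec.mapping_quality = a.mapq
            rec.cigarstring = None if a.cigar == "*" else a.cigar
            if a.seq != "*":
                rec.query_sequence = a.seq
            if a.sa is not None:
                rec.set_tag("SA", a.sa)
            out.write(rec)
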