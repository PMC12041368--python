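"""Readers and writers for the external formats the pipeline touches.

Coordinate contract
-------------------
All intervals are 0-based half-open in memory.  Variant positions are stored
1-based (VCF convention) and converted exactly once, at intersection time
(``pos - 1``).  SEG files are read as 1-based inclusive (the GISTIC input
dialect) and converted to half-open on the way in.

Chromosome names: a leading ``"chr"`` is stripped for *matching* but the
original spelling is preserved for output, so tracks from UCSC-style sources
("chr17") interoperate with PCAWG-style calls ("17").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_JASPAR_PSEUDOCOUNT = 0.8


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix so UCSC and Ensembl spellings match."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region, the unit of all overlap logic."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            normalize_chrom(self.chrom) == normalize_chrom(other.chrom)
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, chrom: str, pos_1based: int) -> bool:
        """Whether the 1-based position falls inside this interval."""
        p0 = pos_1based - 1
        return (
            normalize_chrom(self.chrom) == normalize_chrom(chrom)
            and self.start <= p0 < self.end
        )

    def sort_key(self):
        return (normalize_chrom(self.chrom), self.start, self.end)


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant; ``sample`` is None for germline variants."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample: str | None = None

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"malformed base in {self.chrom}:{self.pos} "
                             f"{self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"1-based position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class SegmentRecord:
    """One copy-number segment (0-based half-open; seg_mean is log2 ratio)."""

    sample: str
    chrom: str
    start: int
    end: int
    n_markers: int
    seg_mean: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment start >= end: {self.sample} "
                f"{self.chrom}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class PWM:
    """A position weight matrix: 4 x L column-stochastic probabilities.

    Rows are ordered A, C, G, T.  ``pseudocount`` records the per-cell value
    added to raw counts before normalization.
    """

    tf_name: str
    matrix: np.ndarray
    pseudocount: float = DEFAULT_JASPAR_PSEUDOCOUNT

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError(f"PWM matrix must be 4 x L with L >= 1, got {m.shape}")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.tf_name}: columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


def pwm_from_counts(tf_name: str, counts: np.ndarray,
                    pseudocount: float = DEFAULT_JASPAR_PSEUDOCOUNT) -> PWM:
    """Convert a 4 x L count matrix to probabilities with a pseudocount.

    Each cell gets ``pseudocount`` added before per-column normalization:
    ``p = (c + pc) / (colsum + 4 * pc)``.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError(f"PWM {tf_name}: negative counts")
    probs = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
    return PWM(tf_name=tf_name, matrix=probs, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ into intervals; column 4 → name, column 5 → value."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: need >= 3 tab-separated columns")
            chrom, start_s, end_s = fields[:3]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            value = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                value = float(fields[4])
            intervals.append(GenomicInterval(chrom, start, end, name, value))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.value is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.value is not None:
                fields.append(f"{iv.value:g}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Variants (minimal VCF / 5-column TSV)
# ---------------------------------------------------------------------------

def read_variants(path: str | Path, format: str = "vcf") -> list[VariantRecord]:
    """Read SNVs from a minimal VCF 4.x or a 5-column TSV.

    VCF: only CHROM, POS, ID, REF, ALT are used; multi-allelic rows are
    split into one record per alternate allele.  Non-SNV rows (indels,
    symbolic alleles) are skipped and their count logged.

    TSV: columns chrom, pos, ref, alt, sample (header optional; sample
    column optional for germline variant files).
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_variant_tsv(path)
    raise ValueError(f"unknown variant format {format!r}")


def _read_vcf(path: str | Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: VCF row needs >= 5 columns")
            chrom, pos_s, _id, ref, alts = fields[:5]
            for alt in alts.split(","):
                if len(ref) != 1 or len(alt) != 1 or alt in ("*", "."):
                    n_skipped += 1
                    continue
                records.append(VariantRecord(chrom, int(pos_s), ref.upper(),
                                             alt.upper()))
    if n_skipped:
        logger.info("read_variants: skipped %d non-SNV allele(s) in %s",
                    n_skipped, path)
    return records


def _read_variant_tsv(path: str | Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and not fields[1].isdigit():
                continue  # header row
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need >= 4 columns")
            chrom, pos_s, ref, alt = fields[:4]
            sample = fields[4] if len(fields) > 4 and fields[4] else None
            if len(ref) != 1 or len(alt) != 1:
                n_skipped += 1
                continue
            records.append(VariantRecord(chrom, int(pos_s), ref.upper(),
                                         alt.upper(), sample))
    if n_skipped:
        logger.info("read_variants: skipped %d non-SNV row(s) in %s",
                    n_skipped, path)
    return records


def write_variants_tsv(variants: Iterable[VariantRecord],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tsample\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                     f"{v.sample if v.sample is not None else ''}\n")


def variants_to_frame(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
            "sample": [v.sample for v in variants],
        }
    )


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------

_SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_markers", "seg_mean"]


def read_seg(path: str | Path) -> list[SegmentRecord]:
    """Read a SEG file (GISTIC input dialect; 1-based inclusive on disk)."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 6:
        raise ValueError(f"{path}: SEG needs 6 columns, got {df.shape[1]}")
    df = df.iloc[:, :6]
    df.columns = _SEG_COLUMNS
    records = []
    for row in df.itertuples(index=False):
        start0 = int(row.start) - 1  # 1-based inclusive -> half-open
        end0 = int(row.end)
        if start0 >= end0:
            raise ValueError(
                f"{path}: segment start > end for sample {row.sample} "
                f"at {row.chrom}:{row.start}-{row.end}"
            )
        records.append(
            SegmentRecord(str(row.sample), str(row.chrom), start0, end0,
                          int(row.n_markers), float(row.seg_mean))
        )
    return records


def write_seg(segments: Iterable[SegmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tnum.mark\tseg.mean\n")
        for s in segments:
            fh.write(f"{s.sample}\t{s.chrom}\t{s.start + 1}\t{s.end}\t"
                     f"{s.n_markers}\t{s.seg_mean:.6g}\n")


# ---------------------------------------------------------------------------
# Matrices (TSV with header row + index column)
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled samples x columns TSV matrix; labels must be unique."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate column labels {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate row labels {dup}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# JASPAR PFM text
# ---------------------------------------------------------------------------

def read_jaspar(path: str | Path,
                pseudocount: float = DEFAULT_JASPAR_PSEUDOCOUNT) -> list[PWM]:
    """Read JASPAR-format count matrices and convert to probability PWMs."""
    pwms: list[PWM] = []
    with open(path) as fh:
        for motif in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([motif.counts[b] for b in BASES], dtype=float)
            name = motif.name or motif.matrix_id or "unnamed"
            pwms.append(pwm_from_counts(name, counts, pseudocount))
    return pwms


def write_jaspar_counts(counts_by_tf: dict[str, np.ndarray],
                        path: str | Path) -> None:
    """Write integer count matrices in JASPAR 2020 PFM text format."""
    with open(path, "w") as fh:
        for name, counts in counts_by_tf.items():
            counts = np.asarray(counts)
            fh.write(f">{name}\t{name}\n")
            for base, row in zip(BASES, counts):
                vals = " ".join(f"{v:.0f}" for v in row)
                fh.write(f"{base}  [ {vals} ]\n")
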