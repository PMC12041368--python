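"""Risk-locus construction and the interval overlap/coverage engine.

The engine is a plain sorted-sweep implementation of merge, intersect and
coverage over 0-based half-open intervals; abutting intervals do not
overlap.  Every enrichment computation in the package routes through it,
and the test suite checks it against a per-base brute-force oracle.

A germline risk locus is the 1 Mb region centred on a GWAS index SNP:
500 kb upstream and downstream of the lead position, clipped at the
chromosome edge.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

from .io_formats import GenomicInterval, normalize_chrom

FLANK_BP = 500_000  # each side of the index SNP


@dataclass(frozen=True)
class RiskLocus:
    """A GWAS index SNP with its derived 1 Mb susceptibility region."""

    locus_id: str
    index_chrom: str
    index_pos: int  # 1-based
    histotype: str
    region: GenomicInterval

    def __post_init__(self) -> None:
        if not self.region.contains_pos(self.index_chrom, self.index_pos):
            raise ValueError(
                f"locus {self.locus_id}: index SNP not inside region"
            )


def build_risk_locus(locus_id: str, chrom: str, index_pos: int,
                     histotype: str,
                     chrom_sizes: Mapping[str, int]) -> RiskLocus:
    """Extend 500 kb either side of the lead SNP; clip at chromosome edges.

    ``index_pos`` is 1-based.  The region is [p0 - 500000, p0 + 500000) in
    0-based coordinates, width exactly 1,000,000 bp unless clipped.
    """
    sizes = {normalize_chrom(c): s for c, s in chrom_sizes.items()}
    key = normalize_chrom(chrom)
    if key not in sizes:
        raise ValueError(f"unknown chromosome {chrom!r}")
    size = sizes[key]
    p0 = index_pos - 1
    if not (0 <= p0 < size):
        raise ValueError(
            f"index position {index_pos} outside chromosome {chrom} "
            f"(size {size})"
        )
    start = max(0, p0 - FLANK_BP)
    end = min(size, p0 + FLANK_BP)
    region = GenomicInterval(chrom, start, end, name=locus_id)
    return RiskLocus(locus_id, chrom, index_pos, histotype, region)


# ---------------------------------------------------------------------------
# Core engine
# ---------------------------------------------------------------------------

def _by_chrom(intervals: Iterable[GenomicInterval]):
    groups: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        groups[normalize_chrom(iv.chrom)].append(iv)
    for ivs in groups.values():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
    return groups


def merge(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals; abutting pieces are joined (half-open semantics)."""
    out: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(intervals)):
        ivs = _by_chrom(intervals)[chrom]
        cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
                cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
        out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return out


class OverlapFragment(NamedTuple):
    """One overlapping piece, with the names of its two parent intervals."""

    chrom: str
    start: int
    end: int
    a_name: str | None
    b_name: str | None


def intersect(a: Sequence[GenomicInterval],
              b: Sequence[GenomicInterval]) -> list[OverlapFragment]:
    """All pairwise overlapping fragments of ``a`` x ``b``, sorted.

    Half-open: abutting intervals do NOT overlap.  Fragment names carry the
    parent interval names for bookkeeping.
    """
    a_groups, b_groups = _by_chrom(a), _by_chrom(b)
    out: list[OverlapFragment] = []
    for chrom in sorted(set(a_groups) & set(b_groups)):
        avs, bvs = a_groups[chrom], b_groups[chrom]
        j0 = 0
        for av in avs:
            # advance past b intervals that end before av starts
            while j0 < len(bvs) and bvs[j0].end <= av.start:
                j0 += 1
            j = j0
            while j < len(bvs) and bvs[j].start < av.end:
                bv = bvs[j]
                lo, hi = max(av.start, bv.start), min(av.end, bv.end)
                if lo < hi:
                    out.append(OverlapFragment(av.chrom, lo, hi,
                                               av.name, bv.name))
                j += 1
    out.sort(key=lambda f: (normalize_chrom(f.chrom), f.start, f.end))
    return out


def coverage_fraction(targets: Sequence[GenomicInterval],
                      by: Sequence[GenomicInterval]) -> list[float]:
    """Per-target fraction of bp covered by the union of ``by`` intervals."""
    merged = _by_chrom(merge(by))
    fractions = []
    for t in targets:
        covered = 0
        for m in merged.get(normalize_chrom(t.chrom), []):
            lo, hi = max(t.start, m.start), min(t.end, m.end)
            if lo < hi:
                covered += hi - lo
        fractions.append(covered / t.width)
    return fractions


def covered_bp(targets: Sequence[GenomicInterval],
               by: Sequence[GenomicInterval]) -> int:
    """Total bp of the merged ``targets`` covered by the merged ``by``."""
    mt = merge(targets)
    fracs = coverage_fraction(mt, by)
    return int(round(sum(f * t.width for f, t in zip(fracs, mt))))


def enrichment_percent(n_significant: int, n_total: int) -> float:
    """Percentage of elements significant among those annotated.

    Returns NaN (an explicit "undefined" marker) when nothing is annotated;
    values are rounded to two decimals, the reporting precision used
    throughout.
    """
    if n_significant < 0 or n_total < 0:
        raise ValueError("counts must be non-negative")
    if n_significant > n_total:
        raise ValueError(
            f"n_significant ({n_significant}) > n_total ({n_total})"
        )
    if n_total == 0:
        return math.nan
    return round(100.0 * n_significant / n_total, 2)
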