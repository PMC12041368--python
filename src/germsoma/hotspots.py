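"""SNV recurrence tallies and frequently-mutated-element detection.

The burden model is deliberately simple: SNVs pooled across samples are
compared against a uniform per-bp background within each annotation track
(upper-tail Poisson, BH-adjusted across the track's elements).  It is a
stand-in for a full driver-discovery model with covariates — the layer of
interest here is the enrichment bookkeeping on top: the percentage of
annotated elements that are frequently mutated, genome-wide, per
chromosome, and within germline risk loci.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import RiskLocus, enrichment_percent
from .io_formats import GenomicInterval, VariantRecord, normalize_chrom


@dataclass(frozen=True)
class RecurrenceTally:
    """Distribution of per-position recurrence across samples.

    ``histogram`` maps k (number of distinct samples mutated at a
    position) to the number of positions with that k.  The totals satisfy
    total_snvs = sum(k * count) and unique_positions = sum(count).
    """

    histogram: dict[int, int]
    total_snvs: int
    unique_positions: int

    @classmethod
    def from_histogram(cls, histogram: dict[int, int]) -> "RecurrenceTally":
        """Build a tally from a printed recurrence distribution."""
        total = sum(k * c for k, c in histogram.items())
        unique = sum(histogram.values())
        return cls(dict(histogram), total, unique)


@dataclass(frozen=True)
class ElementTestResult:
    """Mutation-burden test on one annotated element (samples pooled)."""

    element: GenomicInterval
    annotation: str
    observed: int
    expected: float
    p_value: float
    q_value: float | None = None
    significant: bool = False


def tally_recurrence(snvs: Sequence[VariantRecord]) -> RecurrenceTally:
    """Count, per position, the number of distinct samples mutated there.

    A sample carrying several records at one position counts once toward
    that position's recurrence k; every record counts toward total_snvs.
    """
    samples_at: dict[tuple[str, int], set] = defaultdict(set)
    for v in snvs:
        samples_at[(normalize_chrom(v.chrom), v.pos)].add(v.sample)
    histogram = Counter(len(s) for s in samples_at.values())
    return RecurrenceTally(dict(histogram), total_snvs=len(snvs),
                           unique_positions=len(samples_at))


def test_element(element: GenomicInterval, snvs: Sequence[VariantRecord],
                 background_rate: float,
                 annotation: str = "") -> ElementTestResult:
    """Upper-tail Poisson burden test for one element.

    ``background_rate`` is mutations per bp pooled across samples, so the
    null is Poisson(rate x width); p = P(X >= observed), inclusive.
    """
    if background_rate <= 0:
        raise ValueError("background_rate must be > 0")
    observed = sum(1 for v in snvs
                   if element.contains_pos(v.chrom, v.pos))
    lam = background_rate * element.width
    p = float(stats.poisson.sf(observed - 1, lam))  # P(X >= observed)
    return ElementTestResult(element, annotation or (element.name or ""),
                             observed, lam, min(p, 1.0))


def scan_track(track: Sequence[GenomicInterval],
               snvs: Sequence[VariantRecord],
               fdr: float = 0.05,
               annotation: str | None = None,
               background_rate: float | None = None
               ) -> list[ElementTestResult]:
    """Burden-test every element of one annotation track.

    Unless given, the background rate is estimated as (SNVs falling in the
    track's elements) / (total annotated width), i.e. a uniform rate over
    the track.  BH is applied across the track's elements only; an
    element is significant when q < fdr.
    """
    if not track:
        raise ValueError("empty track")
    ann = annotation
    if ann is None:
        first = track[0].name or ""
        ann = first.rsplit("_", 1)[0] if first else ""
    total_width = sum(iv.width for iv in track)
    # fast per-element counting: bucket variant positions by chromosome
    pos_by_chrom: dict[str, np.ndarray] = {}
    tmp: dict[str, list[int]] = defaultdict(list)
    for v in snvs:
        tmp[normalize_chrom(v.chrom)].append(v.pos - 1)
    for c, ps in tmp.items():
        pos_by_chrom[c] = np.sort(np.asarray(ps))
    counts = []
    for iv in track:
        ps = pos_by_chrom.get(normalize_chrom(iv.chrom))
        if ps is None:
            counts.append(0)
        else:
            counts.append(int(np.searchsorted(ps, iv.end)
                              - np.searchsorted(ps, iv.start)))
    if background_rate is None:
        in_track = sum(counts)
        if in_track == 0:
            # no mutations at all: everything is trivially non-significant
            return [ElementTestResult(iv, ann, 0, 0.0, 1.0, 1.0, False)
                    for iv in track]
        background_rate = in_track / total_width
    pvals = []
    for iv, obs in zip(track, counts):
        lam = background_rate * iv.width
        pvals.append(min(float(stats.poisson.sf(obs - 1, lam)), 1.0))
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return [
        ElementTestResult(iv, ann, obs, background_rate * iv.width,
                          p, float(q), bool(r))
        for iv, obs, p, q, r in zip(track, counts, pvals, qvals, reject)
    ]


def enrich(results: Iterable[ElementTestResult],
           stratify_by: str = "genome",
           loci: Sequence[RiskLocus] | None = None) -> pd.DataFrame:
    """Percentage of elements frequently mutated, per annotation x stratum.

    ``stratify_by`` is "genome", "chromosome", or "loci" (requires
    ``loci``; an element belongs to a locus on >= 1 bp overlap and is
    counted once per locus it touches).  Percent is NaN where a stratum
    has no annotated elements.
    """
    results = list(results)
    rows = []
    if stratify_by == "genome":
        groups: dict[tuple, list[ElementTestResult]] = defaultdict(list)
        for r in results:
            groups[(r.annotation, "genome")].append(r)
    elif stratify_by == "chromosome":
        groups = defaultdict(list)
        for r in results:
            groups[(r.annotation,
                    normalize_chrom(r.element.chrom))].append(r)
    elif stratify_by == "loci":
        if loci is None:
            raise ValueError("stratify_by='loci' requires loci")
        groups = defaultdict(list)
        annotations = sorted({r.annotation for r in results})
        for locus in loci:
            key_rs = [r for r in results
                      if r.element.overlaps(locus.region)]
            for ann in annotations:
                groups[(ann, locus.locus_id)] = [
                    r for r in key_rs if r.annotation == ann
                ]
    else:
        raise ValueError(f"unknown stratify_by {stratify_by!r}")
    for (ann, stratum), rs in sorted(groups.items()):
        n_total = len(rs)
        n_sig = sum(r.significant for r in rs)
        rows.append({
            "annotation": ann,
            "stratum": stratum,
            "n_total": n_total,
            "n_significant": n_sig,
            "percent": enrichment_percent(n_sig, n_total),
        })
    return pd.DataFrame(rows,
                        columns=["annotation", "stratum", "n_total",
                                 "n_significant", "percent"])
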