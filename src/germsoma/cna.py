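"""Recurrent copy-number region calling, chromatin-state coverage, and
risk-locus intersection.

The caller is a simplified recurrence model over fixed genomic bins: a
sample "carries" an amplification at a bin when an overlapping segment has
seg.mean >= t_amp (deletions analogous with t_del), and the per-bin
alteration frequency is compared against a null built by circularly
permuting each sample's altered-bin layout, which preserves that sample's
altered mass exactly (at bin resolution).  Adjacent significant bins of
one direction are merged into regions.  An externally produced region
list (e.g. from a dedicated CNA caller on real data) can be fed straight
into the annotation and locus-intersection steps.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .intervals import RiskLocus, covered_bp, merge
from .io_formats import GenomicInterval, SegmentRecord, normalize_chrom

#: Chromatin-state vocabulary (the low-signal state is excluded upstream,
#: as it cannot be distinguished from poised regions without repressive
#: marks).
ALLOWED_STATES = frozenset({
    "active_region", "active_promoter", "weak_promoter",
    "active_enhancer", "weak_enhancer", "transcribed", "insulator",
})


@dataclass(frozen=True)
class RecurrentCNARegion:
    """A region recurrently amplified or deleted across samples."""

    region: GenomicInterval
    direction: str  # "amp" | "del"
    frequency: float
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.direction not in ("amp", "del"):
            raise ValueError("direction must be 'amp' or 'del'")
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError("frequency out of [0,1]")


def _group_segments(segments: Sequence[SegmentRecord]):
    by_sample_chrom: dict[tuple[str, str], list[SegmentRecord]] = \
        defaultdict(list)
    for s in segments:
        by_sample_chrom[(s.sample, normalize_chrom(s.chrom))].append(s)
    for key, segs in by_sample_chrom.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs[:-1], segs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping segments within sample {key[0]} on "
                    f"chromosome {key[1]}: {a.start}-{a.end} vs "
                    f"{b.start}-{b.end}"
                )
    return by_sample_chrom


def call_recurrent(
    segments: Sequence[SegmentRecord],
    t_amp: float = 0.3,
    t_del: float = -0.3,
    bin_bp: int = 10_000,
    n_perm: int = 1000,
    fdr: float = 0.25,
    seed: int | None = None,
) -> list[RecurrentCNARegion]:
    """Call recurrently amplified/deleted regions from segmentations.

    Per bin and direction, the observed alteration frequency is compared
    with a pooled null obtained from ``n_perm`` circular permutations of
    each sample's per-bin alteration indicator; p-values are BH-adjusted
    per direction and adjacent significant bins are merged.
    """
    by_sample_chrom = _group_segments(segments)
    samples = sorted({s for s, _ in by_sample_chrom})
    chrom_spelling: dict[str, str] = {}
    chrom_size: dict[str, int] = {}
    for s in segments:
        key = normalize_chrom(s.chrom)
        chrom_spelling.setdefault(key, s.chrom)
        chrom_size[key] = max(chrom_size.get(key, 0), s.end)
    rng = np.random.default_rng(seed)
    n = len(samples)
    regions: list[RecurrentCNARegion] = []
    per_direction: dict[str, list[tuple[str, int, int, float, float]]] = {
        "amp": [], "del": []}
    # (chrom, bin_index) bookkeeping so BH can run across all chromosomes
    for direction, thr in (("amp", t_amp), ("del", t_del)):
        bin_records = []   # (chrom_key, bin_idx, obs_count)
        pool = []          # pooled null counts
        for ckey in sorted(chrom_size):
            size = chrom_size[ckey]
            n_bins = math.ceil(size / bin_bp)
            ind = np.zeros((n, n_bins), dtype=np.int8)
            for i, sample in enumerate(samples):
                for seg in by_sample_chrom.get((sample, ckey), []):
                    hit = (seg.seg_mean >= thr if direction == "amp"
                           else seg.seg_mean <= thr)
                    if hit:
                        b0 = seg.start // bin_bp
                        b1 = (seg.end - 1) // bin_bp + 1
                        ind[i, b0:b1] = 1
            obs = ind.sum(axis=0)
            for b in range(n_bins):
                bin_records.append((ckey, b, int(obs[b])))
            cols = np.arange(n_bins)
            for _ in range(n_perm):
                offs = rng.integers(0, n_bins, size=n)
                rolled = ind[np.arange(n)[:, None],
                             (cols[None, :] - offs[:, None]) % n_bins]
                pool.append(rolled.sum(axis=0))
        pool_arr = np.sort(np.concatenate(pool)) if pool else np.array([0])
        total = len(pool_arr)
        pvals = []
        for _, _, obs_count in bin_records:
            n_ge = total - np.searchsorted(pool_arr, obs_count, side="left")
            pvals.append((1 + n_ge) / (1 + total))
        if not pvals:
            continue
        reject, qvals, _, _ = multipletests(pvals, alpha=fdr,
                                            method="fdr_bh")
        for (ckey, b, obs_count), p, q, r in zip(bin_records, pvals,
                                                 qvals, reject):
            if r:
                per_direction[direction].append(
                    (ckey, b, obs_count, p, float(q)))
        # merge adjacent significant bins per chromosome
        sig = sorted(per_direction[direction])
        i = 0
        while i < len(sig):
            ckey, b0, obs_count, p, q = sig[i]
            b1, best_obs, best_p, best_q = b0, obs_count, p, q
            j = i + 1
            while (j < len(sig) and sig[j][0] == ckey
                   and sig[j][1] == b1 + 1):
                b1 = sig[j][1]
                best_obs = max(best_obs, sig[j][2])
                best_p = min(best_p, sig[j][3])
                best_q = min(best_q, sig[j][4])
                j += 1
            start = b0 * bin_bp
            end = min((b1 + 1) * bin_bp, chrom_size[ckey])
            regions.append(RecurrentCNARegion(
                GenomicInterval(chrom_spelling[ckey], start, end,
                                name=direction),
                direction, best_obs / n, best_p, best_q))
            i = j
        per_direction[direction] = []
    regions.sort(key=lambda r: (normalize_chrom(r.region.chrom),
                                r.region.start))
    return regions


def annotate_cna(
    regions: Sequence[RecurrentCNARegion],
    state_tracks: Mapping[str, Mapping[str, Sequence[GenomicInterval]]],
) -> pd.DataFrame:
    """Chromatin-state coverage of recurrent CNA regions per cell type.

    ``state_tracks`` maps cell type → state name → intervals.  For every
    (cell_type, state, direction) present, the covered bp is the overlap
    between the merged CNA regions of that direction and the state's
    intervals, and the fraction is relative to the direction's total CNA
    bp.
    """
    for cell_type, states in state_tracks.items():
        for state in states:
            if state not in ALLOWED_STATES:
                raise ValueError(
                    f"unknown chromatin state {state!r} for "
                    f"{cell_type!r}; allowed: {sorted(ALLOWED_STATES)}"
                )
    rows = []
    for direction in ("amp", "del"):
        cna = [r.region for r in regions if r.direction == direction]
        if not cna:
            continue
        total_bp = sum(iv.width for iv in merge(cna))
        for cell_type, states in state_tracks.items():
            for state, ivs in states.items():
                cov = covered_bp(cna, list(ivs))
                rows.append({
                    "cell_type": cell_type,
                    "state": state,
                    "direction": direction,
                    "covered_bp": cov,
                    "fraction_of_cna_bp": cov / total_bp,
                })
    return pd.DataFrame(rows, columns=["cell_type", "state", "direction",
                                       "covered_bp", "fraction_of_cna_bp"])


def intersect_with_loci(
    regions: Sequence[RecurrentCNARegion],
    loci: Sequence[RiskLocus],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Overlay recurrent CNA regions on germline risk loci.

    Returns a per-locus table of overlapping regions (a region spanning
    several loci is listed under each and flagged multi-locus) and a
    summary counting loci carrying >= 1 CNA, >= 1 amplification, and
    >= 1 deletion.
    """
    locus_hits: dict[str, int] = defaultdict(int)
    rows = []
    for region in regions:
        touching = [lc for lc in loci if region.region.overlaps(lc.region)]
        for lc in touching:
            rows.append({
                "locus_id": lc.locus_id,
                "histotype": lc.histotype,
                "chrom": region.region.chrom,
                "start": region.region.start,
                "end": region.region.end,
                "direction": region.direction,
                "frequency": region.frequency,
                "q_value": region.q_value,
                "multi_locus": len(touching) > 1,
            })
    table = pd.DataFrame(rows, columns=["locus_id", "histotype", "chrom",
                                        "start", "end", "direction",
                                        "frequency", "q_value",
                                        "multi_locus"])
    if len(table):
        with_cna = table["locus_id"].nunique()
        with_amp = table.loc[table["direction"] == "amp",
                             "locus_id"].nunique()
        with_del = table.loc[table["direction"] == "del",
                             "locus_id"].nunique()
    else:
        with_cna = with_amp = with_del = 0
    summary = {"loci_with_cna": int(with_cna), "amp": int(with_amp),
               "del": int(with_del)}
    return table, summary
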