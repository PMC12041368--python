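"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of a PCAWG-style ovarian
cancer cohort — non-negative signature activities linearly coupled to the
expression of planted genes, background somatic SNVs with planted hotspot
elements, recurrent amplification/deletion segments, annotation tracks
tiling a toy genome, and JASPAR-style motifs with planted disruptable
binding sites — so that every downstream stage is testable offline with a
known ground truth.

All generators are deterministic for a fixed seed, emit 0-based half-open
coordinates, and use the fixed alphabet {A, C, G, T} (no indels; indel
signatures enter the analysis only through the activity matrix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    BASES,
    BASE_INDEX,
    DEFAULT_JASPAR_PSEUDOCOUNT,
    GenomicInterval,
    PWM,
    SegmentRecord,
    VariantRecord,
    normalize_chrom,
    pwm_from_counts,
)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """A toy genome: ordered chromosome labels with their sizes in bp."""

    chrom_names: tuple[str, ...]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        for name in self.chrom_names:
            if self.chrom_sizes.get(name, 0) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive size")

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_sizes[c] for c in self.chrom_names)


@dataclass(frozen=True)
class PlantedAssociation:
    """A gene whose expression linearly drives one signature's activity."""

    gene: str
    signature: str
    slope: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PlantedHotspot:
    """An interval whose per-bp mutation rate is a multiple of background."""

    interval: GenomicInterval
    rate_multiplier: float

    def __post_init__(self) -> None:
        if self.rate_multiplier <= 1:
            raise ValueError("rate_multiplier must be > 1")


@dataclass(frozen=True)
class RecurrentCNASpec:
    """A planted recurrent CNA: region, direction and sample penetrance."""

    interval: GenomicInterval
    direction: str  # "amp" | "del"
    penetrance: float

    def __post_init__(self) -> None:
        if self.direction not in ("amp", "del"):
            raise ValueError("direction must be 'amp' or 'del'")
        if not (0 < self.penetrance <= 1):
            raise ValueError("penetrance must be in (0, 1]")

    @property
    def sign(self) -> int:
        return +1 if self.direction == "amp" else -1


class PWMScenario(NamedTuple):
    """Output of :func:`gen_pwms_and_variants`."""

    pwms: list[PWM]
    counts_by_tf: dict[str, np.ndarray]
    chrom: str
    sequence: str
    sites: pd.DataFrame     # tf, start, end (planted perfect-match sites)
    variants: pd.DataFrame  # chrom, pos, ref, alt, tf, label


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_genome(n_chroms: int, size_bp: int, seed: int = 0) -> GenomeModel:
    """A genome of ``n_chroms`` chromosomes, each ``size_bp`` long."""
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if size_bp < 10_000:
        raise ValueError("size_bp must be >= 10,000")
    names = tuple(f"chr{i + 1}" for i in range(n_chroms))
    return GenomeModel(names, {n: int(size_bp) for n in names})


def gen_annotation_tracks(genome: GenomeModel, classes: Sequence[str],
                          n_per_class: int, mean_len: int,
                          seed: int = 0) -> dict[str, list[GenomicInterval]]:
    """Place disjoint annotation elements of each class on the genome.

    Elements within a class never overlap; classes are placed
    independently.  Element lengths are 1 + Poisson(mean_len - 1).
    """
    if mean_len < 1:
        raise ValueError("mean_len must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = np.array([genome.chrom_sizes[c] for c in genome.chrom_names],
                     dtype=float)
    tracks: dict[str, list[GenomicInterval]] = {}
    for cls in classes:
        per_chrom = rng.multinomial(n_per_class, sizes / sizes.sum())
        intervals: list[GenomicInterval] = []
        idx = 0
        for chrom, k in zip(genome.chrom_names, per_chrom):
            if k == 0:
                continue
            size = genome.chrom_sizes[chrom]
            lengths = 1 + rng.poisson(max(mean_len - 1, 0), size=k)
            if lengths.sum() > size:
                raise ValueError(
                    f"class {cls!r}: requested {lengths.sum()} bp exceeds "
                    f"chromosome {chrom} size {size}"
                )
            slack = size - int(lengths.sum())
            gaps = np.sort(rng.integers(0, slack + 1, size=k))
            starts = gaps + np.concatenate([[0], np.cumsum(lengths[:-1])])
            for s, ln in zip(starts, lengths):
                intervals.append(
                    GenomicInterval(chrom, int(s), int(s + ln),
                                    name=f"{cls}_{idx}")
                )
                idx += 1
        intervals.sort(key=lambda iv: iv.sort_key())
        tracks[cls] = intervals
    return tracks


def gen_snvs(genome: GenomeModel, n_samples: int, background_rate: float,
             hotspots: Sequence[PlantedHotspot] = (),
             seed: int = 0) -> list[VariantRecord]:
    """Background SNVs at ``background_rate`` mut/bp/sample, plus hotspots.

    Per-sample mutation counts are Poisson; inside each hotspot the per-bp
    rate is background x rate_multiplier.  A zero rate with no hotspots
    yields an empty table (downstream stages must tolerate empty inputs).
    """
    if not genome.chrom_names:
        raise ValueError("empty genome")
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    rng = np.random.default_rng(seed)
    base_idx = np.arange(4)
    records: list[VariantRecord] = []
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    for sample in sample_ids:
        for chrom in genome.chrom_names:
            size = genome.chrom_sizes[chrom]
            n_bg = rng.poisson(background_rate * size)
            positions = list(rng.integers(0, size, size=n_bg))
            for hs in hotspots:
                if normalize_chrom(hs.interval.chrom) != normalize_chrom(chrom):
                    continue
                extra_rate = background_rate * (hs.rate_multiplier - 1)
                n_extra = rng.poisson(extra_rate * hs.interval.width)
                positions.extend(
                    rng.integers(hs.interval.start, hs.interval.end,
                                 size=n_extra)
                )
            for p0 in positions:
                ref = int(rng.integers(0, 4))
                alt = int(rng.choice(np.delete(base_idx, ref)))
                records.append(
                    VariantRecord(chrom, int(p0) + 1, BASES[ref], BASES[alt],
                                  sample)
                )
    return records


def gen_signature_expression(
    n_samples: int,
    genes: Sequence[str],
    signatures: Sequence[str],
    planted: Sequence[PlantedAssociation] = (),
    seed: int = 0,
    expr_mu: float = 1.0,
    expr_sigma: float = 0.5,
    intercept: float = 1.0,
    base_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lognormal expression and coupled non-negative signature activities.

    Expression ~ lognormal(expr_mu, expr_sigma) per gene.  For each
    signature, activity = max(0, intercept + sum(slope * expr_gene) +
    Normal(0, sd)) where the sum runs over associations planted on that
    signature (empty for unplanted signatures, which are therefore
    independent of every gene).
    """
    genes = list(genes)
    signatures = list(signatures)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids")
    if len(set(signatures)) != len(signatures):
        raise ValueError("duplicate signature ids")
    for pa in planted:
        if pa.gene not in genes:
            raise ValueError(f"planted gene {pa.gene!r} not in gene list")
        if pa.signature not in signatures:
            raise ValueError(
                f"planted signature {pa.signature!r} not in signature list"
            )
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    expr = pd.DataFrame(
        rng.lognormal(expr_mu, expr_sigma, size=(n_samples, len(genes))),
        index=samples, columns=genes,
    )
    by_sig: dict[str, list[PlantedAssociation]] = {}
    for pa in planted:
        by_sig.setdefault(pa.signature, []).append(pa)
    act = np.empty((n_samples, len(signatures)))
    for j, sig in enumerate(signatures):
        assocs = by_sig.get(sig, [])
        mean = np.full(n_samples, intercept)
        sd = base_sd
        for pa in assocs:
            mean = mean + pa.slope * expr[pa.gene].to_numpy()
            sd = pa.noise_sd  # planted signatures use the planted noise
        act[:, j] = np.maximum(0.0, mean + rng.normal(0.0, sd, n_samples))
    activity = pd.DataFrame(act, index=samples, columns=signatures)
    return expr, activity


def gen_cna_segments(
    genome: GenomeModel,
    n_samples: int,
    recurrent_regions: Sequence[RecurrentCNASpec] = (),
    seed: int = 0,
    background_sd: float = 0.05,
    n_background_breaks: int = 4,
) -> list[SegmentRecord]:
    """Per-sample segmentations tiling each chromosome exactly once.

    Background segments have seg.mean ~ Normal(0, background_sd); with
    probability = penetrance a sample carries each recurrent region at
    seg.mean = sign x Uniform(0.5, 1.5).
    """
    for i, a in enumerate(recurrent_regions):
        for b in recurrent_regions[i + 1:]:
            if a.interval.overlaps(b.interval) and a.sign != b.sign:
                raise ValueError(
                    "overlapping recurrent regions of opposite sign: "
                    f"{a.interval} vs {b.interval}"
                )
    rng = np.random.default_rng(seed)
    records: list[SegmentRecord] = []
    samples = [f"S{i:03d}" for i in range(n_samples)]
    regions_by_chrom: dict[str, list[RecurrentCNASpec]] = {}
    for spec in recurrent_regions:
        regions_by_chrom.setdefault(
            normalize_chrom(spec.interval.chrom), []).append(spec)
    # hit indicator per (sample, region), drawn up front for determinism
    hits = {
        (s, id(spec)): rng.random() < spec.penetrance
        for s in samples for spec in recurrent_regions
    }
    for sample in samples:
        for chrom in genome.chrom_names:
            size = genome.chrom_sizes[chrom]
            specs = regions_by_chrom.get(normalize_chrom(chrom), [])
            breaks = {0, size}
            for spec in specs:
                breaks.add(spec.interval.start)
                breaks.add(spec.interval.end)
            # random extra breakpoints, kept out of recurrent regions so a
            # planted region stays a single segment
            extra = rng.integers(0, size, size=n_background_breaks)
            for x in extra:
                x = int(x)
                if all(not (sp.interval.start < x < sp.interval.end)
                       for sp in specs):
                    breaks.add(x)
            bounds = sorted(breaks)
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                seg_mean = float(rng.normal(0.0, background_sd))
                for spec in specs:
                    if spec.interval.start <= lo and hi <= spec.interval.end:
                        if hits[(sample, id(spec))]:
                            seg_mean = spec.sign * float(
                                rng.uniform(0.5, 1.5))
                        break
                records.append(
                    SegmentRecord(sample, chrom, lo, hi,
                                  n_markers=max(1, (hi - lo) // 1000),
                                  seg_mean=round(seg_mean, 6))
                )
    return records


def gen_pwms_and_variants(
    n_tfs: int,
    motif_len: int,
    genome: GenomeModel,
    n_sites: int,
    seed: int = 0,
    consensus_count: int = 97,
    pseudocount: float = DEFAULT_JASPAR_PSEUDOCOUNT,
) -> PWMScenario:
    """Motifs with planted perfect-match sites and known variant effects.

    Each of ``n_tfs`` motifs gets ``n_sites`` non-overlapping perfect
    consensus sites written into a random sequence on the genome's first
    chromosome.  Half of each motif's sites receive a disruptive variant
    (consensus base of one column replaced by a non-consensus base); an
    equal number of neutral variants are placed well outside all sites.
    """
    if motif_len < 4:
        raise ValueError("motif_len must be >= 4")
    chrom = genome.chrom_names[0]
    seq_len = genome.chrom_sizes[chrom]
    total_site_bp = n_tfs * n_sites * motif_len
    if n_sites * motif_len > seq_len or total_site_bp > seq_len // 2:
        raise ValueError("requested sites do not fit in the sequence")
    rng = np.random.default_rng(seed)

    # motif count matrices: one dominant base per column
    counts_by_tf: dict[str, np.ndarray] = {}
    pwms: list[PWM] = []
    consensus: dict[str, np.ndarray] = {}
    for t in range(n_tfs):
        name = f"TF{t + 1}"
        cons = rng.integers(0, 4, size=motif_len)
        counts = np.ones((4, motif_len))
        counts[cons, np.arange(motif_len)] = consensus_count
        counts_by_tf[name] = counts
        consensus[name] = cons
        pwms.append(pwm_from_counts(name, counts, pseudocount))

    seq = rng.integers(0, 4, size=seq_len)

    # non-overlapping site placement with a motif-length buffer between sites
    n_total = n_tfs * n_sites
    unit = 2 * motif_len
    slack = seq_len - n_total * unit
    gaps = np.sort(rng.integers(0, slack + 1, size=n_total))
    starts = gaps + np.arange(n_total) * unit
    rng.shuffle(starts)
    site_rows = []
    site_iter = iter(starts)
    for pwm in pwms:
        cons = consensus[pwm.tf_name]
        for _ in range(n_sites):
            s = int(next(site_iter))
            seq[s:s + motif_len] = cons
            site_rows.append({"tf": pwm.tf_name, "start": s,
                              "end": s + motif_len})
    sites = pd.DataFrame(site_rows)

    # disruptive variants: half the sites per TF
    var_rows = []
    n_disrupt_per_tf = max(1, n_sites // 2)
    for pwm in pwms:
        tf_sites = sites[sites["tf"] == pwm.tf_name].reset_index(drop=True)
        chosen = rng.choice(len(tf_sites), size=n_disrupt_per_tf,
                            replace=False)
        for ci in chosen:
            s = int(tf_sites.loc[ci, "start"])
            col = int(rng.integers(0, motif_len))
            ref_i = int(consensus[pwm.tf_name][col])
            alt_i = int(rng.choice(np.delete(np.arange(4), ref_i)))
            var_rows.append({"chrom": chrom, "pos": s + col + 1,
                             "ref": BASES[ref_i], "alt": BASES[alt_i],
                             "tf": pwm.tf_name, "label": "disruptive"})

    # neutral variants: outside every site, with a full-motif buffer
    forbidden = np.zeros(seq_len, dtype=bool)
    for row in site_rows:
        lo = max(0, row["start"] - motif_len)
        hi = min(seq_len, row["end"] + motif_len)
        forbidden[lo:hi] = True
    free = np.flatnonzero(~forbidden)
    free = free[(free >= motif_len) & (free < seq_len - motif_len)]
    n_neutral = len(var_rows)
    neutral_pos = rng.choice(free, size=n_neutral, replace=False)
    for p0 in neutral_pos:
        ref_i = int(seq[p0])
        alt_i = int(rng.choice(np.delete(np.arange(4), ref_i)))
        var_rows.append({"chrom": chrom, "pos": int(p0) + 1,
                         "ref": BASES[ref_i], "alt": BASES[alt_i],
                         "tf": "", "label": "neutral"})

    variants = pd.DataFrame(var_rows)
    sequence = "".join(BASES[i] for i in seq)
    return PWMScenario(pwms, counts_by_tf, chrom, sequence, sites, variants)
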