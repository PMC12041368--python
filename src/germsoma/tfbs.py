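"""PWM scanning and motif-disruption scoring for germline and somatic
variants, plus the intersection of the two disrupted-TF lists.

Scores are log-likelihood sums min-max normalized to [0, 1]: the
per-column best base scores 1 (consensus) and the per-column worst base
scores 0.  A variant "disrupts" a motif when the better of its two allele
scores reaches the strong-site threshold and the allele difference
reaches the delta threshold.  Both alleles are scored over every window
overlapping the variant, on both strands; the best window may differ
between alleles.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (BASE_INDEX, BASES, GenomicInterval, PWM,
                         VariantRecord, normalize_chrom)

STRONG_SITE_THRESHOLD = 0.85
DELTA_THRESHOLD = 0.10


@dataclass(frozen=True)
class DisruptionCall:
    """Ref/alt motif scores for one variant x motif."""

    variant: VariantRecord
    tf_name: str
    ref_score: float
    alt_score: float
    delta: float
    disrupting: bool


@dataclass(frozen=True)
class TFBurdenRow:
    """Somatic mutation count inside one TF's predicted sites in an element."""

    tf_name: str
    element: GenomicInterval
    n_mutations: int
    passes_filter: bool


def _seq_to_idx(seq: str) -> np.ndarray:
    try:
        return np.fromiter((BASE_INDEX[b] for b in seq.upper()), dtype=np.int8,
                           count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in sequence: {exc}") from None


def _log_matrix(pwm: PWM) -> tuple[np.ndarray, float, float]:
    logp = np.log2(pwm.matrix)
    raw_max = float(logp.max(axis=0).sum())
    raw_min = float(logp.min(axis=0).sum())
    if raw_max == raw_min:
        raise ValueError(f"zero-information motif {pwm.tf_name}")
    return logp, raw_min, raw_max


def score_site(seq: str, pwm: PWM) -> float:
    """Normalized log-likelihood score of one window (single strand)."""
    if len(seq) != pwm.length:
        raise ValueError(
            f"window length {len(seq)} != motif length {pwm.length}"
        )
    idx = _seq_to_idx(seq)
    logp, raw_min, raw_max = _log_matrix(pwm)
    raw = float(logp[idx, np.arange(pwm.length)].sum())
    return (raw - raw_min) / (raw_max - raw_min)


def _window_scores(seq_idx: np.ndarray, pwm: PWM,
                   both_strands: bool = True) -> np.ndarray:
    """Best-of-strands normalized score at every window start."""
    L = pwm.length
    n = len(seq_idx) - L + 1
    if n <= 0:
        return np.empty(0)
    logp, raw_min, raw_max = _log_matrix(pwm)
    fwd = np.zeros(n)
    for j in range(L):
        fwd += logp[seq_idx[j:j + n], j]
    best = fwd
    if both_strands:
        # minus-strand site at the same window = reverse complement
        rc = 3 - seq_idx
        rev = np.zeros(n)
        for j in range(L):
            rev += logp[rc[L - 1 - j:L - 1 - j + n], j]
        best = np.maximum(fwd, rev)
    return (best - raw_min) / (raw_max - raw_min)


def score_variant(
    variant: VariantRecord,
    sequence_context: str,
    pwm: PWM,
    strong_site_threshold: float = STRONG_SITE_THRESHOLD,
    delta_threshold: float = DELTA_THRESHOLD,
    variant_offset: int | None = None,
) -> DisruptionCall:
    """Score a variant against one motif over all overlapping windows.

    ``sequence_context`` must cover motif_len - 1 bp on each side of the
    variant (the variant base sits at ``variant_offset``, by default the
    center).  Ref and alt are searched independently over all windows
    overlapping the variant, both strands.
    """
    L = pwm.length
    offset = (len(sequence_context) - 1) // 2 if variant_offset is None \
        else variant_offset
    context = sequence_context.upper()
    if context[offset] != variant.ref:
        raise ValueError(
            f"context base {context[offset]!r} at offset {offset} does not "
            f"match ref allele {variant.ref!r}"
        )
    if offset < L - 1 or len(context) - offset < L:
        raise ValueError("context must cover motif_len-1 bp on both sides")
    lo, hi = offset - (L - 1), offset + L
    ref_idx = _seq_to_idx(context[lo:hi])
    alt_idx = ref_idx.copy()
    alt_idx[L - 1] = BASE_INDEX[variant.alt]
    ref_score = float(_window_scores(ref_idx, pwm).max())
    alt_score = float(_window_scores(alt_idx, pwm).max())
    delta = ref_score - alt_score
    disrupting = (max(ref_score, alt_score) >= strong_site_threshold
                  and abs(delta) >= delta_threshold)
    return DisruptionCall(variant, pwm.tf_name, ref_score, alt_score,
                          delta, disrupting)


def germline_disrupted_tfs(
    variants: Sequence[VariantRecord],
    pwms: Sequence[PWM],
    sequences: Mapping[str, str],
    elements: Sequence[GenomicInterval] | None = None,
    strong_site_threshold: float = STRONG_SITE_THRESHOLD,
    delta_threshold: float = DELTA_THRESHOLD,
) -> tuple[pd.DataFrame, list[DisruptionCall]]:
    """Per-TF counts of motif-disrupting variants, within given elements.

    Variants are first restricted to the element set (>= 1 bp overlap;
    pass ``elements=None`` to keep all).  A variant disrupting several
    motifs contributes once to each TF.  Returns the per-TF count table,
    sorted descending, and the underlying disruption calls.
    """
    seqs = {normalize_chrom(c): s for c, s in sequences.items()}
    kept = []
    for v in variants:
        if elements is not None and not any(
                e.contains_pos(v.chrom, v.pos) for e in elements):
            continue
        kept.append(v)
    counts: dict[str, int] = defaultdict(int)
    calls: list[DisruptionCall] = []
    for v in kept:
        seq = seqs.get(normalize_chrom(v.chrom))
        if seq is None:
            continue
        p0 = v.pos - 1
        for pwm in pwms:
            L = pwm.length
            if p0 < L - 1 or p0 + L > len(seq):
                continue  # too close to the sequence edge for a full search
            context = seq[p0 - (L - 1):p0 + L]
            call = score_variant(v, context, pwm,
                                 strong_site_threshold, delta_threshold)
            calls.append(call)
            if call.disrupting:
                counts[pwm.tf_name] += 1
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["tf_name", "n_disrupting"],
    )
    return table, calls


def predict_sites(element: GenomicInterval, sequence: str, pwm: PWM,
                  site_threshold: float = STRONG_SITE_THRESHOLD
                  ) -> np.ndarray:
    """Boolean mask over the element's bp covered by predicted sites."""
    if element.end > len(sequence):
        raise ValueError(
            f"no sequence available for element "
            f"{element.chrom}:{element.start}-{element.end}"
        )
    seq_idx = _seq_to_idx(sequence[element.start:element.end])
    mask = np.zeros(element.width, dtype=bool)
    scores = _window_scores(seq_idx, pwm)
    L = pwm.length
    for s in np.flatnonzero(scores >= site_threshold):
        mask[s:s + L] = True
    return mask


def somatic_tf_burden(
    elements: Sequence[GenomicInterval],
    snvs: Sequence[VariantRecord],
    pwms: Sequence[PWM],
    sequences: Mapping[str, str],
    site_threshold: float = STRONG_SITE_THRESHOLD,
    min_mutations: int = 3,
) -> list[TFBurdenRow]:
    """Somatic mutation burden on predicted TF binding sites per element.

    Binding sites are predicted by scanning each element's sequence for
    windows scoring >= ``site_threshold`` (either strand).  Rows are
    emitted for every (TF, element) with at least one mutation in a
    predicted site; ``passes_filter`` requires >= ``min_mutations``
    mutations in that element's sites for that TF.
    """
    seqs = {normalize_chrom(c): s for c, s in sequences.items()}
    rows: list[TFBurdenRow] = []
    for element in elements:
        seq = seqs.get(normalize_chrom(element.chrom))
        if seq is None or element.end > len(seq):
            raise ValueError(
                f"no sequence available for element "
                f"{element.chrom}:{element.start}-{element.end}"
            )
        in_el = [v for v in snvs if element.contains_pos(v.chrom, v.pos)]
        if not in_el:
            continue
        offsets = np.array([v.pos - 1 - element.start for v in in_el])
        for pwm in pwms:
            if element.width < pwm.length:
                continue
            mask = predict_sites(element, seq, pwm, site_threshold)
            n_mut = int(mask[offsets].sum())
            if n_mut > 0:
                rows.append(TFBurdenRow(pwm.tf_name, element, n_mut,
                                        n_mut >= min_mutations))
    return rows


def intersect_tf_lists(germline_tfs: Sequence[str],
                       somatic_tfs: Sequence[str]) -> list[str]:
    """Exact name-set intersection, ordered as in the germline list.

    Dimer names such as ``"PPARA::RXRA"`` are matched as whole strings.
    """
    somatic = set(somatic_tfs)
    seen = set()
    out = []
    for tf in germline_tfs:
        if tf in somatic and tf not in seen:
            out.append(tf)
            seen.add(tf)
    return out
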