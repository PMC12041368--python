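import numpy as np
import pytest

from germsoma import synthetic_data as sd
from germsoma import tfbs
from germsoma.io_formats import BASES, GenomicInterval, PWM, VariantRecord, \
    pwm_from_counts

from helpers_oracles import pwm_raw_score

REVCOMP = str.maketrans("ACGT", "TGCA")


def _random_pwm(rng, name="TF", length=8):
    counts = rng.integers(0, 50, size=(4, length)).astype(float)
    counts[rng.integers(0, 4), 0] += 60  # guarantee information content
    return pwm_from_counts(name, counts, 0.8)


def _anti_consensus(pwm):
    return "".join(BASES[i] for i in pwm.matrix.argmin(axis=0))


# ---------------------------------------------------------------------------
# Window scoring
# ---------------------------------------------------------------------------

def test_consensus_scores_one_anticonsensus_zero(rng):
    for i in range(10):
        pwm = _random_pwm(rng, f"TF{i}")
        assert tfbs.score_site(pwm.consensus, pwm) == pytest.approx(1.0)
        assert tfbs.score_site(_anti_consensus(pwm), pwm) == \
            pytest.approx(0.0, abs=1e-12)


def test_score_matches_bruteforce_log_sum(rng):
    for _ in range(20):
        pwm = _random_pwm(rng, length=int(rng.integers(4, 12)))
        seq = "".join(rng.choice(list("ACGT"), size=pwm.length))
        raw = pwm_raw_score(seq, pwm.matrix)
        logp = np.log2(pwm.matrix)
        lo, hi = logp.min(axis=0).sum(), logp.max(axis=0).sum()
        assert tfbs.score_site(seq, pwm) == \
            pytest.approx((raw - lo) / (hi - lo), abs=1e-12)


def test_zero_information_motif_rejected():
    flat = PWM("flat", np.full((4, 5), 0.25))
    with pytest.raises(ValueError, match="zero-information"):
        tfbs.score_site("ACGTA", flat)


def test_strand_symmetry_of_best_window_search(rng):
    """Scoring a context against a motif must equal scoring the reverse
    complement context: the search covers both strands."""
    pwm = _random_pwm(rng)
    L = pwm.length
    seq = "".join(rng.choice(list("ACGT"), size=2 * L - 1))
    v = VariantRecord("chr1", L, seq[L - 1], "ACGT".replace(seq[L - 1],
                                                            "")[0])
    rc = seq.translate(REVCOMP)[::-1]
    v_rc = VariantRecord("chr1", L, rc[L - 1], v.alt.translate(REVCOMP))
    fwd = tfbs.score_variant(v, seq, pwm)
    rev = tfbs.score_variant(v_rc, rc, pwm)
    assert fwd.ref_score == pytest.approx(rev.ref_score, abs=1e-12)
    assert fwd.alt_score == pytest.approx(rev.alt_score, abs=1e-12)


# ---------------------------------------------------------------------------
# Variant disruption calls
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def scenario():
    g = sd.gen_genome(1, 20_000, seed=0)
    return sd.gen_pwms_and_variants(4, 8, g, 4, seed=13)


def _context(sc, pos, L):
    return sc.sequence[pos - 1 - (L - 1):pos - 1 + L]


def test_planted_disruptive_variants_flagged(scenario):
    sc = scenario
    pwms = {p.tf_name: p for p in sc.pwms}
    for row in sc.variants[sc.variants["label"] == "disruptive"].itertuples():
        pwm = pwms[row.tf]
        v = VariantRecord(row.chrom, row.pos, row.ref, row.alt)
        call = tfbs.score_variant(v, _context(sc, row.pos, pwm.length), pwm)
        assert call.ref_score == pytest.approx(1.0)
        assert call.alt_score < 1.0
        assert call.disrupting


def test_neutral_variants_not_flagged(scenario):
    sc = scenario
    n_false = 0
    n_total = 0
    for row in sc.variants[sc.variants["label"] == "neutral"].itertuples():
        v = VariantRecord(row.chrom, row.pos, row.ref, row.alt)
        for pwm in sc.pwms:
            call = tfbs.score_variant(v, _context(sc, row.pos, pwm.length),
                                      pwm)
            n_total += 1
            n_false += call.disrupting
    assert n_false / n_total <= 0.1


def test_ref_mismatch_with_context_errors(scenario):
    sc = scenario
    pwm = sc.pwms[0]
    row = sc.variants.iloc[0]
    ctx = _context(sc, row.pos, pwm.length)
    wrong_ref = next(b for b in "ACGT" if b != ctx[pwm.length - 1])
    alt = next(b for b in "ACGT" if b not in (wrong_ref,))
    v = VariantRecord(row.chrom, int(row.pos), wrong_ref, alt)
    with pytest.raises(ValueError, match="does not match ref"):
        tfbs.score_variant(v, ctx, pwm)


# ---------------------------------------------------------------------------
# Germline counts / somatic burden
# ---------------------------------------------------------------------------

def test_germline_counts_per_tf(scenario):
    sc = scenario
    seqs = {sc.chrom: sc.sequence}
    variants = [VariantRecord(r.chrom, r.pos, r.ref, r.alt)
                for r in sc.variants.itertuples()]
    counts, calls = tfbs.germline_disrupted_tfs(variants, sc.pwms, seqs)
    counts = counts.set_index("tf_name")["n_disrupting"]
    truth = sc.variants[sc.variants["label"] == "disruptive"] \
        .groupby("tf")["pos"].count()
    for tf, expected in truth.items():
        assert counts.get(tf, 0) >= expected  # every planted one recovered
    # extra calls (chance strong sites, similar motifs) stay a small
    # fraction of all scored (variant, TF) pairs
    n_pairs = len(variants) * len(sc.pwms)
    assert (counts.sum() - truth.sum()) / n_pairs <= 0.1


def test_germline_counts_restricted_to_elements(scenario):
    sc = scenario
    seqs = {sc.chrom: sc.sequence}
    variants = [VariantRecord(r.chrom, r.pos, r.ref, r.alt)
                for r in sc.variants.itertuples()]
    empty_el = [GenomicInterval(sc.chrom, 0, 1)]
    counts, calls = tfbs.germline_disrupted_tfs(variants, sc.pwms, seqs,
                                                elements=empty_el)
    assert counts.empty and not calls


def test_somatic_burden_min_mutation_filter(scenario):
    sc = scenario
    seqs = {sc.chrom: sc.sequence}
    pwm = sc.pwms[0]
    site = sc.sites[sc.sites["tf"] == pwm.tf_name].iloc[0]
    element = GenomicInterval(sc.chrom, max(0, site["start"] - 50),
                              site["end"] + 50)
    def snv_at(offset, sample):
        p0 = site["start"] + offset
        ref = sc.sequence[p0]
        alt = next(b for b in "ACGT" if b != ref)
        return VariantRecord(sc.chrom, p0 + 1, ref, alt, sample)

    three = [snv_at(i, f"S{i}") for i in range(3)]
    rows = tfbs.somatic_tf_burden([element], three, [pwm], seqs)
    mine = [r for r in rows if r.tf_name == pwm.tf_name]
    assert mine and mine[0].n_mutations == 3 and mine[0].passes_filter

    rows2 = tfbs.somatic_tf_burden([element], three[:2], [pwm], seqs)
    mine2 = [r for r in rows2 if r.tf_name == pwm.tf_name]
    assert mine2 and mine2[0].n_mutations == 2 and not mine2[0].passes_filter


def test_snv_outside_predicted_sites_contributes_nothing(scenario):
    sc = scenario
    seqs = {sc.chrom: sc.sequence}
    pwm = sc.pwms[0]
    # a neutral-position SNV sits outside all predicted sites
    neutral = sc.variants[sc.variants["label"] == "neutral"].iloc[0]
    element = GenomicInterval(sc.chrom, max(0, neutral["pos"] - 30),
                              neutral["pos"] + 30)
    snv = VariantRecord(sc.chrom, int(neutral["pos"]), neutral["ref"],
                        neutral["alt"], "S0")
    rows = tfbs.somatic_tf_burden([element], [snv], [pwm], seqs)
    assert rows == []


def test_element_without_sequence_errors(scenario):
    sc = scenario
    with pytest.raises(ValueError, match="no sequence"):
        tfbs.somatic_tf_burden(
            [GenomicInterval("chr99", 0, 100)],
            [VariantRecord("chr99", 10, "A", "G", "S0")],
            sc.pwms, {sc.chrom: sc.sequence})


# ---------------------------------------------------------------------------
# TF list intersection
# ---------------------------------------------------------------------------

def test_intersect_tf_lists():
    assert tfbs.intersect_tf_lists(["A", "B", "C"], ["B", "C", "D"]) == \
        ["B", "C"]
    assert tfbs.intersect_tf_lists(["A"], ["B"]) == []
    # dimer names are whole strings, not split on the separator
    assert tfbs.intersect_tf_lists(["PPARA::RXRA", "RXRA"],
                                   ["PPARA::RXRA"]) == ["PPARA::RXRA"]
    assert tfbs.intersect_tf_lists(["PPARA"], ["PPARA::RXRA"]) == []
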