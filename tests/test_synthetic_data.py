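import numpy as np
import pytest

from germsoma import synthetic_data as sd
from germsoma.io_formats import GenomicInterval

from helpers_oracles import ols_slope_pvalue


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def test_gen_genome_construction():
    g = sd.gen_genome(2, 1_000_000, seed=1)
    assert g.chrom_names == ("chr1", "chr2")
    assert g.chrom_sizes["chr1"] == 1_000_000
    assert sd.gen_genome(2, 1_000_000, seed=7) == \
        sd.gen_genome(2, 1_000_000, seed=7)


def test_gen_genome_rejects_bad_args():
    with pytest.raises(ValueError):
        sd.gen_genome(0, 1_000_000)
    with pytest.raises(ValueError):
        sd.gen_genome(1, 5_000)


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------

def test_tracks_disjoint_within_class_sorted_and_bounded(genome_100kb):
    tracks = sd.gen_annotation_tracks(genome_100kb,
                                      ["enhancer", "promoter"], 30, 400,
                                      seed=3)
    assert set(tracks) == {"enhancer", "promoter"}
    for cls, ivs in tracks.items():
        assert len(ivs) == 30
        assert ivs == sorted(ivs, key=lambda i: i.sort_key())
        for a, b in zip(ivs[:-1], ivs[1:]):
            assert a.end <= b.start  # disjoint within class
        for iv in ivs:
            assert 0 <= iv.start < iv.end <= 100_000
            assert iv.name.startswith(cls)


def test_tracks_mass_exceeding_genome_errors(genome_100kb):
    with pytest.raises(ValueError, match="exceeds"):
        sd.gen_annotation_tracks(genome_100kb, ["big"], 100, 50_000, seed=0)


# ---------------------------------------------------------------------------
# SNVs
# ---------------------------------------------------------------------------

def test_snvs_zero_rate_yields_empty_table(genome_100kb):
    assert sd.gen_snvs(genome_100kb, 5, 0.0, seed=0) == []


def test_snvs_deterministic_for_fixed_seed(genome_100kb):
    a = sd.gen_snvs(genome_100kb, 5, 1e-4, seed=11)
    b = sd.gen_snvs(genome_100kb, 5, 1e-4, seed=11)
    assert a == b
    assert a != sd.gen_snvs(genome_100kb, 5, 1e-4, seed=12)


def test_snvs_ref_alt_valid_and_within_genome(genome_100kb):
    snvs = sd.gen_snvs(genome_100kb, 10, 1e-4, seed=2)
    for v in snvs:
        assert v.ref != v.alt
        assert 1 <= v.pos <= 100_000


def test_hotspot_density_approaches_rate_multiplier(genome_100kb):
    """Pooled over seeds, hotspot mut density / background ≈ multiplier."""
    hs = sd.PlantedHotspot(GenomicInterval("chr1", 10_000, 11_000), 50.0)
    hot, bg = 0, 0
    for seed in range(30):
        snvs = sd.gen_snvs(genome_100kb, 20, 1e-5, [hs], seed=seed)
        for v in snvs:
            if 10_000 <= v.pos - 1 < 11_000:
                hot += 1
            else:
                bg += 1
    hot_density = hot / 1_000
    bg_density = bg / 99_000
    assert hot_density / bg_density == pytest.approx(50.0, rel=0.2)


# ---------------------------------------------------------------------------
# Expression / activities
# ---------------------------------------------------------------------------

def test_activities_nonnegative_and_slope_recovered():
    genes = [f"G{i}" for i in range(40)]
    planted = sd.PlantedAssociation("G5", "SBS3", 2.0, 0.01)
    expr, act = sd.gen_signature_expression(89, genes, ["SBS1", "SBS3"],
                                            [planted], seed=4)
    assert (act.to_numpy() >= 0).all()
    slope, _ = ols_slope_pvalue(expr["G5"].to_numpy(),
                                act["SBS3"].to_numpy())
    assert slope == pytest.approx(2.0, abs=0.1)


def test_unplanted_pairs_are_null_calibrated():
    """With nothing planted, ~5% of pairwise regressions reach p<0.05."""
    genes = [f"G{i}" for i in range(60)]
    sigs = [f"SBS{i}" for i in range(20)]
    n_sig = n_tot = 0
    for seed in range(5):
        expr, act = sd.gen_signature_expression(89, genes, sigs, [],
                                                seed=seed)
        for g in genes[:30]:
            for s in sigs:
                _, p = ols_slope_pvalue(expr[g].to_numpy(),
                                        act[s].to_numpy())
                n_tot += 1
                n_sig += p < 0.05
    frac = n_sig / n_tot
    mc = 3 * np.sqrt(0.05 * 0.95 / n_tot)
    assert abs(frac - 0.05) < mc + 0.01


def test_duplicate_gene_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        sd.gen_signature_expression(10, ["G1", "G1"], ["S1"], [], seed=0)


# ---------------------------------------------------------------------------
# CNA segments
# ---------------------------------------------------------------------------

def test_segments_tile_each_chromosome_exactly(genome_100kb):
    segs = sd.gen_cna_segments(genome_100kb, 5, seed=1)
    by_sample = {}
    for s in segs:
        by_sample.setdefault(s.sample, []).append(s)
    assert len(by_sample) == 5
    for sample_segs in by_sample.values():
        sample_segs.sort(key=lambda s: s.start)
        assert sample_segs[0].start == 0
        assert sample_segs[-1].end == 100_000
        for a, b in zip(sample_segs[:-1], sample_segs[1:]):
            assert a.end == b.start


def test_full_penetrance_amplifies_every_sample(genome_100kb):
    spec = sd.RecurrentCNASpec(GenomicInterval("chr1", 20_000, 30_000),
                               "amp", 1.0)
    segs = sd.gen_cna_segments(genome_100kb, 20, [spec], seed=2)
    amped = {
        s.sample for s in segs
        if s.start == 20_000 and s.end == 30_000 and s.seg_mean >= 0.5
    }
    assert len(amped) == 20


def test_partial_penetrance_matches_binomial(genome_100kb):
    spec = sd.RecurrentCNASpec(GenomicInterval("chr1", 20_000, 30_000),
                               "del", 0.6)
    segs = sd.gen_cna_segments(genome_100kb, 100, [spec], seed=3)
    hit = {
        s.sample for s in segs
        if s.start == 20_000 and s.end == 30_000 and s.seg_mean <= -0.5
    }
    # 3 sigma binomial band around 60
    assert abs(len(hit) - 60) <= 3 * np.sqrt(100 * 0.6 * 0.4)


def test_opposite_sign_overlap_rejected(genome_100kb):
    a = sd.RecurrentCNASpec(GenomicInterval("chr1", 0, 10_000), "amp", 0.5)
    b = sd.RecurrentCNASpec(GenomicInterval("chr1", 5_000, 15_000), "del",
                            0.5)
    with pytest.raises(ValueError, match="opposite sign"):
        sd.gen_cna_segments(genome_100kb, 5, [a, b], seed=0)


# ---------------------------------------------------------------------------
# PWMs and planted variants
# ---------------------------------------------------------------------------

def test_pwm_scenario_structure():
    g = sd.gen_genome(1, 20_000, seed=0)
    sc = sd.gen_pwms_and_variants(3, 8, g, 4, seed=5)
    assert len(sc.pwms) == 3
    for pwm in sc.pwms:
        np.testing.assert_allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-9)
    # every planted site carries the motif consensus on the sequence
    cons = {p.tf_name: p.consensus for p in sc.pwms}
    for row in sc.sites.itertuples():
        assert sc.sequence[row.start:row.end] == cons[row.tf]
    # variant bookkeeping: disruptive inside a site, neutral outside all
    labels = sc.variants["label"].value_counts()
    assert labels["disruptive"] == labels["neutral"]
    site_bp = set()
    for row in sc.sites.itertuples():
        site_bp.update(range(row.start, row.end))
    for row in sc.variants.itertuples():
        inside = (row.pos - 1) in site_bp
        assert inside == (row.label == "disruptive")
        assert sc.sequence[row.pos - 1] == row.ref


def test_pwm_scenario_rejects_impossible_requests():
    g = sd.gen_genome(1, 10_000, seed=0)
    with pytest.raises(ValueError):
        sd.gen_pwms_and_variants(2, 3, g, 4, seed=0)  # motif too short
    with pytest.raises(ValueError, match="do not fit"):
        sd.gen_pwms_and_variants(50, 20, g, 100, seed=0)
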