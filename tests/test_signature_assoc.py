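import numpy as np
import pandas as pd
import pytest

from germsoma import signature_assoc as sa
from germsoma import synthetic_data as sd

from helpers_oracles import ols_slope_pvalue


# ---------------------------------------------------------------------------
# fit_pair
# ---------------------------------------------------------------------------

def test_perfect_linearity_gives_exact_slope():
    r = sa.fit_pair([1, 2, 3, 4], [2, 4, 6, 8])
    assert r.slope == pytest.approx(2.0, abs=1e-12)
    assert r.p_value < 1e-10


def test_constant_activity_gives_null_result():
    r = sa.fit_pair([1, 2, 3, 4], [5, 5, 5, 5])
    assert (r.slope, r.p_value) == (0.0, 1.0)


def test_zero_expression_variance_flagged_degenerate():
    r = sa.fit_pair([2, 2, 2, 2], [1, 3, 2, 4])
    assert r.degenerate and r.p_value == 1.0 and r.slope == 0.0


def test_noisy_pair_matches_closed_form():
    r = sa.fit_pair([1, 2, 3, 4], [2.1, 3.9, 6.2, 7.8])
    slope, p = ols_slope_pvalue(np.array([1, 2, 3, 4.0]),
                                np.array([2.1, 3.9, 6.2, 7.8]))
    assert r.slope == pytest.approx(slope, abs=1e-12)
    assert r.p_value == pytest.approx(p, abs=1e-12)
    assert r.slope == pytest.approx(1.94, abs=0.005)
    assert r.p_value == pytest.approx(0.00217, abs=5e-5)


def test_missing_values_dropped_pairwise():
    x = [1, 2, np.nan, 4, 5]
    y = [2, 4, 6, np.nan, 10]
    r = sa.fit_pair(x, y)
    assert r.n_samples == 3
    assert r.slope == pytest.approx(2.0, abs=1e-9)


def test_pvalues_match_t_oracle_on_random_vectors(rng):
    for _ in range(50):
        n = int(rng.integers(5, 30))
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)
        r = sa.fit_pair(x, y)
        _, p = ols_slope_pvalue(x, y)
        assert abs(r.p_value - p) < 1e-10


def test_vectorized_scan_agrees_with_fit_pair():
    expr, act = sd.gen_signature_expression(
        30, ["G1", "G2", "G3"], ["S1", "S2"],
        [sd.PlantedAssociation("G1", "S1", 1.0, 0.5)], seed=9)
    results, _ = sa.scan(expr, act, ["G1", "G2", "G3"],
                         log_transform=False)
    for row in results.itertuples():
        r = sa.fit_pair(expr[row.gene], act[row.signature])
        assert row.p_value == pytest.approx(r.p_value, abs=1e-9)
        assert row.slope == pytest.approx(r.slope, abs=1e-9)


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def planted_dataset():
    genes = [f"G{i}" for i in range(50)]
    planted = sd.PlantedAssociation("G0", "SBS3", 2.0, 0.05)
    expr, act = sd.gen_signature_expression(
        89, genes, ["SBS1", "SBS3", "SBS5"], [planted], seed=21)
    return expr, act


def test_scan_recovers_planted_pair(planted_dataset):
    expr, act = planted_dataset
    results, counts = sa.scan(expr, act, [f"G{i}" for i in range(5)])
    sig = results[results["significant"]]
    assert ("G0", "SBS3") in set(zip(sig["gene"], sig["signature"]))
    # at most a few false positives among the other 14 tests
    assert len(sig) <= 1 + 3
    assert counts.loc[counts["signature"] == "SBS3",
                      "n_significant"].item() >= 1


def test_scan_alpha_zero_nothing_significant(planted_dataset):
    expr, act = planted_dataset
    _, counts = sa.scan(expr, act, [f"G{i}" for i in range(5)], alpha=0.0)
    assert (counts["n_significant"] == 0).all()


def test_scan_skips_absent_genes(planted_dataset):
    expr, act = planted_dataset
    results, counts = sa.scan(expr, act, ["G1", "NOT_A_GENE"])
    assert set(results["gene"]) == {"G1"}
    assert (counts["n_significant"] <= 1).all()


def test_scan_empty_sample_intersection_errors(planted_dataset):
    expr, act = planted_dataset
    act2 = act.copy()
    act2.index = [f"X{i}" for i in range(len(act2))]
    with pytest.raises(ValueError, match="samples"):
        sa.scan(expr, act2, ["G1"])


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def test_permutation_pvalue_is_strict_exceed_fraction(planted_dataset):
    expr, act = planted_dataset
    perm = sa.permutation_test(expr, act, ["G0", "G1", "G2"], n_iter=500,
                               seed=1)
    assert perm.p_value == perm.n_exceed / perm.n_iter
    assert len(perm.null_counts) == 500
    assert (perm.p_value == 0.0) == (perm.observed >= perm.null_counts.max())


def test_permutation_p_zero_iff_observed_above_all_nulls():
    """A list holding every strongly planted gene beats all random lists."""
    genes = [f"G{i}" for i in range(100)]
    planted = [sd.PlantedAssociation(f"G{i}", f"S{i}", 2.0, 0.05)
               for i in range(5)]
    expr, act = sd.gen_signature_expression(
        89, genes, [f"S{i}" for i in range(5)], planted, seed=3)
    perm = sa.permutation_test(expr, act, [f"G{i}" for i in range(5)],
                               n_iter=300, seed=4)
    assert perm.observed >= 5
    assert perm.p_value <= 0.05


def test_permutation_requires_iterations_and_gene_pool(planted_dataset):
    expr, act = planted_dataset
    with pytest.raises(ValueError):
        sa.permutation_test(expr, act, ["G1"], n_iter=0, seed=0)
    with pytest.raises(ValueError, match="more genes"):
        sa.permutation_test(expr[["G1", "G2"]], act, ["G1", "G2"],
                            n_iter=10, seed=0)


def test_adding_planted_signal_never_raises_p():
    """Permutation p is monotone in planted signal strength over seeds."""
    genes = [f"G{i}" for i in range(80)]
    sigs = [f"S{i}" for i in range(5)]
    cand = [f"G{i}" for i in range(10)]
    for seed in range(3):
        expr0, act0 = sd.gen_signature_expression(60, genes, sigs, [],
                                                  seed=seed)
        planted = [sd.PlantedAssociation(g, "S0", 3.0, 0.05)
                   for g in cand[:5]]
        expr1, act1 = sd.gen_signature_expression(60, genes, sigs, planted,
                                                  seed=seed)
        p0 = sa.permutation_test(expr0, act0, cand, n_iter=200,
                                 seed=seed).p_value
        p1 = sa.permutation_test(expr1, act1, cand, n_iter=200,
                                 seed=seed).p_value
        assert p1 <= p0


# ---------------------------------------------------------------------------
# Etiology groups
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("signature,group", [
    ("SBS26", "mismatch repair deficiency"),
    ("DBS7", "mismatch repair deficiency"),
    ("ID1", "homologous recombination deficiency"),
    ("SBS3", "homologous recombination deficiency"),
    ("SBS40", "age-related mutagenesis"),
    ("SBS35", "platinum chemotherapy treatment"),
    ("SBS18", "environmental factors"),
    ("SBS13", "APOBEC mutagenesis"),
    ("SBS99", "unassigned"),
])
def test_etiology_grouping(signature, group):
    assert sa.map_etiology(signature) == group


def test_every_signature_maps_to_exactly_one_group():
    groups = {sa.map_etiology(s) for s in sa.DEFAULT_ETIOLOGY}
    assert len(sa.DEFAULT_ETIOLOGY) == 20
    assert "unassigned" not in groups
    assert len(groups) == 6
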