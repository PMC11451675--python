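"""Synthetic study generator: determinism, calibration, ground-truth recovery."""

import numpy as np
import pytest
from scipy import stats

import gwaspar as g
from gwaspar.simulate import _simulate_block_records


def small_config(seed=5):
    return g.SimulationConfig(
        seed=seed,
        ancestries=[g.AncestrySpec("EUR", 5000, 5000), g.AncestrySpec("AFR", 3000, 4000)],
        loci=[
            g.LocusSpec("L1", n_variants=1, true_or=1.4, true_raf=0.25),
            g.LocusSpec("L2", n_variants=5, causal_index=2, true_or=1.3,
                        true_raf=0.4, ld_rho=0.6),
        ],
        protective_fraction=0.3,
    )


def test_same_seed_reproduces_study_exactly():
    s1, t1 = g.simulate_study(small_config())
    s2, t2 = g.simulate_study(small_config())
    assert t1.equals(t2)
    for label in s1:
        assert s1[label].variants == s2[label].variants
    s3, _ = g.simulate_study(small_config(seed=6))
    assert s3["EUR"].variants != s1["EUR"].variants


def test_ground_truth_par_matches_levin_formula():
    _, truth = g.simulate_study(small_config())
    row = truth[(truth.ancestry == "EUR") & (truth.locus == "L2")].iloc[0]
    assert row.true_par == pytest.approx(g.compute_par(0.4, 1.3))
    assert g.compute_par(0.3, 1.3) == pytest.approx(0.09 / 1.09, abs=1e-12)


def test_zero_loci_study_is_valid_and_empty():
    cfg = g.SimulationConfig(seed=1, ancestries=[g.AncestrySpec("EUR", 100, 100)], loci=[])
    strata, truth = g.simulate_study(cfg)
    assert len(strata["EUR"]) == 0 and truth.empty


def test_null_variant_mean_beta_near_zero():
    rng = np.random.default_rng(42)
    betas = np.array([
        g.simulate_single_variant(2000, 2000, 0.3, 1.0, rng).beta for _ in range(1000)
    ])
    se_mean = betas.std(ddof=1) / np.sqrt(len(betas))
    assert abs(betas.mean()) < 3 * se_mean


def test_flipped_emission_recovers_truth_after_harmonization():
    rng = np.random.default_rng(9)
    rec = g.simulate_single_variant(
        20000, 20000, 0.3, 1.3, rng, protective_fraction=1.0
    )
    assert rec.beta < 0 and rec.effect_allele == "G"
    h = g.harmonize_variant(rec)
    assert h.flipped and h.risk_allele == "A"
    assert h.odds_ratio >= 1.0
    assert h.raf == pytest.approx(1.0 - rec.eaf)
    assert h.raf == pytest.approx(0.3, abs=0.05)  # pooled sample frequency near truth


def test_or_estimator_calibrated_against_generating_value():
    rng = np.random.default_rng(123)
    ors = np.exp([
        g.simulate_single_variant(20000, 20000, 0.3, 1.3, rng).beta for _ in range(200)
    ])
    assert ors.mean() == pytest.approx(1.3, abs=0.01)


class TestLocusBlock:
    def test_ar1_matrix_is_spd(self):
        R = g.ar1_ld(20, 0.7)
        assert np.allclose(R, R.T)
        assert np.linalg.eigvalsh(R).min() > 0

    def test_independent_variants_have_null_mean_z(self):
        spec = g.LocusSpec("L", n_variants=5, causal_index=0, true_or=1.3,
                           true_raf=0.3, ld_rho=0.0)
        anc = g.AncestrySpec("EUR", 20000, 20000)
        rng = np.random.default_rng(21)
        zs = []
        for _ in range(500):
            records, _ = _simulate_block_records(spec, anc, rng)
            zs.append([r.beta / r.se for r in records[1:]])
        zs = np.array(zs)
        se = zs.std(ddof=1) / np.sqrt(len(zs))
        assert (np.abs(zs.mean(axis=0)) < 3 * se.mean()).all()

    def test_causal_mean_z_matches_configured_lambda(self):
        spec = g.LocusSpec("L", n_variants=3, causal_index=1, true_or=1.3,
                           true_raf=0.3, ld_rho=0.5)
        anc = g.AncestrySpec("EUR", 20000, 20000)
        lam = g.expected_z(1.3, 0.3, 20000, 20000)
        rng = np.random.default_rng(77)
        z_causal = []
        for _ in range(500):
            records, _ = _simulate_block_records(spec, anc, rng)
            v = records[1]
            z_causal.append(v.beta / v.se)
        mean = np.mean(z_causal)
        mc_se = np.std(z_causal, ddof=1) / np.sqrt(len(z_causal))
        assert mean == pytest.approx(lam, abs=3.5 * mc_se)

    def test_block_carries_valid_ld_and_harmonized_members(self):
        spec = g.LocusSpec("L", n_variants=4, causal_index=0, true_or=1.5,
                           true_raf=0.2, ld_rho=0.7)
        block = g.simulate_locus_block(spec, g.AncestrySpec("EUR", 5000, 5000),
                                       np.random.default_rng(1),
                                       protective_fraction=0.5)
        assert block.ld.shape == (4, 4)
        assert all(v.odds_ratio >= 1 for v in block.variants)

    def test_invalid_configs_rejected(self):
        with pytest.raises(g.ConfigError):
            g.LocusSpec("L", n_variants=2, causal_index=5)
        with pytest.raises(g.ConfigError):
            g.LocusSpec("L", ld_rho=1.0)
        with pytest.raises(g.ConfigError):
            g.SimulationConfig(seed=1, ancestries=[], loci=[], prevalence=0.9)


def test_wald_pvalues_uniform_under_null():
    """KS uniformity of two-sided Wald p-values at true OR = 1."""
    rng = np.random.default_rng(2024)
    pvals = [
        g.simulate_single_variant(2000, 2000, 0.3, 1.0, rng).p_value for _ in range(500)
    ]
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
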