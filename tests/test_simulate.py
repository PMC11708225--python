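"""Synthetic data generators and study drivers."""

import numpy as np
import pytest

from mageit.simulate import (
    A4GALT_LIKE,
    NULL_SET,
    TIMP3_LIKE,
    ScenarioConfig,
    power_study,
    scenario_grid,
    simulate_binary,
    simulate_continuous,
    simulate_genotypes,
    type1_study,
)


class TestSimulateGenotypes:
    def test_gene_profile_counts(self):
        assert (A4GALT_LIKE.n_common, A4GALT_LIKE.n_rare) == (38, 162)
        assert (TIMP3_LIKE.n_common, TIMP3_LIKE.n_rare) == (107, 189)
        assert (NULL_SET.n_common, NULL_SET.n_rare) == (2, 8)

    def test_empirical_maf_tracks_target(self):
        rng = np.random.default_rng(0)
        markers, maf = simulate_genotypes(A4GALT_LIKE, 5000, rng)
        emp = markers.dosages.mean(axis=0) / 2.0
        se = np.sqrt(maf * (1 - maf) / (2 * 5000))
        assert np.mean(np.abs(emp - maf) < 3 * se) > 0.98

    def test_deterministic_given_seed(self):
        a, maf_a = simulate_genotypes(NULL_SET, 200, np.random.default_rng(5))
        b, maf_b = simulate_genotypes(NULL_SET, 200, np.random.default_rng(5))
        np.testing.assert_array_equal(a.dosages, b.dosages)
        np.testing.assert_array_equal(maf_a, maf_b)

    def test_ld_mode_matches_maf_and_correlates_neighbours(self):
        rng = np.random.default_rng(1)
        markers, maf = simulate_genotypes(
            ScenarioConfig().profile, 8000, rng, ld_rho=0.7
        )
        emp = markers.dosages.mean(axis=0) / 2.0
        # allele frequencies still honoured under the copula
        assert np.corrcoef(emp, np.minimum(maf, 1 - maf))[0, 1] > 0.99
        # neighbouring common variants show positive dosage correlation
        common = np.flatnonzero(maf > 0.2)
        adj = [c for c in common if c + 1 in set(common)]
        rs = [
            np.corrcoef(markers.dosages[:, c], markers.dosages[:, c + 1])[0, 1]
            for c in adj[:10]
        ]
        assert np.mean(rs) > 0.3


class TestTraitModels:
    def test_zero_effect_zero_noise_is_deterministic_mean(self):
        """With beta = gamma = 0 and no noise, y is the fixed-effect mean exactly."""
        cfg = ScenarioConfig(
            trait_type="continuous", profile=NULL_SET, n=50, null=True,
            noise_sd=0.0, beta_common=0.0, beta_rare=0.0,
        )
        d = simulate_continuous(cfg, np.random.default_rng(3))
        X, E = d.inputs.covariates, d.inputs.environment
        np.testing.assert_allclose(
            d.inputs.phenotype, 0.05 * X[:, 0] + 0.057 * X[:, 1] + 0.64 * E, atol=1e-12
        )

    def test_sign_patterns_balance_each_class(self):
        cfg = ScenarioConfig(trait_type="continuous", profile=NULL_SET, sign_pattern=(0.5, 0.5), n=100)
        rng = np.random.default_rng(9)
        d = simulate_continuous(cfg, rng)
        beta, gamma = d.truth["beta"], d.truth["gamma"]
        maf = d.truth["true_maf"]
        for coef, idx in ((beta, d.truth["main_idx"]), (gamma, d.truth["inter_idx"])):
            rare = maf[idx] < 0.05
            assert np.sum(coef[rare] < 0) == np.sum(rare) // 2
            assert np.sum(coef[~rare] < 0) == np.sum(~rare) // 2

    def test_scenario_grid_enumerates_crossing(self):
        for trait in ("continuous", "binary"):
            grid = scenario_grid(trait)
            assert len(grid) == 32
            assert len({(g.profile.name, g.causal_selection, g.sign_pattern, g.gamma_rare) for g in grid}) == 32
        # both trait types together: the full 64-scenario crossing
        assert len(scenario_grid("continuous")) + len(scenario_grid("binary")) == 64


class TestSimulateBinary:
    def test_exact_case_control_quota(self):
        cfg = ScenarioConfig(trait_type="binary", profile=NULL_SET, n=400, null=True)
        d = simulate_binary(cfg, np.random.default_rng(2), block_size=4000)
        y = d.inputs.phenotype
        assert int(y.sum()) == 200
        assert len(y) == 400

    def test_population_prevalence_near_design_value(self):
        """Null-coefficient logistic model: prevalence ~ 0.08."""
        cfg = ScenarioConfig(trait_type="binary", profile=NULL_SET, n=1000, null=True)
        d = simulate_binary(cfg, np.random.default_rng(4), block_size=30000)
        prev = d.truth["population_prevalence"]
        # design targets a prevalence just under 0.09
        assert 0.06 < prev < 0.11

    def test_deterministic_given_seed(self):
        cfg = ScenarioConfig(trait_type="binary", profile=NULL_SET, n=200, null=True)
        a = simulate_binary(cfg, np.random.default_rng(8), block_size=3000)
        b = simulate_binary(cfg, np.random.default_rng(8), block_size=3000)
        np.testing.assert_array_equal(a.inputs.markers.dosages, b.inputs.markers.dosages)
        np.testing.assert_array_equal(a.inputs.phenotype, b.inputs.phenotype)


class TestStudyDrivers:
    def test_type1_reproducible_and_documented(self):
        r1 = type1_study(n=300, n_reps=30, alpha_levels=(0.05,), seed=13)
        r2 = type1_study(n=300, n_reps=30, alpha_levels=(0.05,), seed=13)
        np.testing.assert_array_equal(r1.pvalues, r2.pvalues)
        assert set(r1.table.columns) >= {"alpha", "rate", "ci_low", "ci_high"}

    def test_broken_pvalue_caught_by_calibration_check(self):
        """Negative control: squaring the p-values wrecks calibration."""
        res = type1_study(n=300, n_reps=200, alpha_levels=(0.2,), seed=1)
        honest = res.rate(0.2)
        broken = float(np.mean(res.pvalues**2 < 0.2))
        # p^2 < 0.2 <=> p < 0.447: the broken rate is far above nominal here,
        # and the uniform-null expectation p^2 ~ rate 0.447 is detectably off 0.2
        assert abs(broken - 0.447) < 0.12
        assert abs(honest - 0.2) < 0.1

    def test_power_at_null_config_reduces_to_alpha(self):
        cfg = ScenarioConfig(trait_type="continuous", profile=NULL_SET, n=300, null=True)
        with pytest.warns(UserWarning, match="null config"):
            res = power_study(cfg, n_reps=200, alpha=0.2, seed=3)
        assert abs(res.rate(0.2) - 0.2) < 0.12

    def test_power_detects_strong_interaction(self):
        cfg = ScenarioConfig(
            trait_type="continuous", profile=NULL_SET, n=400, gamma_rare=2.0, gamma_common=2.0
        )
        res = power_study(cfg, n_reps=40, alpha=1e-3, seed=5)
        assert res.rate(1e-3) > 0.8
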