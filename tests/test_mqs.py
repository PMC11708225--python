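"""Method-of-moments component estimation: oracles and sampling properties."""

import numpy as np
import pytest

from mageit.kernels import build_kernels
from mageit.mqs import (
    estimate_fix,
    estimate_null_fix,
    estimate_null_ran,
    estimate_ran,
    kernel_traces,
)

from conftest import make_inputs


def dense_ran_solve(bundle):
    """Independent dense-matrix solve of the 3x3 moment system."""
    M = bundle.projector.dense()
    Gs = bundle.Gfac @ bundle.Gfac.T
    Ss = bundle.Sfac @ bundle.Sfac.T
    lam = np.array(
        [
            [np.trace(Gs @ Gs), np.trace(Gs @ Ss), np.trace(Gs @ M)],
            [np.trace(Ss @ Gs), np.trace(Ss @ Ss), np.trace(Ss @ M)],
            [np.trace(M @ Gs), np.trace(M @ Ss), np.trace(M @ M)],
        ]
    )
    y = bundle.y_star
    rhs = np.array([y @ Gs @ y, y @ Ss @ y, y @ M @ y])
    return np.linalg.solve(lam, rhs), lam


class TestEstimateRan:
    def test_zero_response_gives_zero_estimates(self, ran_bundle):
        ran_bundle.y_star = np.zeros(ran_bundle.n)
        est = estimate_ran(ran_bundle)
        assert est.omega2 == est.sigma2 == est.tau2 == 0.0

    def test_factor_path_equals_dense_solve(self):
        for seed in range(5):
            bundle = build_kernels(make_inputs(n=40, p=4, seed=seed), mode="random_main")
            est = estimate_ran(bundle)
            dense, lam_dense = dense_ran_solve(bundle)
            np.testing.assert_allclose(
                [est.omega2, est.sigma2, est.tau2], dense, rtol=1e-8, atol=1e-12
            )
            np.testing.assert_allclose(est.lambda_matrix, lam_dense, rtol=1e-8)

    def test_moment_equations_satisfied(self, ran_bundle):
        est = estimate_ran(ran_bundle)
        lhs = est.lambda_matrix @ np.array([est.omega2, est.sigma2, est.tau2])
        np.testing.assert_allclose(lhs, est.rhs, rtol=1e-8)

    def test_h_coeffs_are_sigma2_row_of_inverse(self, ran_bundle):
        est = estimate_ran(ran_bundle)
        inv = np.linalg.inv(est.lambda_matrix)
        np.testing.assert_allclose(est.h_coeffs, inv[1], rtol=1e-8)

    def test_scale_equivariance(self, ran_bundle):
        est1 = estimate_ran(ran_bundle)
        ran_bundle.y_star = 3.0 * ran_bundle.y_star
        est9 = estimate_ran(ran_bundle)
        for a, b in [(est1.omega2, est9.omega2), (est1.sigma2, est9.sigma2), (est1.tau2, est9.tau2)]:
            assert b == pytest.approx(9.0 * a, rel=1e-10)

    def test_unbiased_under_known_components(self):
        """MoM estimates centred on the truth (Monte-Carlo, 3 SE band)."""
        truth = {"omega2": 0.3, "sigma2": 0.2, "tau2": 1.0}
        bundle = build_kernels(make_inputs(n=500, p=8, seed=9), mode="random_main")
        rng = np.random.default_rng(77)
        reps = 2000
        est = np.empty((reps, 3))
        for i in range(reps):
            g = rng.normal(0, np.sqrt(truth["omega2"]), bundle.p)
            s = rng.normal(0, np.sqrt(truth["sigma2"]), bundle.p)
            e = rng.normal(0, np.sqrt(truth["tau2"]), bundle.n)
            bundle.y_star = bundle.Gfac @ g + bundle.Sfac @ s + bundle.projector.apply(e)
            r = estimate_ran(bundle)
            est[i] = (r.omega2, r.sigma2, r.tau2)
        mean = est.mean(axis=0)
        se = est.std(axis=0, ddof=1) / np.sqrt(reps)
        for k, (name, val) in enumerate(truth.items()):
            assert abs(mean[k] - val) < 3 * se[k], f"{name}: {mean[k]} vs {val} (se {se[k]})"


class TestEstimateFix:
    def test_closed_form_equals_linear_solve(self):
        for seed in range(5):
            bundle = build_kernels(make_inputs(n=50, p=4, seed=seed), mode="fixed_main")
            est = estimate_fix(bundle)
            sol = np.linalg.solve(est.lambda_matrix, est.rhs)
            assert est.sigma2 == pytest.approx(sol[0], rel=1e-12)
            assert est.tau2 == pytest.approx(sol[1], rel=1e-12)

    def test_zero_response(self, fix_bundle):
        fix_bundle.y_star = np.zeros(fix_bundle.n)
        est = estimate_fix(fix_bundle)
        assert est.sigma2 == est.tau2 == 0.0

    def test_orthogonal_response_gives_negative_sigma2(self, fix_bundle):
        """y* orthogonal to the kernel column space: Eq. gives sigma2 < 0."""
        rng = np.random.default_rng(0)
        y = rng.normal(size=fix_bundle.n)
        y = fix_bundle.projector.apply(y)
        # remove the Sfac span component
        q, _ = np.linalg.qr(fix_bundle.Sfac)
        y = y - q @ (q.T @ y)
        fix_bundle.y_star = y
        est = estimate_fix(fix_bundle)
        t = kernel_traces(fix_bundle)
        d = fix_bundle.df_resid
        expected = -t.trS * (y @ y) / (d * t.trSS - t.trS**2)
        assert est.sigma2 == pytest.approx(expected, rel=1e-10)
        assert est.sigma2 < 0


class TestNullEstimates:
    def test_null_ran_unbiased(self):
        bundle = build_kernels(make_inputs(n=500, p=8, seed=13), mode="random_main")
        rng = np.random.default_rng(5)
        truth = {"omega2": 0.2, "tau2": 1.0}
        reps = 2000
        est = np.empty((reps, 2))
        for i in range(reps):
            g = rng.normal(0, np.sqrt(truth["omega2"]), bundle.p)
            e = rng.normal(0, np.sqrt(truth["tau2"]), bundle.n)
            bundle.y_star = bundle.Gfac @ g + bundle.projector.apply(e)
            r = estimate_null_ran(bundle)
            est[i] = (r.raw_omega2_0, r.raw_tau2_0)
        mean = est.mean(axis=0)
        se = est.std(axis=0, ddof=1) / np.sqrt(reps)
        assert abs(mean[0] - truth["omega2"]) < 3 * se[0]
        assert abs(mean[1] - truth["tau2"]) < 3 * se[1]

    def test_sigma2_mean_zero_under_null(self):
        """Full 3-component estimate of sigma2 averages ~0 when gamma=0."""
        bundle = build_kernels(make_inputs(n=500, p=8, seed=21), mode="random_main")
        rng = np.random.default_rng(6)
        reps = 2000
        vals = np.empty(reps)
        for i in range(reps):
            g = rng.normal(0, np.sqrt(0.2), bundle.p)
            e = rng.normal(0, 1.0, bundle.n)
            bundle.y_star = bundle.Gfac @ g + bundle.projector.apply(e)
            vals[i] = estimate_ran(bundle).sigma2
        se = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean()) < 3 * se

    def test_null_fix_matches_chi2_sampling(self):
        """iid N(0, 4) residuals: tau0 estimate within 3 SEs of 4."""
        bundle = build_kernels(make_inputs(n=1000, p=10, seed=3), mode="fixed_main")
        rng = np.random.default_rng(8)
        bundle.y_star = bundle.projector.apply(rng.normal(0, 2.0, bundle.n))
        est = estimate_null_fix(bundle)
        df = bundle.df_resid
        se = 4.0 * np.sqrt(2.0 / df)  # sd of a scaled chi2_df mean
        assert abs(est.tau2_0 - 4.0) < 3 * se

    def test_null_fix_equals_dense_quadratic_form(self, fix_bundle):
        M = fix_bundle.projector.dense()
        rng = np.random.default_rng(4)
        y = rng.normal(size=fix_bundle.n)
        fix_bundle.y_star = fix_bundle.projector.apply(y)
        est = estimate_null_fix(fix_bundle)
        assert est.tau2_0 == pytest.approx((y @ M @ y) / np.trace(M), rel=1e-8)

    def test_floor_flag_recorded(self, ran_bundle):
        # craft a response anti-correlated with the main kernel so the raw
        # omega0 solve goes negative
        rng = np.random.default_rng(10)
        found = False
        for _ in range(50):
            ran_bundle.y_star = ran_bundle.projector.apply(rng.normal(size=ran_bundle.n))
            r = estimate_null_ran(ran_bundle)
            if r.raw_omega2_0 < 0:
                assert r.floored and r.omega2_0 == 0.0
                assert "null_component_floored" in r.flags
                found = True
                break
        assert found, "no negative raw omega0 encountered in 50 draws"
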