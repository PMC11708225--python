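"""Liability-threshold pipeline for binary phenotypes.

A binary outcome y is modelled as the indicator that a latent Gaussian
liability z crosses zero. The full likelihood involves an n-dimensional
integral, so the test is run on the posterior mean of the liability
instead: the nuisance effects (intercept, covariates, environment) are
fitted by a probit regression, genetic terms are assumed small enough to
ignore in the posterior, and each subject's liability estimate is the mean
of a unit-variance normal truncated at zero —

    zhat_k = mu_k + phi(mu_k)/Phi(mu_k)      if y_k = 1
    zhat_k = mu_k - phi(mu_k)/Phi(-mu_k)     if y_k = 0

with mu the probit linear predictor. The continuous machinery (projection,
kernels, MQS estimation, mixture p-value) then runs on zhat unchanged.

For identifiability the latent-variance constraint (component sum = 1) is
applied as a pure rescaling of the statistic and its null spectrum; the
test is scale invariant, so the p-value is unaffected (this is asserted in
the test suite) and the constraint is presentational.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .data_model import TestInputs, WeightScheme
from .kernels import FIXED_MAIN, RANDOM_MAIN, build_kernels
from .mqs import estimate_fix, estimate_null_fix, estimate_null_ran, estimate_ran
from .pvalue import TestResult, pvalue

__all__ = ["LiabilityEstimate", "fit_probit", "posterior_liability", "run_binary_test"]


@dataclass
class LiabilityEstimate:
    zhat: np.ndarray
    probit_coefs: np.ndarray  # (intercept, covariates..., environment)
    linear_predictor: np.ndarray
    constraint_mode: str


def _probit_newton(y: np.ndarray, X: np.ndarray, maxiter: int = 100, tol: float = 1e-10):
    """Newton-Raphson probit MLE with step halving.

    The score and observed information use the standard probit quantities
    q = (2y-1), lam = q * phi(eta) / Phi(q*eta) (signed inverse Mills
    ratio), score = X' lam, info = X' diag(lam * (lam + eta)) X. Verified
    against the statsmodels reference fit in the test suite.
    """
    n, k = X.shape
    beta = np.zeros(k)
    beta[0] = float(special.ndtri(np.clip(y.mean(), 1e-10, 1 - 1e-10)))
    ll_old = -np.inf
    for _ in range(maxiter):
        eta = X @ beta
        q = 2.0 * y - 1.0
        log_cdf = special.log_ndtr(q * eta)
        ll = float(np.sum(log_cdf))
        lam = q * np.exp(-0.5 * eta**2 - 0.5 * np.log(2 * np.pi) - log_cdf)
        score = X.T @ lam
        w = lam * (lam + eta)
        info = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"probit information matrix singular ({err})") from err
        # step halving against likelihood decreases
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = float(np.sum(special.log_ndtr((2.0 * y - 1.0) * (X @ cand))))
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e3:
            raise ValueError(
                "probit fit diverged; check for separation in the covariates"
            )
        if abs(ll_new - ll_old) < tol * (1.0 + abs(ll_new)) and np.max(np.abs(score)) < 1e-6 * n:
            break
        ll_old = ll_new
    else:
        if np.max(np.abs(score)) > 1e-4 * n:
            raise ValueError("probit fit did not converge; check for separation")
    # (quasi-)complete separation: every subject ends up on the correct side
    # of the threshold by a wide margin, and the MLE is at infinity
    if np.min((2.0 * y - 1.0) * (X @ beta)) > 3.0:
        raise ValueError("probit fit indicates separation; check the covariates")
    return beta


def fit_probit(
    phenotype: np.ndarray, covariates: np.ndarray, environment: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood probit of y on [1, X, E]; returns (coefs, mu)."""
    y = np.asarray(phenotype, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("binary phenotype must be coded {0, 1}")
    if classes.size < 2:
        raise ValueError("phenotype has a single class; probit fit impossible")
    design = np.column_stack(
        [np.ones(len(y)), np.atleast_2d(covariates.T).T, np.asarray(environment)]
    )
    # drop linearly dependent columns (constant E, collinear covariates) so
    # the information matrix stays invertible; dropped coefficients are 0
    s = np.linalg.svd(design, compute_uv=False)
    rank = int(np.sum(s > 1e-10 * s[0]))
    if rank == design.shape[1]:
        keep = list(range(design.shape[1]))
    else:
        keep = [0]
        for j in range(1, design.shape[1]):
            sub = design[:, keep + [j]]
            if np.linalg.matrix_rank(sub, tol=1e-10 * s[0]) > len(keep):
                keep.append(j)
            if len(keep) == rank:
                break
    coefs = np.zeros(design.shape[1])
    coefs[keep] = _probit_newton(y, design[:, keep])
    mu = design @ coefs
    return coefs, mu


def posterior_liability(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Posterior mean of the zero-truncated unit-variance liability.

    Evaluated with log-scale Mills ratios (log-pdf minus log-cdf) so that
    extreme linear predictors (|mu| >> 5) stay finite: for a control with
    mu -> -inf, zhat -> mu.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    log_phi = -0.5 * mu**2 - 0.5 * np.log(2.0 * np.pi)
    mills_upper = np.exp(log_phi - special.log_ndtr(mu))  # phi/Phi(mu)
    mills_lower = np.exp(log_phi - special.log_ndtr(-mu))  # phi/Phi(-mu)
    return np.where(y == 1.0, mu + mills_upper, mu - mills_lower)


def run_binary_test(
    inputs: TestInputs,
    scheme: WeightScheme | None = None,
    mode: str = RANDOM_MAIN,
    constraint_mode: str = "normalize_to_one",
) -> TestResult:
    """MAGEIT on a binary trait via the posterior-mean liability.

    Builds zhat from a probit fit of the nuisance effects, then executes
    the continuous pipeline with zhat as the response. With
    ``constraint_mode="normalize_to_one"`` the statistic and spectrum are
    rescaled so the null components sum to one (identifiability
    convention); ``"none"`` skips the rescaling.
    """
    if inputs.trait_type != "binary":
        raise ValueError("run_binary_test requires binary trait inputs")
    if constraint_mode not in ("none", "normalize_to_one"):
        raise ValueError(f"unknown constraint_mode {constraint_mode!r}")
    coefs, mu = fit_probit(inputs.phenotype, inputs.covariates, inputs.environment)
    zhat = posterior_liability(inputs.phenotype, mu)

    bundle = build_kernels(inputs, scheme=scheme, mode=mode, response=zhat)
    if mode == RANDOM_MAIN:
        comps = estimate_ran(bundle)
        null = estimate_null_ran(bundle)
        total = null.omega2_0 + null.tau2_0
    elif mode == FIXED_MAIN:
        comps = estimate_fix(bundle)
        null = estimate_null_fix(bundle)
        total = null.tau2_0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    flags = ["liability_threshold"]
    scale = 1.0
    if constraint_mode == "normalize_to_one" and total > 0:
        scale = 1.0 / total
        flags.append("variance_constraint_normalized")
    return pvalue(bundle, comps, null, flags=flags, scale=scale)
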