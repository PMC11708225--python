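"""Method-of-moments (MQS) variance-component estimation and test statistics.

For the projected model ``y* ~ N(0, omega^2 G* + sigma^2 S* + tau^2 M)``
second-moment matching with probe matrices A1 = G*, A2 = S*, A3 = M gives a
linear "trace system"

    Lambda [omega^2, sigma^2, tau^2]' = [y*'G*y*, y*'S*y*, y*'y*]'

with Lambda built from pairwise kernel traces. The estimated interaction
component ``sigma^2_hat`` is the test statistic (MAGEIT_RAN). In fixed-main
mode the genotypes are projected out and the analogous 2x2 system yields
MAGEIT_FIX. Method-of-moments estimates can legitimately be negative; only
the null components used to build the null covariance are floored at zero
(the covariance must be PSD for its matrix square root).

All traces are computed from the low-rank factors:

    tr(G*)    = ||Gfac||_F^2          tr(G*G*) = ||Gfac'Gfac||_F^2
    tr(G*S*)  = ||Gfac'Sfac||_F^2     y*'G*y*  = ||Gfac'y*||^2

and tr(A M) = tr(A) for any A built from projected factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kernels import FIXED_MAIN, RANDOM_MAIN, KernelBundle

__all__ = [
    "ComponentEstimates",
    "NullComponents",
    "kernel_traces",
    "estimate_ran",
    "estimate_fix",
    "null_from_estimates",
    "estimate_null_ran",
    "estimate_null_fix",
]

COND_LIMIT = 1e12


@dataclass
class Traces:
    trG: float
    trGG: float
    trGS: float
    trS: float
    trSS: float
    df: int  # tr(M) = n - rank(b)


def kernel_traces(bundle: KernelBundle) -> Traces:
    K = bundle.gram()
    p = bundle.p
    if bundle.mode == FIXED_MAIN:
        GtG = np.zeros((0, 0))
        GtS = np.zeros((0, 0))
        StS = K
    else:
        GtG = K[:p, :p]
        GtS = K[:p, p:]
        StS = K[p:, p:]
    return Traces(
        trG=float(np.trace(GtG)) if GtG.size else 0.0,
        trGG=float(np.sum(GtG * GtG)),
        trGS=float(np.sum(GtS * GtS)),
        trS=float(np.trace(StS)),
        trSS=float(np.sum(StS * StS)),
        df=bundle.df_resid,
    )


@dataclass
class ComponentEstimates:
    """Variance-component estimates and the trace system that produced them.

    ``h_coeffs = (a, b, c)`` is the row of Lambda^-1 belonging to sigma^2,
    so the statistic is the quadratic form y*' H y* with
    ``H = a G* + b S* + c I``.
    """

    mode: str
    sigma2: float
    tau2: float
    omega2: Optional[float]
    lambda_matrix: np.ndarray
    rhs: np.ndarray
    h_coeffs: tuple[float, float, float]
    flags: list[str] = field(default_factory=list)


@dataclass
class NullComponents:
    """Null-model components used to build the null covariance Sigma_0.

    ``omega2_0``/``tau2_0`` are floored at zero (PSD requirement); the raw
    signed solutions are kept for diagnostics, with ``floored`` recording
    whether any flooring happened.
    """

    omega2_0: float
    tau2_0: float
    raw_omega2_0: float
    raw_tau2_0: float
    floored: bool = False
    flags: list[str] = field(default_factory=list)


def _solve_sym(lam: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(lam)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise np.linalg.LinAlgError(
            "trace system is numerically singular; kernels indistinguishable "
            "(cannot separate the interaction component) — is the environment "
            "nearly constant?"
        )
    return np.linalg.solve(lam, rhs)


def estimate_ran(bundle: KernelBundle) -> ComponentEstimates:
    """Three-component MQS solve; sigma2 is the MAGEIT_RAN statistic."""
    if bundle.mode != RANDOM_MAIN:
        raise ValueError("estimate_ran requires a random_main kernel bundle")
    t = kernel_traces(bundle)
    lam = np.array(
        [
            [t.trGG, t.trGS, t.trG],
            [t.trGS, t.trSS, t.trS],
            [t.trG, t.trS, float(t.df)],
        ]
    )
    y = bundle.y_star
    rhs = np.array(
        [
            float(np.sum((bundle.Gfac.T @ y) ** 2)),
            float(np.sum((bundle.Sfac.T @ y) ** 2)),
            float(y @ y),
        ]
    )
    est = _solve_sym(lam, rhs)
    h = _solve_sym(lam, np.array([0.0, 1.0, 0.0]))
    return ComponentEstimates(
        mode=RANDOM_MAIN,
        omega2=float(est[0]),
        sigma2=float(est[1]),
        tau2=float(est[2]),
        lambda_matrix=lam,
        rhs=rhs,
        h_coeffs=(float(h[0]), float(h[1]), float(h[2])),
    )


def estimate_fix(bundle: KernelBundle) -> ComponentEstimates:
    """Two-component MQS solve; sigma2 is the MAGEIT_FIX statistic.

    Closed form: with d = df_resid,
    sigma2 = (d * y*'S*y* - tr(S*) * y*'y*) / (d * tr(S*S*) - tr(S*)^2).
    """
    if bundle.mode != FIXED_MAIN:
        raise ValueError("estimate_fix requires a fixed_main kernel bundle")
    t = kernel_traces(bundle)
    d = float(t.df)
    denom = d * t.trSS - t.trS**2
    if denom <= 0:
        raise np.linalg.LinAlgError(
            "degenerate interaction kernel: (df * tr(S*S*) - tr(S*)^2) <= 0"
        )
    y = bundle.y_star
    ySy = float(np.sum((bundle.Sfac.T @ y) ** 2))
    yy = float(y @ y)
    sigma2 = (d * ySy - t.trS * yy) / denom
    tau2 = (t.trSS * yy - t.trS * ySy) / denom
    lam = np.array([[t.trSS, t.trS], [t.trS, d]])
    return ComponentEstimates(
        mode=FIXED_MAIN,
        omega2=None,
        sigma2=sigma2,
        tau2=tau2,
        lambda_matrix=lam,
        rhs=np.array([ySy, yy]),
        h_coeffs=(0.0, d / denom, -t.trS / denom),
    )


def null_from_estimates(comps: ComponentEstimates) -> NullComponents:
    """Null covariance components from the unrestricted MoM solve.

    Under H0 the unrestricted (omega2, tau2) estimates are unbiased for the
    null components; using them (floored at zero for PSD-ness) rather than
    a refitted null-restricted system keeps the null covariance decoupled
    from the fluctuation of the statistic itself and yields near-nominal
    type-I error, matching the reference calibration of the test. The
    restricted alternative is :func:`estimate_null_ran`.
    """
    if comps.mode != RANDOM_MAIN:
        raise ValueError("null_from_estimates applies to random_main estimates")
    raw = np.array([comps.omega2, comps.tau2])
    floored = bool(np.any(raw < 0))
    omega0, tau0 = np.maximum(raw, 0.0)
    flags = ["null_component_floored"] if floored else []
    return NullComponents(
        omega2_0=float(omega0),
        tau2_0=float(tau0),
        raw_omega2_0=float(raw[0]),
        raw_tau2_0=float(raw[1]),
        floored=floored,
        flags=flags,
    )


def estimate_null_ran(bundle: KernelBundle) -> NullComponents:
    """Two-component null restriction (sigma2 = 0) of the random-main system.

    Probe matrices A1 = G*, A2 = M give the 2x2 system
    [[tr(G*G*), tr(G*)], [tr(G*), df]] (omega0, tau0)' = (y*'G*y*, y*'y*)'.
    If the main-effect kernel is degenerate (all-zero G*), falls back to the
    single-component solve tau0 = y*'y* / df.
    """
    if bundle.mode != RANDOM_MAIN:
        raise ValueError("estimate_null_ran requires a random_main kernel bundle")
    t = kernel_traces(bundle)
    y = bundle.y_star
    yy = float(y @ y)
    flags: list[str] = []
    if t.trGG <= 0 or t.trG <= 0:
        flags.append("degenerate_main_kernel")
        raw = np.array([0.0, yy / t.df])
    else:
        lam = np.array([[t.trGG, t.trG], [t.trG, float(t.df)]])
        rhs = np.array([float(np.sum((bundle.Gfac.T @ y) ** 2)), yy])
        raw = _solve_sym(lam, rhs)
    floored = bool(np.any(raw < 0))
    if floored:
        flags.append("null_component_floored")
    omega0, tau0 = np.maximum(raw, 0.0)
    return NullComponents(
        omega2_0=float(omega0),
        tau2_0=float(tau0),
        raw_omega2_0=float(raw[0]),
        raw_tau2_0=float(raw[1]),
        floored=floored,
        flags=flags,
    )


def estimate_null_fix(bundle: KernelBundle) -> NullComponents:
    """Null residual variance for fixed-main mode: tau0 = y*'y* / df."""
    if bundle.mode != FIXED_MAIN:
        raise ValueError("estimate_null_fix requires a fixed_main kernel bundle")
    df = bundle.df_resid
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    tau0 = float(bundle.y_star @ bundle.y_star) / df
    return NullComponents(
        omega2_0=0.0,
        tau2_0=tau0,
        raw_omega2_0=0.0,
        raw_tau2_0=tau0,
        floored=False,
    )
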