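"""Null distribution of the interaction statistic and its tail probability.

Under H0 the projected response is N(0, Sigma_0) with
``Sigma_0 = omega0^2 G* + tau0^2 M`` (random-main) or ``tau0^2 M``
(fixed-main), and the statistic ``sigma2_hat = y*' H y*`` with
``H = a G* + b S* + c I`` is distributed as a mixture
``sum_i lambda_i chi2_1`` whose lambda_i are the eigenvalues of
``Sigma_0^{1/2} H Sigma_0^{1/2}``.

Because G*, S* and M all live inside the rank-(n-q) projection subspace,
the spectrum has exactly three blocks:

* 0 with multiplicity q (the nuisance span, where Sigma_0 vanishes);
* the "bulk" value ``c * tau0^2`` with multiplicity (n - q - r), where r is
  the rank of the combined factor matrix F = [Gfac, Sfac] — on the part of
  the projection subspace orthogonal to the kernels, H acts as c*I and
  Sigma_0 as tau0^2*I;
* r eigenvalues of an r x r reduced symmetric problem assembled entirely
  from the Gram matrix F'F (O(n p^2) work, no n x n matrices).

A dense O(n^3) path is provided as an independent oracle for tests.

Tail probabilities come from the characteristic-function inversion in
:mod:`mageit.davies`; when that reports a fault or an out-of-range value,
the moment-matching (Liu-Tang-Zhang) noncentral-chi-square surrogate is
used instead and the fallback is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .davies import davies_sf
from .kernels import FIXED_MAIN, KernelBundle
from .mqs import ComponentEstimates, NullComponents

__all__ = [
    "MixtureSpec",
    "TestResult",
    "mixture_eigenvalues",
    "davies_pvalue",
    "ltz_pvalue",
    "pvalue",
]

EIG_DROP_TOL = 1e-10  # |lambda| below this fraction of max|lambda| is a numerical zero
P_FLOOR = 1e-300
DAVIES_ACC = 1e-6
DAVIES_LIM = 1_000_000


@dataclass
class MixtureSpec:
    """Distinct eigenvalues (value, multiplicity) of the null mixture.

    Multiplicities sum to n (zeros included); ``bulk`` is the
    high-multiplicity value from the projected identity block.
    """

    eigenvalues: list[tuple[float, int]]
    bulk: float
    source_mode: str
    n: int

    def nonzero(self) -> tuple[np.ndarray, np.ndarray]:
        """(values, multiplicities) after dropping numerical zeros."""
        vals = np.array([v for v, _ in self.eigenvalues])
        mult = np.array([m for _, m in self.eigenvalues])
        if len(vals) == 0:
            return vals, mult
        keep = np.abs(vals) > EIG_DROP_TOL * np.max(np.abs(vals))
        return vals[keep], mult[keep]

    def total_multiplicity(self) -> int:
        return int(sum(m for _, m in self.eigenvalues))

    def trace(self) -> float:
        return float(sum(v * m for v, m in self.eigenvalues))


def _reduced_gram_blocks(bundle: KernelBundle, rank_tol: float = 1e-10):
    """Orthonormal-reduced kernel blocks from the Gram matrix of [Gfac, Sfac].

    Returns (A_G, A_S, r): r x r symmetric reduced forms of G* and S* in an
    orthonormal basis of col([Gfac, Sfac]), built without any n x r
    orthogonalisation — only F'F is formed.
    """
    p = bundle.p
    K = bundle.gram()
    evals, evecs = np.linalg.eigh(K)
    if evals.size == 0 or evals[-1] <= 0:
        return np.zeros((0, 0)), np.zeros((0, 0)), 0
    keep = evals > rank_tol * evals[-1]
    r = int(keep.sum())
    V = evecs[:, keep]
    dinv = 1.0 / np.sqrt(evals[keep])
    # Q = F V D^{-1/2};  Q'Gfac = D^{-1/2} V' (F'Gfac) = D^{-1/2} V' K[:, :p]
    if bundle.mode == FIXED_MAIN:
        C_S = (dinv[:, None] * V.T) @ K
        A_S = C_S @ C_S.T
        A_G = np.zeros((r, r))
    else:
        C_G = (dinv[:, None] * V.T) @ K[:, :p]
        C_S = (dinv[:, None] * V.T) @ K[:, p:]
        A_G = C_G @ C_G.T
        A_S = C_S @ C_S.T
    return A_G, A_S, r


def mixture_eigenvalues(
    bundle: KernelBundle,
    components: ComponentEstimates,
    null_components: NullComponents,
    dense: bool = False,
) -> MixtureSpec:
    """Spectrum of Sigma_0^{1/2} H Sigma_0^{1/2} as (value, multiplicity) pairs.

    ``dense=True`` materialises the n x n matrices and calls a symmetric
    eigensolver — the independent oracle path, usable for n <= ~2000.
    """
    a, b, c = components.h_coeffs
    w0 = null_components.omega2_0
    t0 = null_components.tau2_0
    n = bundle.n
    q = bundle.projector.rank
    d = bundle.df_resid

    if dense:
        M = bundle.projector.dense()
        Gs = bundle.Gfac @ bundle.Gfac.T
        Ss = bundle.Sfac @ bundle.Sfac.T
        H = a * Gs + b * Ss + c * np.eye(n)
        Sigma0 = w0 * Gs + t0 * M
        sev, svec = np.linalg.eigh(Sigma0)
        sev = np.clip(sev, 0.0, None)
        root = svec * np.sqrt(sev) @ svec.T
        lam = np.linalg.eigvalsh(root @ H @ root)
        pairs = [(float(v), 1) for v in lam]
        return MixtureSpec(pairs, bulk=c * t0, source_mode=bundle.mode, n=n)

    A_G, A_S, r = _reduced_gram_blocks(bundle)
    pairs: list[tuple[float, int]] = []
    if r > 0:
        H_r = a * A_G + b * A_S + c * np.eye(r)
        Sig_r = w0 * A_G + t0 * np.eye(r)
        sev, svec = np.linalg.eigh(Sig_r)
        sev = np.clip(sev, 0.0, None)
        root = svec * np.sqrt(sev) @ svec.T
        lam = np.linalg.eigvalsh(root @ H_r @ root)
        if not np.all(np.isfinite(lam)):
            raise FloatingPointError(
                f"non-finite mixture eigenvalue (mode={bundle.mode}, r={r}, "
                f"omega0={w0!r}, tau0={t0!r}, h={components.h_coeffs!r})"
            )
        pairs.extend((float(v), 1) for v in lam)
    bulk = c * t0
    if d - r > 0:
        pairs.append((bulk, d - r))
    if q > 0:
        pairs.append((0.0, q))
    return MixtureSpec(pairs, bulk=bulk, source_mode=bundle.mode, n=n)


def davies_pvalue(
    mixture: MixtureSpec,
    q: float,
    acc: float = DAVIES_ACC,
    lim: int = DAVIES_LIM,
) -> tuple[float, str]:
    """Upper-tail probability by characteristic-function inversion.

    Returns (p, status); status "ok" or "failed". Failure means the
    integration faulted (truncation limit, round-off, no convergence) or p
    escaped (0, 1) — including tails beyond the target accuracy, where the
    inversion can only certify p < acc. The caller is expected to fall
    back to the moment-matching approximation.
    """
    vals, mult = mixture.nonzero()
    if len(vals) == 0:
        raise ValueError("mixture has no nonzero eigenvalue")
    res = davies_sf(vals, mult, q, lim=lim, acc=acc)
    p = res.value
    if res.fault != 0 or math.isnan(p):
        return (p if not math.isnan(p) else 0.0), "failed"
    if p <= 0.0 or p > 1.0:
        return p, "failed"
    return p, "ok"


def _ltz_upper(lam: np.ndarray, mult: np.ndarray, q: float) -> float:
    c1 = float(np.sum(mult * lam))
    c2 = float(np.sum(mult * lam**2))
    c3 = float(np.sum(mult * lam**3))
    c4 = float(np.sum(mult * lam**4))
    if c2 <= 0:
        raise ValueError("mixture has zero variance")
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    tstar = (q - c1) / math.sqrt(2.0 * c2)
    if s1**2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        ell = a**2 - 2.0 * delta
    else:
        a = 1.0 / s1
        delta = 0.0
        ell = c2**3 / c3**2
    mu_x = ell + delta
    sigma_x = math.sqrt(2.0) * a
    x = tstar * sigma_x + mu_x
    if delta > 0:
        return float(stats.ncx2.sf(x, ell, delta))
    return float(stats.chi2.sf(x, ell))


def ltz_pvalue(mixture: MixtureSpec, q: float) -> float:
    """Moment-matching (skewness/kurtosis) noncentral-chi-square surrogate tail.

    The four cumulants of the mixture are matched to a (non)central
    chi-square; for left-skewed (negative third cumulant) mixtures the
    reflected form is matched instead so the surrogate always has the
    canonical right skew.
    """
    lam, mult = mixture.nonzero()
    if len(lam) == 0:
        raise ValueError("mixture has no nonzero eigenvalue")
    c3 = float(np.sum(mult * lam**3))
    if c3 < 0:
        return 1.0 - _ltz_upper(-lam, mult, -q)
    return _ltz_upper(lam, mult, q)


@dataclass
class TestResult:
    """Outcome of one marginal gene-environment interaction test."""

    statistic: float
    pvalue: float
    method: str  # "davies" | "liu_tang_zhang"
    mixture: MixtureSpec
    components: ComponentEstimates
    null_components: NullComponents
    flags: list[str] = field(default_factory=list)

    @property
    def mode(self) -> str:
        return self.components.mode


def pvalue(
    bundle: KernelBundle,
    components: ComponentEstimates,
    null_components: NullComponents,
    flags: Optional[list[str]] = None,
    scale: float = 1.0,
) -> TestResult:
    """Compute the mixture spectrum and the tail probability with fallback.

    ``scale`` multiplies the statistic, the component estimates and the
    spectrum jointly (used by the binary pipeline's variance-normalisation
    constraint); the p-value is invariant to it.
    """
    flags = list(flags or [])
    flags.extend(null_components.flags)
    if bundle.projector.rank < bundle.projector.ncols:
        flags.append("rank_deficient_nuisance")
    mixture = mixture_eigenvalues(bundle, components, null_components)
    stat = components.sigma2
    if scale != 1.0:
        mixture = MixtureSpec(
            [(v * scale, m) for v, m in mixture.eigenvalues],
            bulk=mixture.bulk * scale,
            source_mode=mixture.source_mode,
            n=mixture.n,
        )
        stat = stat * scale
    p, status = davies_pvalue(mixture, stat)
    method = "davies"
    if status != "ok":
        p = ltz_pvalue(mixture, stat)
        method = "liu_tang_zhang"
        flags.append("davies_fallback")
    p = min(max(p, P_FLOOR), 1.0)
    return TestResult(
        statistic=stat,
        pvalue=p,
        method=method,
        mixture=mixture,
        components=components,
        null_components=null_components,
        flags=flags,
    )
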