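"""Nuisance projection and weighted main-effect / interaction kernels.

The fixed nuisance effects (intercept, covariates, environment, and in
fixed-main mode the genotypes themselves) are removed by the orthogonal
projector ``M = I - b (b'b)^-1 b'`` onto the complement of ``col(b)``.
After projection the model for the response is zero-mean Gaussian with
covariance ``omega^2 G* + sigma^2 S* + tau^2 M`` (random-main mode) or
``sigma^2 S* + tau^2 M`` (fixed-main mode), where

    G* = (M G W1)(M G W1)' / p      S* = (M S W2)(M S W2)' / p

with ``S = E . G`` columnwise and W1, W2 the diagonal beta-density weight
matrices. The n x n kernels are never materialised: everything downstream
works from the low-rank factors ``Gfac = M G W1 / sqrt(p)`` and
``Sfac = M S W2 / sqrt(p)`` (traces, quadratic forms, spectra), which keeps
a genome scan at O(n p^2) per gene. A dense path exists purely as a test
oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_model import TestInputs, WeightScheme, variant_weights

__all__ = ["Projector", "KernelBundle", "build_projection", "build_kernels"]

RANDOM_MAIN = "random_main"
FIXED_MAIN = "fixed_main"


@dataclass
class Projector:
    """Orthogonal projector onto the complement of a nuisance design.

    Represented by an orthonormal basis Q of col(b) (n x rank); applying the
    projector is ``v - Q (Q'v)``. The basis is obtained by SVD with singular
    values below ``1e-10 * s_max`` treated as zero, so exactly or nearly
    collinear nuisance columns reduce the rank (and the residual degrees of
    freedom) instead of poisoning the projection.
    """

    basis: np.ndarray  # n x rank, orthonormal
    rank: int
    n: int
    ncols: int  # columns supplied in b (before rank reduction)

    @property
    def df_resid(self) -> int:
        return self.n - self.rank

    def apply(self, v: np.ndarray) -> np.ndarray:
        """Project vectors/matrices (rows = subjects) off the nuisance span."""
        return v - self.basis @ (self.basis.T @ v)

    def dense(self) -> np.ndarray:
        """Materialise M = I - QQ' (test oracle; O(n^2) memory)."""
        return np.eye(self.n) - self.basis @ self.basis.T


def build_projection(
    covariates: np.ndarray,
    environment: np.ndarray,
    genotypes: Optional[np.ndarray] = None,
    rank_tol: float = 1e-10,
) -> Projector:
    """Build the projector for b = [1, X, E] (or [1, X, E, G] in fixed mode).

    Columns are scaled to unit norm before the SVD so the rank decision is
    insensitive to the units of individual covariates.
    """
    n = len(environment)
    cols = [np.ones((n, 1)), np.atleast_2d(covariates.T).T, np.asarray(environment)[:, None]]
    if genotypes is not None:
        cols.append(genotypes)
    b = np.column_stack(cols)
    q = b.shape[1]
    if q >= n:
        raise ValueError(
            f"nuisance design has {q} columns for {n} subjects; no residual degrees of freedom"
        )
    norms = np.linalg.norm(b, axis=0)
    norms[norms == 0] = 1.0
    u, s, _ = np.linalg.svd(b / norms, full_matrices=False)
    rank = int(np.sum(s > rank_tol * s[0]))
    if rank < q:
        warnings.warn(
            f"nuisance design is rank deficient: rank {rank} < {q} columns; "
            "residual degrees of freedom follow the rank",
            stacklevel=2,
        )
    if rank >= n:
        raise ValueError("nuisance design spans the whole sample space")
    return Projector(basis=u[:, :rank], rank=rank, n=n, ncols=q)


@dataclass
class KernelBundle:
    """Projected response and low-rank kernel factors for one gene region.

    ``G* = Gfac Gfac'`` and ``S* = Sfac Sfac'`` are PSD with rank <= p. In
    fixed-main mode the genotypes sit inside the nuisance basis, so
    ``Gfac`` is numerically zero and only S* enters the moment equations.
    ``m`` is the number of covariate columns supplied (used for the nominal
    degrees-of-freedom bookkeeping n - (m+2) / n - (m+p+2); the operative
    count ``df_resid`` is rank-based).
    """

    mode: str
    projector: Projector
    y_star: np.ndarray
    Gfac: np.ndarray  # n x p
    Sfac: np.ndarray  # n x p
    m: int
    p: int
    weights: np.ndarray

    @property
    def n(self) -> int:
        return self.projector.n

    @property
    def df_resid(self) -> int:
        return self.projector.df_resid

    def gram(self) -> np.ndarray:
        """Cached Gram matrix F'F of the combined factors.

        F = [Gfac, Sfac] (random-main) or Sfac alone (fixed-main, where the
        projected genotype factor vanishes). Both the moment-equation
        traces and the mixture spectrum are assembled from this one O(n p^2)
        product, the dominant cost per gene.
        """
        cached = getattr(self, "_gram", None)
        if cached is None:
            if self.mode == FIXED_MAIN:
                F = self.Sfac
            else:
                F = np.concatenate([self.Gfac, self.Sfac], axis=1)
            cached = F.T @ F
            object.__setattr__(self, "_gram", cached)
        return cached


def build_kernels(
    inputs: TestInputs,
    scheme: Optional[WeightScheme] = None,
    mode: str = RANDOM_MAIN,
    response: Optional[np.ndarray] = None,
) -> KernelBundle:
    """Assemble the projected response and weighted kernel factors.

    ``response`` overrides ``inputs.phenotype`` (used by the binary pipeline,
    which substitutes the posterior-mean liability).
    """
    if mode not in (RANDOM_MAIN, FIXED_MAIN):
        raise ValueError(f"unknown mode {mode!r}")
    if scheme is None:
        scheme = WeightScheme(rare_threshold=inputs.markers.rare_threshold)
    G = inputs.markers.dosages
    E = inputs.environment
    y = inputs.phenotype if response is None else np.asarray(response, dtype=float)
    p = G.shape[1]
    if p < 1:
        raise ValueError("marker set is empty")
    if np.unique(E).size < 2:
        raise ValueError("environment is constant; interaction kernel is degenerate")

    proj = build_projection(
        inputs.covariates, E, genotypes=G if mode == FIXED_MAIN else None
    )
    w = variant_weights(inputs.markers.maf, scheme)
    scale = np.sqrt(p)
    Gw = G * w / scale
    Sw = (E[:, None] * G) * w / scale
    Gfac = proj.apply(Gw)
    Sfac = proj.apply(Sw)
    y_star = proj.apply(y)
    return KernelBundle(
        mode=mode,
        projector=proj,
        y_star=y_star,
        Gfac=Gfac,
        Sfac=Sfac,
        m=inputs.m,
        p=p,
        weights=w,
    )
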