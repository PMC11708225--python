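"""Core data containers: marker sets, test inputs, and MAF-based variant weights.

A gene-region test operates on four aligned pieces of data: a phenotype
vector ``y`` (continuous, or binary coded 0/1), a scalar environmental
exposure ``E`` per subject, a covariate matrix ``X`` (n x m), and a dosage
matrix ``G`` (n x p) for the p variants in the region. The interaction
design ``S`` has rows ``S_k = E_k * G_k`` and is derived, never stored.

Variants are split into rare and common by minor-allele frequency (MAF),
with rare = (0.005, 0.05) by default. Both the main-effect and the
interaction coefficients are weighted by a beta-density function of MAF:
``Beta(maf; 1, 25)`` for rare variants and ``c * Beta(maf; 0.5, 0.5)`` for
common ones, where ``c`` makes the weight function continuous at the
rare/common cutoff. Rare variants therefore receive much larger weights,
reflecting the expectation that rarer alleles carry larger per-allele
effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "Region",
    "MarkerSet",
    "TestInputs",
    "WeightScheme",
    "compute_maf",
    "variant_weights",
    "assemble_inputs",
]

DEFAULT_RARE_THRESHOLD = 0.05
DEFAULT_MAF_FLOOR = 0.005


@dataclass(frozen=True)
class Region:
    """A genomic interval (0-based half-open, BED convention)."""

    chrom: str
    start: int
    end: int
    name: str = ""


def compute_maf(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant minor-allele frequency from a dosage matrix.

    Parameters
    ----------
    dosages : (n, p) array
        Allele dosages in [0, 2]; NaN allowed (ignored in the mean).

    Returns
    -------
    maf : (p,) array
        ``min(f, 1 - f)`` with ``f = mean(dosage) / 2``.
    flip : (p,) bool array
        True where the coded allele is the major allele (f > 0.5), i.e.
        where dosages must be reflected (``2 - dosage``) so that the coded
        allele is the minor one.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim != 2:
        raise ValueError("dosages must be a 2-d (subjects x variants) array")
    finite = dosages[np.isfinite(dosages)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise ValueError("dosage entries must lie in [0, 2]")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        f = np.nanmean(dosages, axis=0) / 2.0
    f = np.where(np.isfinite(f), f, 0.0)
    flip = f > 0.5
    maf = np.where(flip, 1.0 - f, f)
    return maf, flip


@dataclass
class MarkerSet:
    """Genotype dosages for one gene region with per-variant MAF annotation.

    Dosages are stored minor-allele oriented: ``mean(dosage)/2 <= 0.5`` for
    every column. Monomorphic variants (MAF == 0) are flagged in
    ``is_monomorphic`` and should be removed (``drop_monomorphic``) before
    testing.
    """

    dosages: np.ndarray
    variant_ids: np.ndarray
    maf: np.ndarray
    is_rare: np.ndarray
    region: Optional[Region] = None
    maf_floor: float = DEFAULT_MAF_FLOOR
    rare_threshold: float = DEFAULT_RARE_THRESHOLD

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    @property
    def is_monomorphic(self) -> np.ndarray:
        return self.maf == 0.0

    @property
    def n_common(self) -> int:
        return int(np.sum((~self.is_rare) & (self.maf > 0)))

    @property
    def n_rare(self) -> int:
        return int(np.sum(self.is_rare))

    @classmethod
    def from_dosages(
        cls,
        dosages: np.ndarray,
        variant_ids: Optional[Sequence] = None,
        region: Optional[Region] = None,
        maf_floor: float = DEFAULT_MAF_FLOOR,
        rare_threshold: float = DEFAULT_RARE_THRESHOLD,
    ) -> "MarkerSet":
        """Build a MarkerSet, flipping columns to minor-allele orientation."""
        dosages = np.array(dosages, dtype=float)
        maf, flip = compute_maf(dosages)
        if flip.any():
            dosages[:, flip] = 2.0 - dosages[:, flip]
        if variant_ids is None:
            variant_ids = np.array([f"v{j}" for j in range(dosages.shape[1])])
        else:
            variant_ids = np.asarray(variant_ids)
        if len(variant_ids) != dosages.shape[1]:
            raise ValueError("variant_ids length does not match dosage columns")
        is_rare = (maf > maf_floor) & (maf < rare_threshold)
        if (maf == 0).any():
            warnings.warn(
                f"{int((maf == 0).sum())} monomorphic variant(s); "
                "they will be excluded from testing",
                stacklevel=2,
            )
        return cls(
            dosages=dosages,
            variant_ids=variant_ids,
            maf=maf,
            is_rare=is_rare,
            region=region,
            maf_floor=maf_floor,
            rare_threshold=rare_threshold,
        )

    def drop_monomorphic(self) -> "MarkerSet":
        keep = ~self.is_monomorphic
        return self.subset(keep)

    def subset(self, mask: np.ndarray) -> "MarkerSet":
        """Restrict to the variants selected by a boolean mask or index array."""
        return MarkerSet(
            dosages=self.dosages[:, mask],
            variant_ids=self.variant_ids[mask],
            maf=self.maf[mask],
            is_rare=self.is_rare[mask],
            region=self.region,
            maf_floor=self.maf_floor,
            rare_threshold=self.rare_threshold,
        )

    def subset_subjects(self, mask: np.ndarray) -> "MarkerSet":
        return MarkerSet(
            dosages=self.dosages[mask, :],
            variant_ids=self.variant_ids,
            maf=self.maf.copy(),
            is_rare=self.is_rare.copy(),
            region=self.region,
            maf_floor=self.maf_floor,
            rare_threshold=self.rare_threshold,
        )


@dataclass(frozen=True)
class WeightScheme:
    """Beta-density MAF weighting for main-effect (W1) and interaction (W2) terms.

    ``weight(maf) = BetaPDF(maf; a1, b1)`` below the rare/common cutoff and
    ``c * BetaPDF(maf; a2, b2)`` at or above it, with
    ``c = BetaPDF(t; a1, b1) / BetaPDF(t; a2, b2)`` at the cutoff ``t`` so
    the function is continuous there. Defaults (1, 25) / (0.5, 0.5) follow
    the standard rare-variant weighting convention.
    """

    rare_params: tuple[float, float] = (1.0, 25.0)
    common_params: tuple[float, float] = (0.5, 0.5)
    rare_threshold: float = DEFAULT_RARE_THRESHOLD

    @property
    def continuity_scale(self) -> float:
        t = np.asarray([self.rare_threshold])
        num = _beta_pdf(t, *self.rare_params)
        den = _beta_pdf(t, *self.common_params)
        return float(num[0] / den[0])


def _beta_pdf(x: np.ndarray, a: float, b: float) -> np.ndarray:
    # log-scale beta density (scipy.special); cheaper than the frozen
    # distribution machinery in per-replicate loops
    return np.exp((a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - special.betaln(a, b))


def variant_weights(maf: np.ndarray, scheme: Optional[WeightScheme] = None) -> np.ndarray:
    """Evaluate the rare/common beta-density weight at each MAF.

    Raises for MAF outside (0, 0.5]: monomorphic variants must be removed
    before weighting.
    """
    if scheme is None:
        scheme = WeightScheme()
    maf = np.asarray(maf, dtype=float)
    if np.any(maf <= 0.0) or np.any(maf > 0.5):
        raise ValueError("MAF must lie in (0, 0.5]; remove monomorphic variants first")
    rare = maf < scheme.rare_threshold
    w = np.empty_like(maf)
    w[rare] = _beta_pdf(maf[rare], *scheme.rare_params)
    w[~rare] = scheme.continuity_scale * _beta_pdf(maf[~rare], *scheme.common_params)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("non-positive or non-finite weight encountered")
    return w


@dataclass
class TestInputs:
    """Aligned (y, E, X, G) inputs for one gene-region interaction test."""

    phenotype: np.ndarray
    environment: np.ndarray
    covariates: np.ndarray
    markers: MarkerSet
    trait_type: str  # "continuous" | "binary"
    subject_ids: Optional[np.ndarray] = None
    n_dropped_subjects: int = 0
    n_dropped_variants: int = 0

    @property
    def n(self) -> int:
        return self.phenotype.shape[0]

    @property
    def m(self) -> int:
        return self.covariates.shape[1]

    @property
    def p(self) -> int:
        return self.markers.p


def _to_frame(obj, name, index) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj
    if isinstance(obj, pd.Series):
        return obj.to_frame(name)
    arr = np.asarray(obj, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
        cols = [name]
    else:
        cols = [f"{name}{i}" for i in range(arr.shape[1])]
    if index is None:
        index = pd.RangeIndex(arr.shape[0])
    return pd.DataFrame(arr, index=index, columns=cols)


def assemble_inputs(
    phenotype,
    environment,
    covariates,
    markers: MarkerSet,
    trait_type: str = "continuous",
) -> TestInputs:
    """Align, complete-case filter, and validate the four test inputs.

    Pandas inputs are aligned on their index (subject IDs); plain arrays are
    taken as positionally aligned. Subjects with any missing value in the
    phenotype, environment, covariates, or dosages are dropped, and
    monomorphic variants (after subject filtering) are removed. MAF and the
    rare/common split are recomputed on the retained subjects.
    """
    if trait_type not in ("continuous", "binary"):
        raise ValueError("trait_type must be 'continuous' or 'binary'")

    index = None
    for obj in (phenotype, environment, covariates):
        if isinstance(obj, (pd.Series, pd.DataFrame)):
            index = obj.index
            break
    y = _to_frame(phenotype, "y", index)
    e = _to_frame(environment, "E", index)
    x = _to_frame(covariates, "X", index)
    if not (len(y) == len(e) == len(x) == markers.n):
        raise ValueError("phenotype, environment, covariates, markers differ in length")
    if index is not None:
        common = y.index.intersection(e.index).intersection(x.index)
        y, e, x = y.loc[common], e.loc[common], x.loc[common]

    dose = markers.dosages
    keep = (
        np.isfinite(y.to_numpy(float)).all(axis=1)
        & np.isfinite(e.to_numpy(float)).all(axis=1)
        & np.isfinite(x.to_numpy(float)).all(axis=1)
        & np.isfinite(dose).all(axis=1)
    )
    n_dropped = int((~keep).sum())
    y_arr = y.to_numpy(float)[keep, 0]
    e_arr = e.to_numpy(float)[keep, 0]
    x_arr = x.to_numpy(float)[keep, :]
    mk = markers.subset_subjects(keep)

    # re-derive MAF on retained subjects, drop monomorphic columns
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mk = MarkerSet.from_dosages(
            mk.dosages,
            variant_ids=mk.variant_ids,
            region=mk.region,
            maf_floor=mk.maf_floor,
            rare_threshold=mk.rare_threshold,
        )
    n_var_before = mk.p
    mk = mk.drop_monomorphic()
    n_dropped_var = n_var_before - mk.p
    if mk.p == 0:
        raise ValueError("no polymorphic variants remain after filtering")

    if np.unique(e_arr).size < 2:
        raise ValueError("environment is constant; interaction kernel is degenerate")
    if trait_type == "binary":
        vals = np.unique(y_arr)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("binary phenotype must be coded {0, 1}")

    ids = None
    if index is not None:
        ids = np.asarray(y.index)[keep]
    return TestInputs(
        phenotype=y_arr,
        environment=e_arr,
        covariates=x_arr,
        markers=mk,
        trait_type=trait_type,
        subject_ids=ids,
        n_dropped_subjects=n_dropped,
        n_dropped_variants=n_dropped_var,
    )
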