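"""Synthetic genotype/phenotype generators and simulation-study drivers.

Genotypes are frequency-spectrum-matched synthetic gene regions: each
variant gets a target MAF drawn uniformly from the common (0.05, 0.5) or
rare (0.005, 0.05) band, with the common/rare split fixed by a gene
profile, and dosages are Binomial(2, MAF) per variant (independent across
variants by default; an optional Gaussian-copula AR(1) mode adds linkage
disequilibrium). Two profiles mirror the chromosome-22 genes used as
templates in the study design: a 200-variant gene with 19% common variants
and a 296-variant gene with 36% common.

Continuous traits follow

    y = 0.05*X1 + 0.057*X2 + 0.64*E + sum_j w1j beta_j G_j
        + sum_l w2l gamma_l E G_l + eps,   eps ~ N(0, 1.5^2)

with X1 ~ N(62.4, 11.5^2) (age-like), X2 ~ Bernoulli(0.52) (sex-like),
E ~ Bernoulli(0.5), ten main-effect and ten interaction variants sampled
per replicate (the two sets may overlap), |beta| = 0.05 (common) / 0.09
(rare), and |gamma| = 0.19 / {0.49, 0.59} for continuous traits or
0.3 / {0.68, 0.78} for binary. The weights w are the beta-density weights
evaluated at the generating (true) MAF. Binary traits replace the linear
model with a logistic one (intercept -6.2, population prevalence ~ 0.08)
and quota-sample equal numbers of cases and controls.

The drivers ``type1_study`` and ``power_study`` run the full analysis
pipeline per replicate and summarise rejection rates with binomial
confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import run_gxe_test
from .data_model import MarkerSet, TestInputs, WeightScheme, variant_weights

__all__ = [
    "GeneProfile",
    "A4GALT_LIKE",
    "TIMP3_LIKE",
    "NULL_SET",
    "ScenarioConfig",
    "ReplicateDataset",
    "simulate_genotypes",
    "simulate_continuous",
    "simulate_binary",
    "type1_study",
    "power_study",
    "scenario_grid",
    "StudyResult",
]

SIGN_PATTERNS = ((1.0, 1.0), (0.5, 1.0), (1.0, 0.5), (0.5, 0.5))
GAMMA_RARE = {"continuous": (0.49, 0.59), "binary": (0.68, 0.78)}
GAMMA_COMMON = {"continuous": 0.19, "binary": 0.3}
BETA_COMMON = 0.05
BETA_RARE = 0.09
LOGIT_INTERCEPT = -6.2
NOISE_SD = 1.5


@dataclass(frozen=True)
class GeneProfile:
    """Synthetic gene region: variant count and common-variant fraction."""

    p_total: int
    fraction_common: float
    name: str = ""

    @property
    def n_common(self) -> int:
        return int(round(self.p_total * self.fraction_common))

    @property
    def n_rare(self) -> int:
        return self.p_total - self.n_common


A4GALT_LIKE = GeneProfile(200, 0.19, "A4GALT-like")  # 38 common + 162 rare
TIMP3_LIKE = GeneProfile(296, 0.36, "TIMP3-like")  # 107 common + 189 rare
NULL_SET = GeneProfile(10, 0.2, "null-set")  # 2 common + 8 rare


def simulate_genotypes(
    profile: GeneProfile,
    n: int,
    rng: np.random.Generator,
    ld_rho: Optional[float] = None,
    maf_bounds_common: tuple[float, float] = (0.05, 0.5),
    maf_bounds_rare: tuple[float, float] = (0.005, 0.05),
) -> tuple[MarkerSet, np.ndarray]:
    """Draw a synthetic gene region; returns (markers, generating MAFs).

    The MarkerSet's ``maf`` field holds the sample MAF (what an analyst
    sees); the second return value holds the generating frequencies used by
    the trait models.
    """
    n_common, n_rare = profile.n_common, profile.n_rare
    maf = np.concatenate(
        [
            rng.uniform(*maf_bounds_common, size=n_common),
            rng.uniform(*maf_bounds_rare, size=n_rare),
        ]
    )
    p = len(maf)
    if ld_rho is None:
        # Binomial(2, f) as two Bernoulli allele draws (faster than binomial)
        dosages = (rng.random((n, p)) < maf).astype(float) + (rng.random((n, p)) < maf)
    else:
        # Gaussian copula with AR(1) latent correlation, thresholded so each
        # variant's genotype distribution matches Hardy-Weinberg at its MAF.
        z = rng.standard_normal((n, p))
        for j in range(1, p):
            z[:, j] = ld_rho * z[:, j - 1] + np.sqrt(1 - ld_rho**2) * z[:, j]
        u = stats.norm.cdf(z)
        p0 = (1 - maf) ** 2
        p01 = p0 + 2 * maf * (1 - maf)
        dosages = (u > p0).astype(float) + (u > p01)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        markers = MarkerSet.from_dosages(dosages)
    return markers, maf


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation design.

    ``sign_pattern`` gives the proportions of positive beta and positive
    gamma; ``causal_selection`` is ``two_common_eight_rare`` (2 common + 8
    rare causal variants per set) or ``any_mix`` (10 variants regardless of
    class). The main-effect and interaction causal sets are sampled
    independently and may overlap. ``n`` is the simulated sample size
    (cases + controls for binary traits, quota-sampled in equal halves).
    """

    trait_type: str = "continuous"
    profile: GeneProfile = A4GALT_LIKE
    causal_selection: str = "two_common_eight_rare"
    sign_pattern: tuple[float, float] = (1.0, 1.0)
    gamma_rare: float = 0.49
    n: int = 5000
    n_causal: int = 10
    beta_common: float = BETA_COMMON
    beta_rare: float = BETA_RARE
    gamma_common: Optional[float] = None
    noise_sd: float = NOISE_SD
    null: bool = False  # force gamma = 0 (type-I error studies)
    ld_rho: Optional[float] = None
    # How beta-density weights enter the generating coefficients:
    # "mean_one" rescales the weights to mean 1 over each causal set, so the
    # weighted coefficients keep the nominal magnitudes on average while
    # up-weighting rarer causal variants; "raw" uses the densities as-is;
    # "none" drops generator-side weighting. mean_one keeps the genetic
    # share of phenotypic variance in the few-percent range the design
    # targets (raw densities, ~25 for the rarest variants, would let the
    # genetic terms dominate the trait).
    trait_weight_norm: str = "mean_one"

    def resolved_gamma_common(self) -> float:
        if self.gamma_common is not None:
            return self.gamma_common
        return GAMMA_COMMON[self.trait_type]


@dataclass
class ReplicateDataset:
    """One simulated dataset plus the generating truth."""

    inputs: TestInputs
    truth: dict = field(default_factory=dict)


def _select_causal(
    config: ScenarioConfig, true_maf: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    rare = true_maf < 0.05
    if config.causal_selection == "two_common_eight_rare":
        common_idx = np.flatnonzero(~rare)
        rare_idx = np.flatnonzero(rare)
        if len(common_idx) < 2 or len(rare_idx) < 8:
            raise ValueError("profile lacks 2 common + 8 rare variants")
        return np.concatenate(
            [rng.choice(common_idx, 2, replace=False), rng.choice(rare_idx, 8, replace=False)]
        )
    if config.causal_selection == "any_mix":
        return rng.choice(len(true_maf), config.n_causal, replace=False)
    raise ValueError(f"unknown causal_selection {config.causal_selection!r}")


def _signed_coeffs(
    idx: np.ndarray,
    true_maf: np.ndarray,
    mag_common: float,
    mag_rare: float,
    frac_positive: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Magnitudes by rarity, with floor(count/2) of each class negated when
    the positive fraction is 0.5 (per-class sign balance)."""
    rare = true_maf[idx] < 0.05
    coef = np.where(rare, mag_rare, mag_common)
    if frac_positive < 1.0:
        for cls in (rare, ~rare):
            members = np.flatnonzero(cls)
            n_neg = int(round(len(members) * (1.0 - frac_positive)))
            if n_neg:
                neg = rng.choice(members, n_neg, replace=False)
                coef[neg] = -coef[neg]
    return coef


def _genetic_terms(
    config: ScenarioConfig,
    G: np.ndarray,
    true_maf: np.ndarray,
    rng: np.random.Generator,
    scheme: WeightScheme,
):
    """Sample causal sets and return (main_term, interaction_term, truth)."""
    w_true = variant_weights(np.clip(true_maf, 1e-12, 0.5), scheme)
    main_idx = _select_causal(config, true_maf, rng)
    inter_idx = _select_causal(config, true_maf, rng)

    def _norm(w):
        if config.trait_weight_norm == "mean_one":
            return w / w.mean()
        if config.trait_weight_norm == "raw":
            return w
        if config.trait_weight_norm == "none":
            return np.ones_like(w)
        raise ValueError(f"unknown trait_weight_norm {config.trait_weight_norm!r}")

    w_main = _norm(w_true[main_idx])
    w_inter = _norm(w_true[inter_idx])
    beta = _signed_coeffs(
        main_idx, true_maf, config.beta_common, config.beta_rare, config.sign_pattern[0], rng
    )
    if config.null:
        gamma = np.zeros(len(inter_idx))
    else:
        gamma = _signed_coeffs(
            inter_idx,
            true_maf,
            config.resolved_gamma_common(),
            config.gamma_rare,
            config.sign_pattern[1],
            rng,
        )
    main_term = G[:, main_idx] @ (w_main * beta)
    inter_term = G[:, inter_idx] @ (w_inter * gamma)
    truth = {
        "main_idx": main_idx,
        "inter_idx": inter_idx,
        "beta": beta,
        "gamma": gamma,
        "w_main": w_main,
        "w_inter": w_inter,
        "true_maf": true_maf,
    }
    return main_term, inter_term, truth


def _covariates(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    x1 = rng.normal(62.4, 11.5, size=n)
    x2 = rng.binomial(1, 0.52, size=n).astype(float)
    return x1, x2


def _quick_inputs(y, env, X, markers: MarkerSet, trait_type: str) -> TestInputs:
    """Fast TestInputs assembly for generated (clean) data: recompute MAF,
    drop monomorphic columns, skip the pandas alignment path."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mk = MarkerSet.from_dosages(markers.dosages)
    n_before = mk.p
    mk = mk.drop_monomorphic()
    if mk.p == 0:
        raise ValueError("no polymorphic variants in simulated region")
    return TestInputs(
        phenotype=np.asarray(y, dtype=float),
        environment=np.asarray(env, dtype=float),
        covariates=X,
        markers=mk,
        trait_type=trait_type,
        n_dropped_variants=n_before - mk.p,
    )


def simulate_continuous(
    config: ScenarioConfig,
    rng: np.random.Generator,
    markers: Optional[MarkerSet] = None,
    true_maf: Optional[np.ndarray] = None,
    scheme: Optional[WeightScheme] = None,
) -> ReplicateDataset:
    """One continuous-trait replicate; genotypes drawn unless supplied."""
    scheme = scheme or WeightScheme()
    n = config.n
    if markers is None:
        markers, true_maf = simulate_genotypes(config.profile, n, rng, ld_rho=config.ld_rho)
    assert true_maf is not None
    x1, x2 = _covariates(n, rng)
    env = rng.binomial(1, 0.5, size=n).astype(float)
    main_term, inter_term, truth = _genetic_terms(
        config, markers.dosages, true_maf, rng, scheme
    )
    eps = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
    y = 0.05 * x1 + 0.057 * x2 + 0.64 * env + main_term + env * inter_term + eps
    X = np.column_stack([x1, x2])
    return ReplicateDataset(_quick_inputs(y, env, X, markers, "continuous"), truth)


def simulate_binary(
    config: ScenarioConfig,
    rng: np.random.Generator,
    scheme: Optional[WeightScheme] = None,
    block_size: int = 50_000,
    max_draws: int = 10_000_000,
) -> ReplicateDataset:
    """One case-control replicate from the logistic liability model.

    Subjects are drawn in blocks until the case and control quotas
    (``config.n // 2`` each) are filled; the generating gene region is drawn
    once per replicate and genotypes are sampled per subject from its MAFs.

    Only the causal genotype columns are drawn for the oversampling pool;
    the disease status depends on the pool subjects only through those
    columns (plus covariates, exposure and logistic noise), so the
    non-causal columns are exchangeable with draws made after quota
    selection and are filled in for the retained subjects only. This keeps
    the pool cost O(pool x n_causal) instead of O(pool x p).
    """
    scheme = scheme or WeightScheme()
    n_cases = n_controls = config.n // 2
    maf = np.concatenate(
        [
            rng.uniform(0.05, 0.5, size=config.profile.n_common),
            rng.uniform(0.005, 0.05, size=config.profile.n_rare),
        ]
    )
    p = len(maf)

    # causal structure fixed for the replicate (drawn from the MAFs alone)
    _, _, truth = _genetic_terms(config, np.empty((0, p)), maf, rng, scheme)
    main_idx, inter_idx = truth["main_idx"], truth["inter_idx"]
    wb = truth["w_main"] * truth["beta"]
    wg = truth["w_inter"] * truth["gamma"]
    causal = np.unique(np.concatenate([main_idx, inter_idx]))
    pos_in_causal = {j: k for k, j in enumerate(causal)}
    main_c = np.array([pos_in_causal[j] for j in main_idx])
    inter_c = np.array([pos_in_causal[j] for j in inter_idx])
    maf_c = maf[causal]

    def draw_binom2(freqs, rows):
        # Binomial(2, f) as two Bernoulli allele draws (faster than binomial)
        shape = (rows, len(freqs))
        return (
            (rng.random(shape) < freqs).astype(float) + (rng.random(shape) < freqs)
        )

    cases, controls = [], []
    n_case_found = n_control_found = 0
    drawn = 0
    while n_case_found < n_cases or n_control_found < n_controls:
        if drawn >= max_draws:
            raise RuntimeError(
                f"case/control quota unreachable after {max_draws} draws "
                "(prevalence too extreme for the requested sample size)"
            )
        block = min(block_size, max_draws - drawn)
        drawn += block
        Gc = draw_binom2(maf_c, block)
        main_term = Gc[:, main_c] @ wb
        inter_term = Gc[:, inter_c] @ wg
        x1, x2 = _covariates(block, rng)
        env = rng.binomial(1, 0.5, size=block).astype(float)
        eta = LOGIT_INTERCEPT + 0.05 * x1 + 0.057 * x2 + 0.64 * env + main_term + env * inter_term
        y = (rng.random(block) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        rows = np.column_stack([y, x1, x2, env])
        case_idx = np.flatnonzero(y == 1)
        control_idx = np.flatnonzero(y == 0)
        cases.append((case_idx, rows, Gc))
        controls.append((control_idx, rows, Gc))
        n_case_found += len(case_idx)
        n_control_found += len(control_idx)

    def _take(blocks, quota):
        out_rows, out_G, got = [], [], 0
        for idx, rows, Gc in blocks:
            take = idx[: quota - got]
            out_rows.append(rows[take])
            out_G.append(Gc[take])
            got += len(take)
            if got >= quota:
                break
        return np.vstack(out_rows), np.vstack(out_G)

    rows_ca, Gc_ca = _take(cases, n_cases)
    rows_co, Gc_co = _take(controls, n_controls)
    rows = np.vstack([rows_ca, rows_co])
    Gc_all = np.vstack([Gc_ca, Gc_co])
    n_total = rows.shape[0]
    # non-causal columns: independent of selection, drawn for retained subjects
    G_all = np.empty((n_total, p))
    noncausal = np.setdiff1d(np.arange(p), causal)
    G_all[:, causal] = Gc_all
    if len(noncausal):
        G_all[:, noncausal] = draw_binom2(maf[noncausal], n_total)
    y, x1, x2, env = rows[:, 0], rows[:, 1], rows[:, 2], rows[:, 3]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        markers = MarkerSet.from_dosages(G_all)
    truth = dict(truth)
    truth["true_maf"] = maf
    truth["n_population_drawn"] = drawn
    truth["population_prevalence"] = n_case_found / drawn
    X = np.column_stack([x1, x2])
    return ReplicateDataset(_quick_inputs(y, env, X, markers, "binary"), truth)


@dataclass
class StudyResult:
    """Rejection-rate summary plus the raw per-replicate p-values."""

    pvalues: np.ndarray
    table: pd.DataFrame
    config: ScenarioConfig
    method: str
    seed: int

    def rate(self, alpha: float) -> float:
        return float(np.mean(self.pvalues < alpha))


def _binomial_ci(rate: float, n: int, level: float = 0.95) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(rate * (1.0 - rate) / n)
    return rate - z * se, rate + z * se


def _replicate_rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))


def _run_replicates(
    config: ScenarioConfig,
    method: str,
    n_reps: int,
    seed: int,
    scheme: Optional[WeightScheme],
    binary_block: Optional[int],
) -> np.ndarray:
    if binary_block is None:
        # size the first quota-sampling block so one block usually suffices
        # at the design prevalence (~0.085); top-up blocks handle shortfalls
        binary_block = max(2000, int(1.1 * (config.n // 2) / 0.085))
    pvals = np.empty(n_reps)
    for rep in range(n_reps):
        rng = _replicate_rng(seed, rep)
        if config.trait_type == "binary":
            data = simulate_binary(config, rng, scheme=scheme, block_size=binary_block)
        else:
            data = simulate_continuous(config, rng, scheme=scheme)
        res = run_gxe_test(data.inputs, scheme=scheme, mode=method)
        pvals[rep] = res.pvalue
    return pvals


def type1_study(
    trait_type: str = "continuous",
    scenario: int = 1,
    method: str = "ran",
    n: int = 5000,
    n_reps: int = 10_000,
    alpha_levels: tuple[float, ...] = (0.01, 0.001),
    seed: int = 0,
    profile: GeneProfile = NULL_SET,
    scheme: Optional[WeightScheme] = None,
    binary_block: Optional[int] = None,
) -> StudyResult:
    """Empirical type-I error under gamma = 0.

    Scenario 1: all main-effect coefficients positive; scenario 2: half of
    the common and half of the rare coefficients negative. Each replicate
    draws a fresh 2-common/8-rare variant set (profile ``NULL_SET``), all
    ten variants causal for the main effect.
    """
    if scenario not in (1, 2):
        raise ValueError("scenario must be 1 or 2")
    config = ScenarioConfig(
        trait_type=trait_type,
        profile=profile,
        causal_selection="two_common_eight_rare",
        sign_pattern=(1.0 if scenario == 1 else 0.5, 1.0),
        n=n,
        null=True,
    )
    pvals = _run_replicates(config, method, n_reps, seed, scheme, binary_block)
    rows = []
    for alpha in alpha_levels:
        rate = float(np.mean(pvals < alpha))
        lo, hi = _binomial_ci(rate, n_reps)
        nominal_lo, nominal_hi = _binomial_ci(alpha, n_reps)
        rows.append(
            {
                "alpha": alpha,
                "rate": rate,
                "ci_low": lo,
                "ci_high": hi,
                "nominal_ci_low": nominal_lo,
                "nominal_ci_high": nominal_hi,
                "within_nominal_ci": nominal_lo <= rate <= nominal_hi,
            }
        )
    return StudyResult(pvals, pd.DataFrame(rows), config, method, seed)


def power_study(
    config: ScenarioConfig,
    method: str = "ran",
    n_reps: int = 1000,
    alpha: float = 1e-4,
    seed: int = 0,
    scheme: Optional[WeightScheme] = None,
    binary_block: Optional[int] = None,
) -> StudyResult:
    """Empirical power: fraction of replicates with p < alpha."""
    if config.null:
        warnings.warn("power_study called with a null config; result is a type-I rate")
    pvals = _run_replicates(config, method, n_reps, seed, scheme, binary_block)
    rate = float(np.mean(pvals < alpha))
    lo, hi = _binomial_ci(rate, n_reps)
    table = pd.DataFrame([{"alpha": alpha, "power": rate, "ci_low": lo, "ci_high": hi}])
    return StudyResult(pvals, table, config, method, seed)


def scenario_grid(trait_type: str = "continuous") -> list[ScenarioConfig]:
    """The full power-scenario crossing for one trait type (32 cells; both
    gene profiles x 2 selection methods x 4 sign patterns x 2 gamma values)."""
    grid = []
    for profile in (A4GALT_LIKE, TIMP3_LIKE):
        for selection in ("two_common_eight_rare", "any_mix"):
            for signs in SIGN_PATTERNS:
                for g_rare in GAMMA_RARE[trait_type]:
                    grid.append(
                        ScenarioConfig(
                            trait_type=trait_type,
                            profile=profile,
                            causal_selection=selection,
                            sign_pattern=signs,
                            gamma_rare=g_rare,
                        )
                    )
    return grid
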