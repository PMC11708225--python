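"""Single-region test drivers tying the pipeline together."""

from __future__ import annotations

from typing import Optional

from .data_model import TestInputs, WeightScheme
from .kernels import FIXED_MAIN, RANDOM_MAIN, build_kernels
from .liability import run_binary_test
from .mqs import estimate_fix, estimate_null_fix, estimate_null_ran, estimate_ran
from .pvalue import TestResult, pvalue

__all__ = ["run_gxe_test", "run_continuous_test"]

_MODE_ALIASES = {
    "ran": RANDOM_MAIN,
    "fix": FIXED_MAIN,
    RANDOM_MAIN: RANDOM_MAIN,
    FIXED_MAIN: FIXED_MAIN,
}


def resolve_mode(mode: str) -> str:
    try:
        return _MODE_ALIASES[mode]
    except KeyError:
        raise ValueError(f"unknown mode {mode!r}; use 'ran' or 'fix'") from None


def run_continuous_test(
    inputs: TestInputs,
    scheme: Optional[WeightScheme] = None,
    mode: str = RANDOM_MAIN,
) -> TestResult:
    """MAGEIT_RAN / MAGEIT_FIX on a continuous phenotype."""
    mode = resolve_mode(mode)
    bundle = build_kernels(inputs, scheme=scheme, mode=mode)
    if mode == RANDOM_MAIN:
        comps = estimate_ran(bundle)
        null = estimate_null_ran(bundle)
    else:
        comps = estimate_fix(bundle)
        null = estimate_null_fix(bundle)
    return pvalue(bundle, comps, null)


def run_gxe_test(
    inputs: TestInputs,
    scheme: Optional[WeightScheme] = None,
    mode: str = RANDOM_MAIN,
    constraint_mode: str = "normalize_to_one",
) -> TestResult:
    """Dispatch to the continuous or binary (liability-threshold) pipeline."""
    mode = resolve_mode(mode)
    if inputs.trait_type == "binary":
        return run_binary_test(inputs, scheme=scheme, mode=mode, constraint_mode=constraint_mode)
    return run_continuous_test(inputs, scheme=scheme, mode=mode)
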