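"""Genome-wide driver: per-gene tests over BED regions, QC, and diagnostics.

The scan iterates gene regions in deterministic order, extracts the
region's variants from the genotype source, applies the variant QC filters
(call rate, MAF, Hardy-Weinberg), assembles the test inputs and runs the
configured MAGEIT test. Per-gene failures are recorded as skips with a
reason and never abort the scan; an existing output file makes the scan
resumable (completed genes are not recomputed).

Diagnostics include the genomic-control inflation factor lambda_GC
(median of the chi-square(1)-transformed p-values over its null median)
and the Bonferroni threshold over tested genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import resolve_mode, run_gxe_test
from .data_model import MarkerSet, Region, WeightScheme, assemble_inputs, compute_maf

__all__ = [
    "qc_filter",
    "QCThresholds",
    "scan",
    "ScanResult",
    "genomic_control",
    "adjust_by_lambda",
    "bonferroni_threshold",
]

CHI2_1_MEDIAN = float(stats.chi2.median(1))  # 0.4549...


@dataclass(frozen=True)
class QCThresholds:
    """Variant QC defaults: call rate > 95%, MAF > 0.5%, HWE p > 1e-6."""

    min_call_rate: float = 0.95
    min_maf: float = 0.005
    hwe_pvalue: float = 1e-6


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Chi-square (1 df) Hardy-Weinberg test per variant on hard calls.

    Columns with non-integer (dosage) entries get NaN — HWE is undefined
    for imputed dosages and such variants are not filtered on it.
    """
    n_var = dosages.shape[1]
    out = np.full(n_var, np.nan)
    for j in range(n_var):
        col = dosages[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0 or not np.all(col == np.round(col)):
            continue
        n0 = float(np.sum(col == 0))
        n1 = float(np.sum(col == 1))
        n2 = float(np.sum(col == 2))
        n = n0 + n1 + n2
        f = (n1 + 2 * n2) / (2 * n)
        exp = np.array([n * (1 - f) ** 2, 2 * n * f * (1 - f), n * f**2])
        if np.any(exp == 0):
            out[j] = 1.0
            continue
        chi2 = float(np.sum((np.array([n0, n1, n2]) - exp) ** 2 / exp))
        out[j] = stats.chi2.sf(chi2, 1)
    return out


def qc_filter(
    markers: MarkerSet, thresholds: QCThresholds = QCThresholds()
) -> tuple[MarkerSet, pd.DataFrame]:
    """Apply call-rate, MAF and HWE filters; returns (filtered, report).

    The report has one row per input variant with the computed metrics and
    a ``kept`` flag. Dosage (non-hard-call) variants skip the HWE test and
    are flagged ``hwe_skipped``.
    """
    d = markers.dosages
    call_rate = np.mean(np.isfinite(d), axis=0)
    maf, _ = compute_maf(d)
    hwe_p = _hwe_pvalues(d)
    hwe_skipped = ~np.isfinite(hwe_p)
    keep = (
        (call_rate > thresholds.min_call_rate)
        & (maf > thresholds.min_maf)
        & (hwe_skipped | (hwe_p > thresholds.hwe_pvalue))
    )
    report = pd.DataFrame(
        {
            "variant_id": markers.variant_ids,
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "hwe_skipped": hwe_skipped,
            "kept": keep,
        }
    )
    return markers.subset(keep), report


@dataclass
class ScanResult:
    """Per-gene rows plus skip records and scan metadata."""

    table: pd.DataFrame
    skipped: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def lambda_gc(self) -> Optional[float]:
        if len(self.table) >= 2:
            return genomic_control(self.table["pvalue"].to_numpy(), min_count=2)
        return None


SCAN_COLUMNS = [
    "chrom",
    "gene",
    "n_snp",
    "n_common",
    "n_rare",
    "sigma2",
    "pvalue",
    "method",
    "flags",
]


def scan(
    marker_source: Callable[[Region], MarkerSet],
    regions: list[Region],
    phenotype,
    covariates,
    environment,
    trait_type: str = "continuous",
    mode: str = "ran",
    scheme: Optional[WeightScheme] = None,
    qc: Optional[QCThresholds] = QCThresholds(),
    min_variants: int = 2,
    out: Optional[Path] = None,
) -> ScanResult:
    """Run the configured test over every region.

    ``marker_source`` maps a Region to a MarkerSet (see :mod:`mageit.io`
    for VCF/PLINK-backed sources). Phenotype/covariates/environment are
    shared across genes and aligned per gene by ``assemble_inputs``. When
    ``out`` points to an existing TSV from a previous (partial) run, genes
    already present are skipped and the new rows are appended.
    """
    mode = resolve_mode(mode)
    done: set[str] = set()
    prior_rows: list[dict] = []
    if out is not None and Path(out).exists():
        prior = pd.read_csv(out, sep="\t", dtype={"chrom": str, "gene": str, "flags": str})
        prior["flags"] = prior["flags"].fillna("")
        done = set(prior["gene"].astype(str))
        prior_rows = prior.to_dict("records")

    rows: list[dict] = list(prior_rows)
    skipped: list[dict] = []
    for region in sorted(regions, key=lambda r: (r.chrom, r.start, r.name)):
        if region.name in done:
            continue
        try:
            markers = marker_source(region)
            if qc is not None:
                markers, _ = qc_filter(markers, qc)
            if markers.p < min_variants:
                skipped.append(
                    {"gene": region.name, "reason": f"fewer than {min_variants} variants after QC"}
                )
                continue
            inputs = assemble_inputs(phenotype, environment, covariates, markers, trait_type)
            res = run_gxe_test(inputs, scheme=scheme, mode=mode)
            rows.append(
                {
                    "chrom": region.chrom,
                    "gene": region.name,
                    "n_snp": inputs.p,
                    "n_common": inputs.markers.n_common,
                    "n_rare": inputs.markers.n_rare,
                    "sigma2": res.statistic,
                    "pvalue": res.pvalue,
                    "method": res.method,
                    "flags": ";".join(res.flags),
                }
            )
        except Exception as err:  # per-gene failures never abort the scan
            skipped.append({"gene": region.name, "reason": str(err)})
    table = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    table = table.sort_values(["chrom", "gene"], kind="stable").reset_index(drop=True)
    result = ScanResult(
        table=table,
        skipped=pd.DataFrame(skipped, columns=["gene", "reason"]),
        metadata={"trait_type": trait_type, "mode": mode, "min_variants": min_variants},
    )
    if out is not None:
        table.to_csv(out, sep="\t", index=False)
    return result


def genomic_control(pvalues: np.ndarray, min_count: int = 100) -> float:
    """Genomic-control inflation factor of a set of p-values.

    lambda_GC = median(F^-1_chi2(1)(1 - p)) / median(chi2(1)); values near 1
    indicate a well-calibrated scan.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < min_count:
        raise ValueError(f"need at least {min_count} p-values for a stable median")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_1_MEDIAN)


def adjust_by_lambda(pvalues: np.ndarray, lam: float) -> np.ndarray:
    """Divide the implied 1-df chi-square statistics by lambda and recompute p."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    chi = stats.chi2.isf(np.asarray(pvalues, dtype=float), 1)
    return stats.chi2.sf(chi / lam, 1)


def bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> float:
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes
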