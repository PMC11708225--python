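"""Genome-scan driver: QC, lambda_GC, Bonferroni, spiked-signal detection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mageit.data_model import MarkerSet, Region
from mageit.scan import (
    QCThresholds,
    adjust_by_lambda,
    bonferroni_threshold,
    genomic_control,
    qc_filter,
    scan,
)


def toy_panel():
    """Five variants with hand-computable QC outcomes (n = 200).

    v0: clean common variant               -> kept
    v1: 10% missing calls                  -> dropped (call rate 0.90 < 0.95)
    v2: maf 0.004                          -> dropped (MAF <= 0.005)
    v3: maf 0.006                          -> kept (just above the MAF filter)
    v4: all heterozygotes                  -> dropped (HWE chi2 p ~ 2e-45)
    """
    n = 200
    d = np.zeros((n, 5))
    d[:60, 0] = 1
    d[60:80, 0] = 2
    d[:, 1] = d[:, 0]
    d[:20, 1] = np.nan
    d[0, 2] = 1  # 1 of 400 alleles: f = 0.0025... use 0.004 -> need 1.6 alleles; use maf via dosage 0/1
    d[:2, 2] = [1, 0.6]  # mean 1.6/200 -> f = 0.004
    d[:3, 3] = [1, 1, 0.4]  # 2.4 / 400 -> f = 0.006
    d[:, 4] = 1.0  # all hets: extreme HWE violation
    return MarkerSet.from_dosages(d)


class TestQCFilter:
    def test_hand_computed_panel(self):
        kept, report = qc_filter(toy_panel())
        assert report["kept"].tolist() == [True, False, False, True, False]
        assert kept.p == 2
        # v2/v3 straddle the MAF boundary
        assert report.loc[2, "maf"] == pytest.approx(0.004)
        assert report.loc[3, "maf"] == pytest.approx(0.006)
        # v1 fails on call rate alone
        assert report.loc[1, "call_rate"] == pytest.approx(0.90)

    def test_dosage_variants_skip_hwe(self):
        kept, report = qc_filter(toy_panel())
        # columns 2 and 3 contain fractional dosages -> HWE skipped for them
        assert report.loc[2, "hwe_skipped"] and report.loc[3, "hwe_skipped"]
        assert not report.loc[4, "hwe_skipped"]
        assert report.loc[4, "hwe_p"] < 1e-6

    def test_thresholds_configurable(self):
        kept, report = qc_filter(toy_panel(), QCThresholds(min_maf=0.003, min_call_rate=0.85, hwe_pvalue=0.0))
        assert report["kept"].tolist() == [True, True, True, True, True]


class TestGenomicControl:
    def test_uniform_pvalues_give_lambda_one(self, rng):
        p = rng.uniform(size=100_000)
        lam = genomic_control(p)
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_inflated_statistics_recovered_and_corrected(self, rng):
        stats1 = 1.5 * rng.chisquare(1, 100_000)
        p = stats.chi2.sf(stats1, 1)
        lam = genomic_control(p)
        assert lam == pytest.approx(1.5, abs=0.03)
        adj = adjust_by_lambda(p, lam)
        ks = stats.kstest(adj, "uniform").statistic
        assert ks < 0.01

    def test_constant_half_gives_unity(self):
        lam = genomic_control(np.full(500, 0.5))
        assert lam == pytest.approx(1.0, rel=1e-12)

    def test_requires_enough_pvalues(self):
        with pytest.raises(ValueError, match="at least"):
            genomic_control(np.full(50, 0.5))


class TestBonferroni:
    def test_genome_wide_threshold(self):
        assert bonferroni_threshold(19005, 0.05) == pytest.approx(2.63e-6, rel=1e-2)

    def test_single_gene(self):
        assert bonferroni_threshold(1, 0.05) == 0.05

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestScan:
    def _panel(self, seed=0, n=400, spike_gene=None):
        """Three synthetic genes; optionally plant a strong interaction in one."""
        rng = np.random.default_rng(seed)
        genes = {}
        regions = []
        for g in range(3):
            p = 6
            maf = rng.uniform(0.05, 0.4, p)
            genes[f"gene{g}"] = rng.binomial(2, maf, size=(n, p)).astype(float)
            regions.append(Region("1", 1000 * g, 1000 * g + 999, f"gene{g}"))
        env = rng.binomial(1, 0.5, n).astype(float)
        cov = rng.normal(50, 10, size=(n, 1))
        y = 0.02 * cov[:, 0] + 0.3 * env + rng.normal(0, 1, n)
        if spike_gene is not None:
            y = y + 1.2 * env * genes[spike_gene][:, 0]
        sources = {name: MarkerSet.from_dosages(d) for name, d in genes.items()}
        return (lambda region: sources[region.name]), regions, y, cov, env

    def test_null_panel_rows_and_pvalues(self):
        source, regions, y, cov, env = self._panel()
        res = scan(source, regions, y, cov, env, qc=None)
        assert len(res.table) == 3
        assert ((res.table["pvalue"] > 0) & (res.table["pvalue"] <= 1)).all()
        assert res.skipped.empty

    def test_spiked_gene_has_minimum_pvalue(self):
        source, regions, y, cov, env = self._panel(seed=3, spike_gene="gene1")
        res = scan(source, regions, y, cov, env, qc=None)
        best = res.table.loc[res.table["pvalue"].idxmin(), "gene"]
        assert best == "gene1"
        assert res.table["pvalue"].min() < 1e-4

    def test_small_gene_skipped_with_reason(self):
        source, regions, y, cov, env = self._panel()
        def one_variant_source(region):
            ms = source(region)
            return ms.subset(np.array([0])) if region.name == "gene2" else ms
        res = scan(one_variant_source, regions, y, cov, env, qc=None, min_variants=2)
        assert len(res.table) == 2
        assert res.skipped["gene"].tolist() == ["gene2"]
        assert "fewer than 2" in res.skipped["reason"].iloc[0]

    def test_resume_reproduces_full_scan(self, tmp_path):
        source, regions, y, cov, env = self._panel(seed=7)
        out = tmp_path / "scan.tsv"
        full = scan(source, regions, y, cov, env, qc=None)
        # partial run: first gene only, then resume over all regions
        scan(source, regions[:1], y, cov, env, qc=None, out=out)
        resumed = scan(source, regions, y, cov, env, qc=None, out=out)
        pd.testing.assert_frame_equal(
            resumed.table.reset_index(drop=True), full.table.reset_index(drop=True)
        )
        # and the output file holds the same rows
        on_disk = pd.read_csv(out, sep="\t")
        assert on_disk["gene"].tolist() == full.table["gene"].tolist()

    def test_order_invariance(self):
        source, regions, y, cov, env = self._panel(seed=9)
        a = scan(source, regions, y, cov, env, qc=None)
        b = scan(source, regions[::-1], y, cov, env, qc=None)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_per_gene_failure_recorded_not_raised(self):
        source, regions, y, cov, env = self._panel()
        def failing_source(region):
            if region.name == "gene1":
                raise RuntimeError("corrupt region")
            return source(region)
        res = scan(failing_source, regions, y, cov, env, qc=None)
        assert len(res.table) == 2
        assert "corrupt region" in res.skipped["reason"].iloc[0]
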