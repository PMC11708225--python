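"""Readers for the standard input formats.

* Genotypes: VCF/VCF.gz (via cyvcf2; the ``DS`` dosage FORMAT field is used
  when present, otherwise GT allele counts) and PLINK1 bed/bim/fam. The
  PLINK reader is a minimal in-house decoder of the SNP-major 2-bit format
  (00 = two copies of allele A1, 10 = het, 11 = zero copies, 01 = missing).
* Regions: BED, 0-based half-open; the gene name is taken from column 4.
* Phenotype / covariates / environment: tab-delimited text with a header
  and a subject-ID column.

VCF coordinates are 1-based inclusive; the conversion from BED's 0-based
half-open convention happens here and only here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import MarkerSet, Region

__all__ = [
    "read_regions_bed",
    "read_phenotype_table",
    "read_vcf_region",
    "read_plink",
    "PlinkData",
]


def read_regions_bed(path) -> list[Region]:
    """Parse a BED file into Region records (0-based half-open)."""
    regions = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: BED line has fewer than 3 columns")
            name = parts[3] if len(parts) > 3 else f"region{line_no}"
            regions.append(Region(parts[0], int(parts[1]), int(parts[2]), name))
    return regions


def read_phenotype_table(path, id_col: Optional[str] = None) -> pd.DataFrame:
    """Tab-delimited table with header, indexed by its subject-ID column
    (first column when ``id_col`` is None)."""
    df = pd.read_csv(path, sep="\t")
    if id_col is None:
        id_col = df.columns[0]
    if id_col not in df.columns:
        raise ValueError(f"ID column {id_col!r} not found in {path}")
    return df.set_index(id_col)


def read_vcf_region(path, region: Region) -> tuple[MarkerSet, np.ndarray]:
    """Extract a region from a VCF; returns (markers, sample IDs).

    Dosages come from the DS FORMAT field when present, else from GT
    counts; missing genotypes become NaN (complete-case handling happens
    at input assembly).
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    path = str(path)
    vcf = VCF(path)
    samples = np.asarray(vcf.samples)
    indexed = path.endswith((".gz", ".bgz")) and (
        Path(path + ".tbi").exists() or Path(path + ".csi").exists()
    )
    if indexed:
        query = f"{region.chrom}:{region.start + 1}-{region.end}"  # BED -> 1-based inclusive
        iterator = vcf(query)
    else:
        # no tabix index (plain-text VCF): stream everything and filter
        iterator = (
            v
            for v in vcf
            if v.CHROM == region.chrom and region.start + 1 <= v.POS <= region.end
        )
    cols, ids = [], []
    for var in iterator:
        # half-open upper bound: VCF POS is 1-based, region.end exclusive
        if var.POS > region.end or var.POS <= region.start:
            continue
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(len(samples), -1)[:, 0]
            d = np.where((d < 0) | (d > 2), np.nan, d)
        else:
            gt = np.asarray(var.genotype.array())[:, :2]
            d = np.where((gt < 0).any(axis=1), np.nan, gt.clip(0).sum(axis=1)).astype(float)
        cols.append(d)
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0] if var.ALT else '.'}")
    vcf.close()
    if not cols:
        raise ValueError(f"no variants in {query}")
    dosages = np.column_stack(cols)
    return MarkerSet.from_dosages(dosages, variant_ids=ids, region=region), samples


class PlinkData:
    """Lazily decoded PLINK1 fileset (bed/bim/fam)."""

    def __init__(self, prefix):
        prefix = str(prefix)
        self.bim = pd.read_csv(
            prefix + ".bim",
            sep=r"\s+",
            header=None,
            names=["chrom", "snp", "cm", "pos", "a1", "a2"],
            dtype={"chrom": str},
        )
        self.fam = pd.read_csv(
            prefix + ".fam",
            sep=r"\s+",
            header=None,
            names=["fid", "iid", "father", "mother", "sex", "pheno"],
            dtype={"iid": str},
        )
        with open(prefix + ".bed", "rb") as fh:
            raw = fh.read()
        if raw[:3] != b"\x6c\x1b\x01":
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK1 bed file")
        self._body = np.frombuffer(raw, dtype=np.uint8, offset=3)
        self.n = len(self.fam)
        self.p = len(self.bim)
        self._stride = (self.n + 3) // 4
        if len(self._body) != self._stride * self.p:
            raise ValueError(f"{prefix}.bed size inconsistent with bim/fam")

    @property
    def samples(self) -> np.ndarray:
        return self.fam["iid"].to_numpy()

    def dosages(self, variant_indices: Optional[Sequence[int]] = None) -> np.ndarray:
        """Decode dosages (count of A1 allele) for the selected variants."""
        idx = np.arange(self.p) if variant_indices is None else np.asarray(variant_indices)
        out = np.empty((self.n, len(idx)))
        # 2-bit codes per sample: 00 -> 2 x A1, 10 -> het, 11 -> 0 x A1, 01 -> missing
        lookup = np.array([2.0, np.nan, 1.0, 0.0])
        for k, j in enumerate(idx):
            block = self._body[j * self._stride : (j + 1) * self._stride]
            codes = (block[:, None] >> np.array([0, 2, 4, 6])) & 0b11
            out[:, k] = lookup[codes.reshape(-1)[: self.n]]
        return out

    def region_markers(self, region: Region) -> MarkerSet:
        """Variants with bim position inside the (0-based half-open) region."""
        pos = self.bim["pos"].to_numpy()  # bim positions are 1-based
        mask = (
            (self.bim["chrom"].to_numpy() == str(region.chrom))
            & (pos >= region.start + 1)
            & (pos <= region.end)
        )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"no variants in {region.chrom}:{region.start}-{region.end}")
        return MarkerSet.from_dosages(
            self.dosages(idx),
            variant_ids=self.bim["snp"].to_numpy()[idx],
            region=region,
        )


def read_plink(prefix) -> PlinkData:
    return PlinkData(prefix)
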