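"""Individual-level allele-frequency (AF) estimation from probe intensities.

The A and B allele channels of an array rarely hybridize with equal
efficiency, so the naive ratio I_A / (I_A + I_B) is biased away from 0.5 for
heterozygotes. The per-SNP coefficient of preferential amplification/
hybridization (CPA), kappa_m, calibrates this: it is estimated as the mean
A/B intensity ratio over heterozygous samples, and the adjusted AF

    lambda = I_A / (I_A + kappa * I_B)

then maps heterozygotes to 0.5 by construction, AA homozygotes toward 1 and
BB homozygotes toward 0 — the three-band AF profile expected of a
good-quality array.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AlleleFrequencyMatrix, GenotypeMatrix, IntensityMatrix
from .errors import InputError

#: Default minimum number of heterozygotes to estimate a per-SNP CPA.
DEFAULT_MIN_HET = 3

_CPA_COLUMNS = ("snp_id", "kappa", "n_het", "fallback")


@dataclass
class CpaTable:
    """Per-SNP CPA estimates.

    ``table`` has columns ``snp_id, kappa, n_het, fallback``; ``fallback``
    is True when fewer than ``min_het`` heterozygotes were available and
    kappa was set to 1 (no adjustment).
    """

    table: pd.DataFrame
    min_het: int = DEFAULT_MIN_HET

    def __post_init__(self) -> None:
        missing = [c for c in _CPA_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"CPA table lacks column(s): {', '.join(missing)}")
        tab = self.table.loc[:, list(_CPA_COLUMNS)].reset_index(drop=True).copy()
        tab["snp_id"] = tab["snp_id"].astype(str)
        if tab["snp_id"].duplicated().any():
            raise InputError("duplicate snp_id in CPA table")
        tab["kappa"] = tab["kappa"].astype(float)
        if (tab["kappa"] <= 0).any():
            snp = tab.loc[tab["kappa"] <= 0, "snp_id"].iloc[0]
            raise InputError(f"kappa must be > 0 (SNP {snp!r})")
        tab["n_het"] = tab["n_het"].astype(np.int64)
        tab["fallback"] = tab["fallback"].astype(bool)
        self.table = tab

    def kappa_for(self, snp_ids: pd.Index | list[str]) -> np.ndarray:
        idx = pd.Index(snp_ids)
        series = self.table.set_index("snp_id")["kappa"]
        missing = idx.difference(series.index)
        if len(missing):
            raise InputError(f"SNP {missing[0]!r} missing from CPA table")
        return series.reindex(idx).to_numpy(dtype=float)


def estimate_cpa(
    intensities: IntensityMatrix,
    genotypes: GenotypeMatrix,
    min_het: int = DEFAULT_MIN_HET,
) -> CpaTable:
    """Estimate the per-SNP CPA kappa_m from heterozygous samples.

    kappa_m is the arithmetic mean of I_A / I_B over samples called AB at SNP
    m whose B intensity is positive. SNPs with fewer than ``min_het`` usable
    heterozygotes fall back to kappa = 1 with ``fallback`` set.
    """
    if min_het < 1:
        raise InputError("min_het must be >= 1")
    shared = [s for s in intensities.sample_ids if s in set(genotypes.sample_ids)]
    if not shared:
        raise InputError("no samples shared between intensities and genotypes")
    snps = intensities.snp_ids
    calls = genotypes.calls.reindex(index=snps, columns=shared)
    ia = intensities.intensity_a.loc[snps, shared].to_numpy(dtype=float)
    ib = intensities.intensity_b.loc[snps, shared].to_numpy(dtype=float)
    het = (calls == "AB").to_numpy() & (ib > 0) & ~np.isnan(ia)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(het, ia / ib, np.nan)
    n_het = het.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows fall back below
        kappa = np.nanmean(ratio, axis=1)
    fallback = n_het < min_het
    kappa = np.where(fallback, 1.0, kappa)
    table = pd.DataFrame(
        {"snp_id": snps, "kappa": kappa, "n_het": n_het, "fallback": fallback}
    )
    return CpaTable(table=table, min_het=min_het)


def estimate_af(intensities: IntensityMatrix, cpa: CpaTable) -> AlleleFrequencyMatrix:
    """Estimate individual-level AFs from CPA-adjusted intensities.

    lambda = I_A / (I_A + kappa * I_B), clipped to [0, 1]. Cells whose
    adjusted total intensity I_A + kappa * I_B is zero (or with a missing
    channel) are returned as missing.
    """
    kappa = cpa.kappa_for(intensities.snp_ids)[:, None]
    ia = intensities.intensity_a.to_numpy(dtype=float)
    ib = intensities.intensity_b.to_numpy(dtype=float)
    total = ia + kappa * ib
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(total > 0, ia / total, np.nan)
    lam = np.clip(lam, 0.0, 1.0)
    af = pd.DataFrame(lam, index=intensities.snp_ids, columns=intensities.sample_ids)
    return AlleleFrequencyMatrix(annotation=intensities.annotation, af=af)


def genotype_implied_af(genotype: str) -> float:
    """AF implied by a genotype call: AA -> 1.0, AB -> 0.5, BB -> 0.0, NC -> NaN."""
    implied = {"AA": 1.0, "AB": 0.5, "BB": 0.0, "NC": np.nan}
    if genotype not in implied:
        raise InputError(f"unknown genotype code {genotype!r}")
    return implied[genotype]


def genotype_implied_af_matrix(genotypes: GenotypeMatrix) -> AlleleFrequencyMatrix:
    """Matrix form of :func:`genotype_implied_af`, for genotype-based AF plots."""
    mapping = {"AA": 1.0, "AB": 0.5, "BB": 0.0, "NC": np.nan}
    af = genotypes.calls.apply(lambda col: col.map(mapping)).astype(float)
    return AlleleFrequencyMatrix(annotation=genotypes.annotation, af=af)
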