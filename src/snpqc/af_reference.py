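"""Genotype-specific allele-frequency references.

An AF reference stores, for each SNP and genotype class (AA/AB/BB), the mean
mu_G and standard deviation sigma_G of individual-level AFs observed in a set
of reference samples, together with the number of samples n that contributed.
These per-genotype bands are the "expected" AFs against which the
standardized-distance quality indices measure departures. References can be
built from samples of the study itself or from independent reference samples.

A reference cell is *eligible* for index computation when it rests on at
least ``min_count`` samples and its SD exceeds ``sd_floor``; ineligible cells
are excluded from distance computation rather than floored, so that
near-degenerate SDs cannot inflate standardized distances.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AlleleFrequencyMatrix, GenotypeMatrix, validate_annotation
from .errors import InputError

#: Genotype classes carried by a reference, in canonical order.
REFERENCE_GENOTYPES: tuple[str, ...] = ("AA", "AB", "BB")

#: Defaults for eligibility.
DEFAULT_MIN_COUNT = 3
DEFAULT_SD_FLOOR = 1e-4

_REF_COLUMNS = (
    "snp_id",
    "chromosome",
    "position_bp",
    "array_label",
    "genotype",
    "mean",
    "sd",
    "n",
    "eligible",
)


@dataclass
class AFReference:
    """Per-(SNP, genotype) mean/SD of individual-level AFs.

    ``table`` is a long-format frame with one row per (snp_id, genotype)
    cell and columns ``snp_id, chromosome, position_bp, array_label,
    genotype, mean, sd, n, eligible``.
    """

    table: pd.DataFrame
    population_label: str = ""
    min_count: int = DEFAULT_MIN_COUNT
    sd_floor: float = DEFAULT_SD_FLOOR

    def __post_init__(self) -> None:
        missing = [c for c in _REF_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"AF reference lacks column(s): {', '.join(missing)}")
        tab = self.table.loc[:, list(_REF_COLUMNS)].reset_index(drop=True).copy()
        tab["snp_id"] = tab["snp_id"].astype(str)
        tab["chromosome"] = tab["chromosome"].astype(str)
        tab["position_bp"] = pd.to_numeric(tab["position_bp"], errors="raise").astype(np.int64)
        tab["array_label"] = tab["array_label"].astype(str)
        tab["n"] = pd.to_numeric(tab["n"], errors="raise").astype(np.int64)
        tab["eligible"] = tab["eligible"].astype(bool)
        tab["genotype"] = tab["genotype"].astype(str)
        bad_g = ~tab["genotype"].isin(REFERENCE_GENOTYPES)
        if bad_g.any():
            raise InputError(
                f"invalid genotype class {tab.loc[bad_g, 'genotype'].iloc[0]!r} in AF reference"
            )
        dup = tab.duplicated(subset=["snp_id", "genotype"])
        if dup.any():
            raise InputError(
                f"duplicate (snp_id, genotype) row in AF reference: "
                f"{tab.loc[dup, 'snp_id'].iloc[0]!r}"
            )
        means = tab["mean"].to_numpy(dtype=float)
        sds = tab["sd"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nansum((means < 0) | (means > 1)):
                snp = tab.loc[(means < 0) | (means > 1), "snp_id"].iloc[0]
                raise InputError(f"reference mean outside [0, 1] for SNP {snp!r}")
            if np.nansum(sds < 0):
                snp = tab.loc[sds < 0, "snp_id"].iloc[0]
                raise InputError(f"negative reference sd for SNP {snp!r}")
        self.table = tab

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.table["snp_id"].unique())

    @property
    def annotation(self) -> pd.DataFrame:
        ann = (
            self.table.loc[:, ["snp_id", "chromosome", "position_bp", "array_label"]]
            .drop_duplicates(subset="snp_id")
            .reset_index(drop=True)
        )
        return validate_annotation(ann)

    def pivots(self, snp_ids: pd.Index | list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (mu, sigma, eligible) arrays of shape (len(snp_ids), 3).

        Column order follows :data:`REFERENCE_GENOTYPES`; absent cells are
        NaN / ineligible. Raises if none of ``snp_ids`` is covered.
        """
        idx = pd.Index(snp_ids)
        tab = self.table
        shape = (len(idx), len(REFERENCE_GENOTYPES))
        mu = np.full(shape, np.nan)
        sigma = np.full(shape, np.nan)
        eligible = np.zeros(shape, dtype=bool)
        row_pos = pd.Series(np.arange(len(idx)), index=idx)
        covered = tab["snp_id"].isin(idx)
        if not covered.any():
            raise InputError("AF reference covers none of the requested SNPs")
        sub = tab.loc[covered]
        r = row_pos[sub["snp_id"]].to_numpy()
        c = pd.Categorical(sub["genotype"], categories=REFERENCE_GENOTYPES).codes
        mu[r, c] = sub["mean"].to_numpy(dtype=float)
        sigma[r, c] = sub["sd"].to_numpy(dtype=float)
        eligible[r, c] = sub["eligible"].to_numpy(dtype=bool)
        return mu, sigma, eligible

    def equals(self, other: "AFReference") -> bool:
        a = self.table.sort_values(["snp_id", "genotype"]).reset_index(drop=True)
        b = other.table.sort_values(["snp_id", "genotype"]).reset_index(drop=True)
        if a.shape != b.shape or self.population_label != other.population_label:
            return False
        num = ["mean", "sd"]
        close = np.allclose(
            a[num].to_numpy(float), b[num].to_numpy(float), rtol=0, atol=1e-12, equal_nan=True
        )
        rest = [c for c in _REF_COLUMNS if c not in num]
        return bool(close) and a[rest].equals(b[rest])


def build_af_reference(
    af: AlleleFrequencyMatrix,
    genotypes: GenotypeMatrix,
    min_count: int = DEFAULT_MIN_COUNT,
    sd_floor: float = DEFAULT_SD_FLOOR,
    population_label: str = "",
) -> AFReference:
    """Build a genotype-stratified AF reference from calls and AFs.

    For every SNP and genotype class the mean and sample SD (n-1 denominator)
    of individual-level AFs are computed over the samples carrying that called
    genotype with a non-missing AF. Cells with fewer than ``min_count``
    samples or SD <= ``sd_floor`` are marked ineligible.
    """
    if min_count < 2:
        raise InputError("min_count must be >= 2")
    shared = [s for s in af.sample_ids if s in set(genotypes.sample_ids)]
    if not shared:
        raise InputError("no samples shared between AF matrix and genotype matrix")
    shared_snps = af.snp_ids.intersection(genotypes.snp_ids)
    if len(shared_snps) == 0:
        raise InputError("no SNPs shared between AF matrix and genotype matrix")
    lam = af.af.loc[shared_snps, shared]
    calls = genotypes.calls.loc[shared_snps, shared]
    ann = af.annotation.loc[shared_snps]

    pieces = []
    for g in REFERENCE_GENOTYPES:
        sel = lam.where(calls == g)
        n = sel.notna().sum(axis=1)
        mean = sel.mean(axis=1)
        sd = sel.std(axis=1, ddof=1)
        pieces.append(
            pd.DataFrame(
                {
                    "snp_id": shared_snps,
                    "chromosome": ann["chromosome"].to_numpy(),
                    "position_bp": ann["position_bp"].to_numpy(),
                    "array_label": ann["array_label"].to_numpy(),
                    "genotype": g,
                    "mean": mean.to_numpy(),
                    "sd": sd.to_numpy(),
                    "n": n.to_numpy(dtype=np.int64),
                }
            )
        )
    table = pd.concat(pieces, ignore_index=True)
    table = table[table["n"] > 0].reset_index(drop=True)
    table["eligible"] = (table["n"] >= min_count) & (table["sd"] > sd_floor)
    table = table.sort_values(["snp_id", "genotype"]).reset_index(drop=True)
    return AFReference(
        table=table,
        population_label=population_label,
        min_count=min_count,
        sd_floor=sd_floor,
    )


def subset_reference(
    ref: AFReference,
    chromosome: str | None = None,
    snp_ids: list[str] | set[str] | None = None,
) -> AFReference:
    """Restrict a reference to one chromosome and/or an explicit SNP-id set.

    Eligibility flags are preserved. Raises :class:`InputError` when the
    selection is empty or selects nothing.
    """
    if chromosome is None and snp_ids is None:
        raise InputError("provide a chromosome or a snp_id set to subset by")
    mask = pd.Series(True, index=ref.table.index)
    if chromosome is not None:
        mask &= ref.table["chromosome"].astype(str) == str(chromosome)
    if snp_ids is not None:
        wanted = {str(s) for s in snp_ids}
        if not wanted:
            raise InputError("empty snp_id selector")
        mask &= ref.table["snp_id"].isin(wanted)
    sub = ref.table.loc[mask].reset_index(drop=True)
    if sub.empty:
        raise InputError("subset selects no reference rows")
    return AFReference(
        table=sub,
        population_label=ref.population_label,
        min_count=ref.min_count,
        sd_floor=ref.sd_floor,
    )
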