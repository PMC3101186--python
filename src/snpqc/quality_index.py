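"""Standardized-distance quality indices for SNP arrays.

Array quality is quantified by how far the estimated individual-level AFs
stray from the genotype-specific reference bands, measured in reference SDs:

* genotype-based (Q1): q = |lambda - mu_G| / sigma_G with G the called
  genotype;
* nearest-mean-based (Q2): the same distance, but against the genotype class
  whose reference mean is closest to lambda — no genotype calls required,
  which keeps the index valid when calls are unreliable (e.g., copy-number
  change).

SNP-level distances are summarized per array with a robust statistic. The
default is the winsorized mean at level rho: values strictly above the rho
quantile of an array's distances are replaced by that quantile before
averaging, which tolerates a small fraction of extreme SNPs. The median and
the (upper-)trimmed mean are alternatives. Summaries are computed per
chromosome and genome-wide, and companion arrays (e.g., Nsp + Sty) can be
pooled at the SNP level into a "Merge" index.

All quantiles in this package use linear interpolation between order
statistics (numpy's default, the "type 7" convention), recorded in output
metadata.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .af_reference import AFReference, REFERENCE_GENOTYPES
from .containers import AlleleFrequencyMatrix, GenotypeMatrix
from .errors import InputError

#: Quantile convention shared by winsorization, empirical limits and
#: null-threshold derivation.
QUANTILE_RULE = "linear"

#: Scope label for the genome-wide summary.
GENOME_SCOPE = "GENOME"

#: Default winsorization level and minimum SNPs per summarized scope.
DEFAULT_RHO = 0.95
DEFAULT_MIN_SNPS = 30

SUMMARY_KINDS = ("winsorized_mean", "median", "trimmed_mean")
INDEX_KINDS = ("genotype_based", "nearest_mean")


# ---------------------------------------------------------------------------
# robust scalar summaries

def quantile(values: np.ndarray, p: float) -> float:
    """The shared quantile rule (linear interpolation of order statistics)."""
    return float(np.quantile(np.asarray(values, dtype=float), p, method=QUANTILE_RULE))


def winsorized_mean(values: np.ndarray, rho: float) -> float:
    """Mean after capping values strictly above the rho quantile at it."""
    x = np.asarray(values, dtype=float)
    cap = quantile(x, rho)
    return float(np.where(x > cap, cap, x).mean())


def trimmed_mean(values: np.ndarray, rho: float) -> float:
    """Mean after removing values strictly above the rho quantile."""
    x = np.asarray(values, dtype=float)
    cap = quantile(x, rho)
    return float(x[x <= cap].mean())


def summarize(values: np.ndarray, rho: float, summary_kind: str) -> float:
    if summary_kind == "winsorized_mean":
        return winsorized_mean(values, rho)
    if summary_kind == "median":
        return float(np.median(np.asarray(values, dtype=float)))
    if summary_kind == "trimmed_mean":
        return trimmed_mean(values, rho)
    raise InputError(f"unknown summary_kind {summary_kind!r}")


# ---------------------------------------------------------------------------
# containers

@dataclass
class SnpQiMatrix:
    """SNP x sample matrix of standardized distances q >= 0 (NaN = missing)."""

    annotation: pd.DataFrame
    q: pd.DataFrame
    index_kind: str

    def __post_init__(self) -> None:
        if self.index_kind not in INDEX_KINDS:
            raise InputError(f"unknown index_kind {self.index_kind!r}")
        vals = self.q.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nansum(vals < 0):
                raise InputError("negative standardized distance")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.q.columns)


@dataclass
class ArrayQiTable:
    """Array-level quality indices Q_x(rho) per sample and scope.

    ``table`` columns: sample_id, array_label, scope, index_kind,
    summary_kind, rho, qi_value, n_snps_used. ``skipped`` records scopes
    dropped for having fewer than ``min_snps`` usable SNPs.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.table.empty and (self.table["qi_value"] < 0).any():
            raise InputError("negative array-level quality index")
        self.metadata.setdefault("quantile_rule", QUANTILE_RULE)

    def genome(self) -> pd.DataFrame:
        return self.table[self.table["scope"] == GENOME_SCOPE].reset_index(drop=True)


@dataclass
class GcrTable:
    """Genotype call rates per sample and scope (fraction of calls != NC)."""

    table: pd.DataFrame  # sample_id, scope, gcr, n_called, n_total


# ---------------------------------------------------------------------------
# SNP-level indices

def _aligned_reference(
    snp_ids: pd.Index, ref: AFReference
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu, sigma, eligible = ref.pivots(snp_ids)
    # guard against zero/NaN SDs slipping through eligibility
    with np.errstate(invalid="ignore"):
        eligible = eligible & np.isfinite(mu) & np.isfinite(sigma) & (sigma > 0)
    return mu, sigma, eligible


def snp_qi_genotype(
    af: AlleleFrequencyMatrix, genotypes: GenotypeMatrix, ref: AFReference
) -> SnpQiMatrix:
    """Genotype-based standardized distances |lambda - mu_G| / sigma_G.

    Cells with NC calls, missing AFs, or an ineligible reference cell for the
    called genotype are missing.
    """
    snps = af.snp_ids.intersection(genotypes.snp_ids)
    if len(snps) == 0:
        raise InputError("no SNPs shared between AF and genotype matrices")
    shared = [s for s in af.sample_ids if s in set(genotypes.sample_ids)]
    if not shared:
        raise InputError("no samples shared between AF and genotype matrices")
    lam = af.af.loc[snps, shared].to_numpy(dtype=float)
    calls = genotypes.calls.loc[snps, shared]
    mu, sigma, eligible = _aligned_reference(snps, ref)
    gidx = pd.DataFrame(
        pd.Categorical(calls.to_numpy().ravel(), categories=REFERENCE_GENOTYPES).codes.reshape(
            calls.shape
        )
    ).to_numpy()  # NC -> -1
    rows = np.arange(len(snps))[:, None]
    safe_g = np.where(gidx >= 0, gidx, 0)
    cell_mu = mu[rows, safe_g]
    cell_sigma = sigma[rows, safe_g]
    cell_ok = eligible[rows, safe_g] & (gidx >= 0) & ~np.isnan(lam)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(cell_ok, np.abs(lam - cell_mu) / cell_sigma, np.nan)
    frame = pd.DataFrame(q, index=snps, columns=shared)
    return SnpQiMatrix(
        annotation=af.annotation.loc[snps].reset_index(drop=True),
        q=frame,
        index_kind="genotype_based",
    )


def snp_qi_nearest(af: AlleleFrequencyMatrix, ref: AFReference) -> SnpQiMatrix:
    """Nearest-mean-based standardized distances.

    For each cell the genotype class G* minimizing |lambda - mu_G| over
    eligible reference cells is selected and q = |lambda - mu_G*| / sigma_G*.
    When two classes are equidistant in mean, the one yielding the smaller q
    (larger sigma) wins. SNPs with no eligible reference cell are missing.
    """
    snps = af.snp_ids
    mu, sigma, eligible = _aligned_reference(snps, ref)
    lam = af.af.to_numpy(dtype=float)
    q = nearest_mean_q(lam, mu, sigma, eligible)
    frame = pd.DataFrame(q, index=snps, columns=af.sample_ids)
    return SnpQiMatrix(
        annotation=af.annotation.reset_index(drop=True),
        q=frame,
        index_kind="nearest_mean",
    )


def nearest_mean_q(
    lam: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    eligible: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized nearest-mean distance kernel.

    ``lam`` is (M, N); ``mu``/``sigma`` are (M, G); returns (M, N) q values
    with NaN where no eligible class exists or lambda is missing.
    """
    lam = np.asarray(lam, dtype=float)
    if eligible is None:
        eligible = np.isfinite(mu) & np.isfinite(sigma) & (sigma > 0)
    mu_f = np.where(eligible, mu, np.nan)
    d = np.abs(lam[:, :, None] - mu_f[:, None, :])  # (M, N, G)
    with np.errstate(invalid="ignore", divide="ignore"):
        qcand = d / np.where(eligible, sigma, np.nan)[:, None, :]
    all_nan = np.all(np.isnan(d), axis=2)
    dmin = np.nanmin(np.where(all_nan[:, :, None], np.inf, d), axis=2)
    # among classes tied at the minimal |lambda - mu|, take the smallest q
    tied = d == dmin[:, :, None]
    qtied = np.where(tied, qcand, np.nan)
    q = np.nanmin(np.where(all_nan[:, :, None], np.inf, qtied), axis=2)
    return np.where(all_nan, np.nan, q)


# ---------------------------------------------------------------------------
# array-level summaries

def _scope_groups(annotation: pd.DataFrame) -> list[tuple[str, np.ndarray]]:
    chroms = annotation["chromosome"].to_numpy()
    groups: list[tuple[str, np.ndarray]] = []
    for c in pd.unique(chroms):
        groups.append((str(c), chroms == c))
    groups.append((GENOME_SCOPE, np.ones(len(annotation), dtype=bool)))
    return groups


def array_qi(
    snp_qi: SnpQiMatrix,
    rho: float = DEFAULT_RHO,
    summary_kind: str = "winsorized_mean",
    min_snps: int = DEFAULT_MIN_SNPS,
    array_label: str | None = None,
    scopes: str = "all",
) -> ArrayQiTable:
    """Summarize SNP-level distances into array-level indices Q_x(rho).

    Indices are computed per chromosome and for the genome-wide scope
    (``scopes='genome'`` restricts to the latter). Scopes with fewer than
    ``min_snps`` non-missing distances for a sample are skipped and recorded
    in ``skipped``.
    """
    if not 0 < rho < 1:
        raise InputError("rho must be in (0, 1)")
    if summary_kind not in SUMMARY_KINDS:
        raise InputError(f"unknown summary_kind {summary_kind!r}")
    if array_label is None:
        labels = snp_qi.annotation["array_label"].unique()
        array_label = labels[0] if len(labels) == 1 else "ALL"
    qvals = snp_qi.q.to_numpy(dtype=float)
    groups = _scope_groups(snp_qi.annotation)
    if scopes == "genome":
        groups = [g for g in groups if g[0] == GENOME_SCOPE]
    rows = []
    skipped: list[tuple[str, str]] = []
    for scope, mask in groups:
        sub = qvals[mask]
        for j, sample in enumerate(snp_qi.q.columns):
            col = sub[:, j]
            col = col[~np.isnan(col)]
            if col.size < min_snps:
                skipped.append((sample, scope))
                continue
            rows.append(
                {
                    "sample_id": sample,
                    "array_label": array_label,
                    "scope": scope,
                    "index_kind": snp_qi.index_kind,
                    "summary_kind": summary_kind,
                    "rho": rho,
                    "qi_value": summarize(col, rho, summary_kind),
                    "n_snps_used": int(col.size),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "array_label",
            "scope",
            "index_kind",
            "summary_kind",
            "rho",
            "qi_value",
            "n_snps_used",
        ],
    )
    meta = {
        "index_kind": snp_qi.index_kind,
        "summary_kind": summary_kind,
        "rho": rho,
        "quantile_rule": QUANTILE_RULE,
    }
    return ArrayQiTable(table=table, metadata=meta, skipped=skipped)


def merge_array_qi(
    snp_qi_parts: list[SnpQiMatrix],
    rho: float = DEFAULT_RHO,
    summary_kind: str = "winsorized_mean",
    min_snps: int = DEFAULT_MIN_SNPS,
    array_label: str = "Merge",
) -> ArrayQiTable:
    """Pool SNP-level distances of companion arrays, then summarize.

    Pooling happens at the SNP level (the merged index is computed on the
    union of SNPs), not by averaging part-level indices. Parts must share
    samples and have disjoint SNP sets.
    """
    if len(snp_qi_parts) < 2:
        raise InputError("need at least two parts to merge")
    kinds = {p.index_kind for p in snp_qi_parts}
    if len(kinds) > 1:
        raise InputError("cannot merge parts with different index kinds")
    samples = list(snp_qi_parts[0].q.columns)
    for p in snp_qi_parts[1:]:
        if list(p.q.columns) != samples:
            raise InputError("merged parts must share identical sample_ids")
    seen: set[str] = set()
    for p in snp_qi_parts:
        ids = set(p.q.index)
        overlap = seen & ids
        if overlap:
            raise InputError(f"snp_id {next(iter(overlap))!r} appears in multiple parts")
        seen |= ids
    pooled = SnpQiMatrix(
        annotation=pd.concat([p.annotation for p in snp_qi_parts], ignore_index=True),
        q=pd.concat([p.q for p in snp_qi_parts], axis=0),
        index_kind=snp_qi_parts[0].index_kind,
    )
    return array_qi(
        pooled,
        rho=rho,
        summary_kind=summary_kind,
        min_snps=min_snps,
        array_label=array_label,
        scopes="genome",
    )


def compute_gcr(genotypes: GenotypeMatrix) -> GcrTable:
    """Genotype call rate: fraction of calls != NC, per sample and scope."""
    if genotypes.calls.empty:
        raise InputError("empty genotype matrix")
    called = (genotypes.calls != "NC").to_numpy()
    rows = []
    for scope, mask in _scope_groups(genotypes.annotation):
        sub = called[mask]
        n_total = sub.shape[0]
        for j, sample in enumerate(genotypes.calls.columns):
            n_called = int(sub[:, j].sum())
            rows.append(
                {
                    "sample_id": sample,
                    "scope": scope,
                    "gcr": n_called / n_total,
                    "n_called": n_called,
                    "n_total": n_total,
                }
            )
    return GcrTable(table=pd.DataFrame(rows))
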