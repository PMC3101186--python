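"""Reference distributions and detection of poor-quality arrays.

Across large cohorts, array-level quality indices are well described by
lognormal distributions. This module fits that model (Gaussian fit on the
log scale), checks it with one-sample Kolmogorov-Smirnov tests, builds
quality-index references — the 95/97.5/99% upper confidence limits of the
reference QI distribution, taken either from empirical quantiles (default)
or from lognormal quantiles exp(meanlog + z * sdlog) — and flags arrays
whose QI strictly exceeds the selected limit. Group comparisons (e.g.,
across ethnic populations or laboratories) test equality of log-scale means
(two-sample Z), log-scale variances (F) and whole distributions (two-sample
KS).

The KS test is run with the fitted parameters plugged in ("plain" KS, no
Lilliefors-style correction), which is conservative when the parameters were
estimated from the same data; the conservativeness is documented rather than
corrected.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .quality_index import ArrayQiTable, QUANTILE_RULE, quantile

#: Confidence levels of the upper limits shipped in a QI reference.
DEFAULT_LEVELS: tuple[float, ...] = (0.95, 0.975, 0.99)

#: Minimum reference arrays per stratum for empirical limits.
DEFAULT_MIN_ARRAYS = 20

#: Columns identifying a reference stratum.
STRATUM_COLUMNS = (
    "population_label",
    "array_label",
    "scope",
    "index_kind",
    "summary_kind",
    "rho",
)


@dataclass
class LognormalFit:
    """Lognormal fit of quality indices: Gaussian parameters of log(QI)."""

    meanlog: float
    sdlog: float
    n: int
    ks_statistic: float
    ks_pvalue: float


@dataclass
class GroupComparison:
    """P-values comparing two QI samples: log-mean (Z), log-variance (F), KS."""

    p_mean: float
    p_var: float
    p_ks: float
    group_labels: tuple[str, str] = ("a", "b")


def _check_positive(values: np.ndarray, n_min: int = 10) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < n_min:
        raise InputError(f"need at least {n_min} values, got {x.size}")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise InputError("quality indices must be positive and finite")
    return x


def fit_lognormal(qi_values: np.ndarray) -> LognormalFit:
    """Fit a lognormal by the sample mean/SD of log values.

    Raises on nonpositive values and on (near-)constant input, for which the
    lognormal fit is degenerate.
    """
    x = _check_positive(qi_values)
    logs = np.log(x)
    meanlog = float(logs.mean())
    sdlog = float(logs.std(ddof=1))
    if sdlog <= 1e-12 * max(1.0, abs(meanlog)) or not np.isfinite(sdlog):
        raise InputError("degenerate lognormal fit: zero variance on the log scale")
    stat, pval = ks_lognormal(x, meanlog=meanlog, sdlog=sdlog)
    return LognormalFit(meanlog=meanlog, sdlog=sdlog, n=x.size, ks_statistic=stat, ks_pvalue=pval)


def ks_lognormal(
    qi_values: np.ndarray, fit: LognormalFit | None = None, *, meanlog: float | None = None, sdlog: float | None = None
) -> tuple[float, float]:
    """One-sample KS test of log(QI) against Normal(meanlog, sdlog).

    Parameters are treated as known (plain KS); the p-value comes from the
    standard asymptotic Kolmogorov distribution.
    """
    x = _check_positive(qi_values)
    if fit is not None:
        meanlog, sdlog = fit.meanlog, fit.sdlog
    if meanlog is None or sdlog is None:
        raise InputError("provide a LognormalFit or explicit meanlog/sdlog")
    if sdlog <= 0:
        raise InputError("sdlog must be positive")
    res = stats.kstest(np.log(x), "norm", args=(meanlog, sdlog), method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class QiReference:
    """Upper confidence limits of the reference QI distribution per stratum.

    ``table`` is long-format with the stratum columns, ``level``, ``limit``,
    ``mu_qi``/``sigma_qi`` (reference sample mean/SD of the QI, used for the
    heatmap level scale) and ``source`` (empirical or lognormal). Limits must
    be nondecreasing in level within a stratum.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = list(STRATUM_COLUMNS) + ["level", "limit", "mu_qi", "sigma_qi", "source"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise InputError(f"QI reference lacks column(s): {', '.join(missing)}")
        tab = self.table.reset_index(drop=True).copy()
        tab["level"] = tab["level"].astype(float)
        tab["limit"] = tab["limit"].astype(float)
        if (tab["limit"] <= 0).any():
            raise InputError("QI reference limits must be positive")
        for key, grp in tab.groupby(list(STRATUM_COLUMNS), dropna=False):
            ordered = grp.sort_values("level")["limit"].to_numpy()
            if np.any(np.diff(ordered) < 0):
                raise InputError(f"limits not nondecreasing in level for stratum {key}")
        self.table = tab
        self.metadata.setdefault("quantile_rule", QUANTILE_RULE)

    def limit_for(
        self,
        array_label: str,
        level: float,
        scope: str = "GENOME",
        index_kind: str | None = None,
        summary_kind: str | None = None,
        rho: float | None = None,
        population_label: str | None = None,
    ) -> float:
        tab = self.table
        mask = (tab["array_label"] == array_label) & (tab["scope"] == scope)
        if index_kind is not None:
            mask &= tab["index_kind"] == index_kind
        if summary_kind is not None:
            mask &= tab["summary_kind"] == summary_kind
        if rho is not None:
            mask &= np.isclose(tab["rho"].astype(float), rho)
        if population_label is not None:
            mask &= tab["population_label"] == population_label
        mask &= np.isclose(tab["level"], level)
        hits = tab.loc[mask]
        if hits.empty:
            raise InputError(
                f"no QI reference stratum for array {array_label!r}, scope {scope!r}, "
                f"level {level}"
            )
        return float(hits["limit"].iloc[0])


def build_qi_reference(
    qi_table: ArrayQiTable,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    source: str = "empirical",
    population_label: str = "",
    min_arrays: int = DEFAULT_MIN_ARRAYS,
) -> QiReference:
    """Build upper confidence limits from a reference cohort's QI table.

    Empirical limits are level-quantiles of the observed QIs under the
    shared quantile rule; lognormal limits are exp(meanlog + z_level *
    sdlog). Strata with fewer than ``min_arrays`` arrays are skipped with a
    warning record in the metadata.
    """
    if source not in ("empirical", "lognormal"):
        raise InputError(f"unknown limit source {source!r}")
    levels = tuple(sorted(float(l) for l in levels))
    if any(not 0 < l < 1 for l in levels):
        raise InputError("levels must lie in (0, 1)")
    rows = []
    skipped = []
    group_cols = ["array_label", "scope", "index_kind", "summary_kind", "rho"]
    for key, grp in qi_table.table.groupby(group_cols, dropna=False):
        values = grp["qi_value"].to_numpy(dtype=float)
        if source == "empirical" and values.size < min_arrays:
            skipped.append(dict(zip(group_cols, key)) | {"n": int(values.size)})
            continue
        mu_qi = float(values.mean())
        sigma_qi = float(values.std(ddof=1)) if values.size > 1 else 0.0
        if source == "lognormal":
            fit = fit_lognormal(values)
            limits = {l: float(np.exp(fit.meanlog + stats.norm.ppf(l) * fit.sdlog)) for l in levels}
        else:
            limits = {l: quantile(values, l) for l in levels}
        for l in levels:
            rows.append(
                {
                    "population_label": population_label,
                    "array_label": key[0],
                    "scope": key[1],
                    "index_kind": key[2],
                    "summary_kind": key[3],
                    "rho": key[4],
                    "level": l,
                    "limit": limits[l],
                    "mu_qi": mu_qi,
                    "sigma_qi": sigma_qi,
                    "source": source,
                    "n_arrays": int(values.size),
                }
            )
    if not rows:
        raise InputError("no stratum had enough reference arrays")
    meta = {"source": source, "quantile_rule": QUANTILE_RULE, "skipped": skipped}
    return QiReference(table=pd.DataFrame(rows), metadata=meta)


def detect_poor_arrays(
    qi_table: ArrayQiTable,
    ref: QiReference,
    level: float = 0.95,
    scope: str = "GENOME",
) -> pd.DataFrame:
    """Flag arrays whose QI strictly exceeds the stratum's upper limit.

    Returns one row per (sample_id, array_label) with columns ``qi``,
    ``limit``, ``level`` and boolean ``flag``. Merge-array rows are flagged
    against the Merge stratum like any other array label. A missing stratum
    raises an error naming it.
    """
    rows = []
    sub = qi_table.table[qi_table.table["scope"] == scope]
    if sub.empty:
        raise InputError(f"QI table has no rows for scope {scope!r}")
    for _, row in sub.iterrows():
        limit = ref.limit_for(
            array_label=row["array_label"],
            level=level,
            scope=scope,
            index_kind=row["index_kind"],
            summary_kind=row["summary_kind"],
            rho=float(row["rho"]),
        )
        qi = float(row["qi_value"])
        rows.append(
            {
                "sample_id": row["sample_id"],
                "array_label": row["array_label"],
                "qi": qi,
                "limit": limit,
                "level": level,
                "flag": qi > limit,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    qi_a: np.ndarray,
    qi_b: np.ndarray,
    group_labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Compare two QI samples on the log scale.

    p_mean: two-sample Z test with unpooled variances; p_var: F test of
    log-variance equality; p_ks: two-sample Kolmogorov-Smirnov. All
    two-sided.
    """
    a = np.log(_check_positive(qi_a))
    b = np.log(_check_positive(qi_b))
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se = np.sqrt(va / na + vb / nb)
    if se == 0:
        p_mean = 1.0
    else:
        z = (a.mean() - b.mean()) / se
        p_mean = float(2 * stats.norm.sf(abs(z)))
    if va == 0 or vb == 0:
        p_var = 1.0 if va == vb else 0.0
    else:
        f = va / vb
        cdf = stats.f.cdf(f, na - 1, nb - 1)
        p_var = float(2 * min(cdf, 1 - cdf))
    ks = stats.ks_2samp(a, b)
    return GroupComparison(
        p_mean=min(p_mean, 1.0),
        p_var=min(p_var, 1.0),
        p_ks=float(ks.pvalue),
        group_labels=group_labels,
    )
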