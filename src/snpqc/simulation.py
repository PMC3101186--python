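"""Generative model and detection-rate experiments for the QI detector.

The generator emulates one chromosome of a genotyping experiment:

1. Per SNP, an allele-A frequency p is drawn uniformly from a MAF range and
   genotype probabilities follow Hardy-Weinberg (p^2, 2p(1-p), (1-p)^2).
2. Per SNP, genotype counts over the N arrays are multinomial; counts are
   assigned to arrays by a uniformly random permutation.
3. Per cell, the individual-level AF is Beta-distributed with genotype-
   specific mean mu_G and total variance V_T = V_S / (1 - r), where V_S is
   the systematic variance of good-quality data and r = V_E / V_T is the
   relative extra error contributed by poor array/DNA quality (r = 0 means a
   clean experiment). Beta shape parameters come from moment matching.

The detection-rate experiment mirrors how the confidence-interval detector
is used: upper thresholds per level are the level-quantiles of array QIs
pooled over clean (r = 0) replications, using the generating (mu_G,
sqrt(V_S)) as the AF reference; then, for each r on a grid, arrays are
simulated, their QI computed, and the proportion flagged (QI strictly above
the threshold) recorded per replication. Means and SDs of that proportion
over replications form the detection-rate curve, which is S-shaped in r.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .af_reference import AFReference, REFERENCE_GENOTYPES
from .containers import AlleleFrequencyMatrix, GenotypeMatrix
from .errors import InputError
from .quality_index import (
    DEFAULT_RHO,
    QUANTILE_RULE,
    nearest_mean_q,
    quantile,
    summarize,
)

#: Default AF band parameters (mean, systematic variance) per genotype,
#: emulating CPA-adjusted three-band profiles of good-quality arrays:
#: homozygote bands pulled slightly off 0/1 by background signal, and a
#: common systematic variance V_S = 0.0015 (SD ~ 0.039).
DEFAULT_BAND_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (0.93, 0.0015),
    "AB": (0.50, 0.0015),
    "BB": (0.07, 0.0015),
}

DEFAULT_MAF_RANGE: tuple[float, float] = (0.05, 0.5)

_GENOTYPE_INDEX = {g: i for i, g in enumerate(REFERENCE_GENOTYPES)}


@dataclass
class SnpGenerativeParams:
    """Per-SNP generative parameters.

    ``genotype_probs`` is (M, 3) over (AA, AB, BB) summing to 1 per row;
    ``mu`` and ``v_systematic`` are (M, 3) with 0 < mu < 1 and
    0 < v_systematic < mu * (1 - mu).
    """

    genotype_probs: np.ndarray
    mu: np.ndarray
    v_systematic: np.ndarray
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotype_probs = np.asarray(self.genotype_probs, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.v_systematic = np.asarray(self.v_systematic, dtype=float)
        m = self.genotype_probs.shape[0]
        for name, arr in (
            ("genotype_probs", self.genotype_probs),
            ("mu", self.mu),
            ("v_systematic", self.v_systematic),
        ):
            if arr.shape != (m, 3):
                raise InputError(f"{name} must have shape (n_snps, 3)")
        if not np.allclose(self.genotype_probs.sum(axis=1), 1.0, atol=1e-9):
            raise InputError("genotype_probs rows must sum to 1")
        if np.any(self.genotype_probs < 0):
            raise InputError("genotype_probs must be nonnegative")
        if np.any((self.mu <= 0) | (self.mu >= 1)):
            raise InputError("mu must lie strictly inside (0, 1)")
        if np.any(self.v_systematic <= 0) or np.any(
            self.v_systematic >= self.mu * (1 - self.mu)
        ):
            raise InputError("v_systematic must satisfy 0 < v < mu * (1 - mu)")
        if not self.snp_ids:
            self.snp_ids = [f"SNP{i + 1:06d}" for i in range(m)]
        if len(self.snp_ids) != m:
            raise InputError("snp_ids length must match n_snps")

    @property
    def n_snps(self) -> int:
        return self.genotype_probs.shape[0]

    def annotation(self, chromosome: str = "19", array_label: str = "SIM") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chromosome": chromosome,
                "position_bp": np.arange(1, self.n_snps + 1, dtype=np.int64) * 1000,
                "array_label": array_label,
            }
        )

    def to_af_reference(
        self, population_label: str = "simulated", chromosome: str = "19", array_label: str = "SIM"
    ) -> AFReference:
        """The generating bands as an AF reference: mean mu_G, SD sqrt(V_S)."""
        ann = self.annotation(chromosome=chromosome, array_label=array_label)
        rows = []
        for g, col in _GENOTYPE_INDEX.items():
            rows.append(
                pd.DataFrame(
                    {
                        "snp_id": self.snp_ids,
                        "chromosome": ann["chromosome"],
                        "position_bp": ann["position_bp"],
                        "array_label": ann["array_label"],
                        "genotype": g,
                        "mean": self.mu[:, col],
                        "sd": np.sqrt(self.v_systematic[:, col]),
                        "n": np.iinfo(np.int32).max,
                        "eligible": True,
                    }
                )
            )
        table = pd.concat(rows, ignore_index=True)
        return AFReference(table=table, population_label=population_label)


@dataclass
class SimulationConfig:
    """Design of a detection-rate experiment.

    Defaults follow the chromosome-scale study design: N = 100 arrays,
    an r grid from 0 to 0.6 in steps of 0.025, 1,000 replications, the
    nearest-mean index with a winsorized mean at rho = 0.95, and limits at
    the 95/97.5/99% levels. ``n_snps`` is 690 (100K-scale chromosome) or
    6,396 (500K-scale).
    """

    n_arrays: int = 100
    n_snps: int = 690
    r_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.6001, 0.025), 4))
    n_replications: int = 1000
    null_replications: int | None = None
    rho: float = DEFAULT_RHO
    index_kind: str = "nearest_mean"
    summary_kind: str = "winsorized_mean"
    levels: tuple[float, ...] = (0.95, 0.975, 0.99)
    seed: int = 0
    threshold_mode: str = "global"

    def __post_init__(self) -> None:
        if self.n_arrays < 2:
            raise InputError("n_arrays must be >= 2")
        grid = tuple(float(r) for r in self.r_grid)
        if any(not 0 <= r < 1 for r in grid):
            raise InputError("every r must satisfy 0 <= r < 1")
        if list(grid) != sorted(grid):
            raise InputError("r_grid must be sorted ascending")
        if grid and grid[0] != 0.0:
            raise InputError("r_grid must start at 0 (needed for null thresholds)")
        self.r_grid = grid
        if self.index_kind not in ("genotype_based", "nearest_mean"):
            raise InputError(f"unknown index_kind {self.index_kind!r}")
        if self.threshold_mode not in ("global", "per_replication"):
            raise InputError(f"unknown threshold_mode {self.threshold_mode!r}")
        self.levels = tuple(sorted(float(l) for l in self.levels))

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Parse a key = value config file (``#`` comments allowed).

        Scalars are numbers; ``r_grid`` and ``levels`` accept comma lists or
        ``start:stop:step`` ranges.
        """
        kwargs: dict = {}
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise InputError(f"malformed config line {lineno}: {raw.strip()!r}")
                key, value = (part.strip() for part in line.split("=", 1))
                if key in ("r_grid", "levels"):
                    kwargs[key] = _parse_grid(value)
                elif key in ("n_arrays", "n_snps", "n_replications", "null_replications", "seed"):
                    kwargs[key] = int(value)
                elif key in ("rho",):
                    kwargs[key] = float(value)
                elif key in ("index_kind", "summary_kind", "threshold_mode"):
                    kwargs[key] = value
                else:
                    raise InputError(f"unknown config key {key!r} (line {lineno})")
        return cls(**kwargs)


def _parse_grid(value: str) -> tuple[float, ...]:
    value = value.strip()
    if ":" in value:
        parts = value.split(":")
        if len(parts) != 3:
            raise InputError(f"range syntax is start:stop:step, got {value!r}")
        start, stop, step = (float(p) for p in parts)
        return tuple(np.round(np.arange(start, stop + step / 2, step), 10))
    return tuple(float(p) for p in value.split(","))


@dataclass
class DetectionCurve:
    """Detection-rate summaries per (r, level), plus the thresholds used."""

    table: pd.DataFrame  # r, level, mean_rate, sd_rate, n_replications
    thresholds: dict[float, float]
    config: SimulationConfig

    def rates(self, level: float) -> pd.DataFrame:
        sub = self.table[np.isclose(self.table["level"], level)]
        return sub.sort_values("r").reset_index(drop=True)


# ---------------------------------------------------------------------------
# generative primitives

def beta_moment_params(mu: float, variance: float) -> tuple[float, float]:
    """Beta shape parameters matching a given mean and variance.

    With c = mu * (1 - mu) / variance - 1: alpha = mu * c, beta = (1 - mu) * c.
    A variance at or above the Bernoulli bound mu * (1 - mu) cannot be
    represented by a Beta and is clamped to 0.99 of the bound with a warning.
    """
    if not 0 < mu < 1:
        raise InputError("mu must lie strictly inside (0, 1)")
    if variance <= 0:
        raise InputError("variance must be positive")
    bound = mu * (1 - mu)
    if variance >= bound:
        warnings.warn(
            f"variance {variance:.6g} >= mu*(1-mu) = {bound:.6g}; clamped to 0.99*bound",
            RuntimeWarning,
            stacklevel=2,
        )
        variance = 0.99 * bound
    c = bound / variance - 1.0
    return mu * c, (1 - mu) * c


def _beta_moment_arrays(mu: np.ndarray, variance: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized moment matching; returns (alpha, beta, n_clamped)."""
    bound = mu * (1 - mu)
    clamped = variance >= bound
    v = np.where(clamped, 0.99 * bound, variance)
    c = bound / v - 1.0
    return mu * c, (1 - mu) * c, int(clamped.sum())


def synth_population(
    n_snps: int,
    maf_range: tuple[float, float] = DEFAULT_MAF_RANGE,
    band_params: dict[str, tuple[float, float]] | None = None,
    seed: int | np.random.Generator = 0,
    mu_jitter_sd: float = 0.01,
    v_jitter_sd: float = 0.1,
) -> SnpGenerativeParams:
    """Synthesize per-SNP generative parameters for one chromosome.

    Allele-A frequencies are Uniform(maf_range) and genotype probabilities
    follow Hardy-Weinberg. AF band means and systematic variances start from
    ``band_params`` (defaults: mu = 0.93/0.50/0.07, V_S = 0.0015) with small
    per-SNP jitter — additive Gaussian (sd ``mu_jitter_sd``) on the means,
    multiplicative lognormal (sdlog ``v_jitter_sd``) on the variances — so
    that SNPs are not identical, as in real hybridization data.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise InputError("maf_range must lie within (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bands = DEFAULT_BAND_PARAMS if band_params is None else band_params
    p = rng.uniform(lo, hi, size=n_snps)
    genotype_probs = np.column_stack([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    mu0 = np.array([bands[g][0] for g in REFERENCE_GENOTYPES])
    v0 = np.array([bands[g][1] for g in REFERENCE_GENOTYPES])
    mu = mu0[None, :] + rng.normal(0.0, mu_jitter_sd, size=(n_snps, 3))
    mu = np.clip(mu, 1e-3, 1 - 1e-3)
    v = v0[None, :] * np.exp(rng.normal(0.0, v_jitter_sd, size=(n_snps, 3)))
    v = np.minimum(v, 0.5 * mu * (1 - mu))
    return SnpGenerativeParams(genotype_probs=genotype_probs, mu=mu, v_systematic=v)


def total_variance(v_systematic: np.ndarray | float, r: float) -> np.ndarray | float:
    """Total AF variance V_T = V_S / (1 - r) implied by relative extra error r."""
    if not 0 <= r < 1:
        raise InputError("r must satisfy 0 <= r < 1")
    return v_systematic / (1.0 - r)


def _simulate_raw(
    params: SnpGenerativeParams,
    n_arrays: int,
    r: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Fast path: returns (genotype index (M, N), lambda (M, N), n_clamped)."""
    m = params.n_snps
    counts = rng.multinomial(n_arrays, params.genotype_probs)  # (M, 3)
    labels = np.repeat(
        np.tile(np.arange(3), m), counts.ravel()
    ).reshape(m, n_arrays)
    geno = rng.permuted(labels, axis=1)
    v_total = total_variance(params.v_systematic, r)
    alpha, beta, n_clamped = _beta_moment_arrays(params.mu, v_total)
    rows = np.arange(m)[:, None]
    lam = rng.beta(alpha[rows, geno], beta[rows, geno])
    return geno, lam, n_clamped


def simulate_arrays(
    params: SnpGenerativeParams,
    n_arrays: int,
    r: float,
    seed: int | np.random.Generator = 0,
    chromosome: str = "19",
    array_label: str = "SIM",
) -> tuple[GenotypeMatrix, AlleleFrequencyMatrix]:
    """Simulate genotype calls and individual-level AFs for ``n_arrays``.

    Genotype counts per SNP are multinomial and assigned to arrays by random
    permutation; AFs are Beta draws with mean mu_G and variance
    V_S / (1 - r). Variance clamping warnings (beta bound exceeded at
    extreme mu and large r) are propagated.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geno, lam, n_clamped = _simulate_raw(params, n_arrays, r, rng)
    if n_clamped:
        warnings.warn(
            f"{n_clamped} SNP/genotype cells exceeded the beta variance bound; clamped",
            RuntimeWarning,
            stacklevel=2,
        )
    ann = params.annotation(chromosome=chromosome, array_label=array_label)
    samples = [f"array{i + 1:03d}" for i in range(n_arrays)]
    codes = np.array(REFERENCE_GENOTYPES, dtype=object)
    calls = pd.DataFrame(codes[geno], index=params.snp_ids, columns=samples)
    af = pd.DataFrame(lam, index=params.snp_ids, columns=samples)
    genotypes = GenotypeMatrix(annotation=ann, calls=calls)
    afm = AlleleFrequencyMatrix(annotation=ann, af=af)
    return genotypes, afm


# ---------------------------------------------------------------------------
# detection-rate experiment

def replicate_array_qi(
    params: SnpGenerativeParams,
    config: SimulationConfig,
    r: float,
    rng: np.random.Generator,
    sigma_ref: np.ndarray,
) -> np.ndarray:
    """One replication: array-level QIs of the configured index/summary."""
    geno, lam, _ = _simulate_raw(params, config.n_arrays, r, rng)
    if config.index_kind == "nearest_mean":
        q = nearest_mean_q(lam, params.mu, sigma_ref)
    else:
        rows = np.arange(params.n_snps)[:, None]
        q = np.abs(lam - params.mu[rows, geno]) / sigma_ref[rows, geno]
    if config.summary_kind == "winsorized_mean":
        cap = np.quantile(q, config.rho, axis=0, method=QUANTILE_RULE)
        return np.minimum(q, cap[None, :]).mean(axis=0)
    if config.summary_kind == "median":
        return np.median(q, axis=0)
    if config.summary_kind == "trimmed_mean":
        cap = np.quantile(q, config.rho, axis=0, method=QUANTILE_RULE)
        keep = q <= cap[None, :]
        return (q * keep).sum(axis=0) / keep.sum(axis=0)
    raise InputError(f"unknown summary_kind {config.summary_kind!r}")


def null_thresholds(
    params: SnpGenerativeParams,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[float, float]:
    """Level-quantiles of array QIs pooled over clean (r = 0) replications."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sigma_ref = np.sqrt(params.v_systematic)
    n_rep = config.null_replications or config.n_replications
    pooled = np.concatenate(
        [replicate_array_qi(params, config, 0.0, rng, sigma_ref) for _ in range(n_rep)]
    )
    return {level: quantile(pooled, level) for level in config.levels}


def detection_rate_experiment(
    config: SimulationConfig,
    params: SnpGenerativeParams | None = None,
) -> DetectionCurve:
    """Run the full detection-rate experiment.

    Stage 1 derives the null thresholds (see :func:`null_thresholds`; with
    ``threshold_mode='per_replication'`` each replication instead derives
    its own threshold from a paired clean run). Stage 2 walks the r grid:
    per replication, ``n_arrays`` arrays are simulated, summarized, and the
    proportion with QI strictly above the threshold recorded. The returned
    curve holds the mean and SD of that proportion per (r, level).
    """
    if params is None:
        params = synth_population(config.n_snps, seed=np.random.default_rng(config.seed + 1))
    if params.n_snps != config.n_snps:
        config = replace(config, n_snps=params.n_snps)
    if 0.0 not in config.r_grid:
        raise InputError("r_grid must include 0")
    ss = np.random.SeedSequence(config.seed)
    null_rng, exp_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    sigma_ref = np.sqrt(params.v_systematic)
    thresholds: dict[float, float] = {}
    if config.threshold_mode == "global":
        thresholds = null_thresholds(params, config, null_rng)
    rows = []
    for r in config.r_grid:
        rates = {level: [] for level in config.levels}
        for _ in range(config.n_replications):
            if config.threshold_mode == "per_replication":
                null_qi = replicate_array_qi(params, config, 0.0, exp_rng, sigma_ref)
                thr = {level: quantile(null_qi, level) for level in config.levels}
            else:
                thr = thresholds
            qi = replicate_array_qi(params, config, r, exp_rng, sigma_ref)
            for level in config.levels:
                rates[level].append(float((qi > thr[level]).mean()))
        for level in config.levels:
            arr = np.asarray(rates[level])
            rows.append(
                {
                    "r": r,
                    "level": level,
                    "mean_rate": float(arr.mean()),
                    "sd_rate": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                    "n_replications": int(arr.size),
                }
            )
    table = pd.DataFrame(rows)
    return DetectionCurve(table=table, thresholds=thresholds, config=config)
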