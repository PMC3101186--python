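"""Diagnostic plots: AF profiles, QI heatmap, QI polygon, GCR chart.

All plot functions are deterministic given their inputs, render without a
display (figures are built directly on an Agg canvas, never through
pyplot's global state) and write exactly one file at ``spec.output_path``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.colors import LinearSegmentedColormap
from matplotlib.figure import Figure
from matplotlib.patches import Rectangle
from scipy.stats import gaussian_kde

from .allele_frequency import genotype_implied_af_matrix
from .containers import AlleleFrequencyMatrix, GenotypeMatrix
from .errors import InputError
from .qi_distribution import QiReference
from .quality_index import ArrayQiTable, GcrTable, GENOME_SCOPE

#: Dark-green-to-white ramp used by the QI heatmap.
_HEATMAP_CMAP = LinearSegmentedColormap.from_list("qi_green", ["#00441b", "#ffffff"])

#: Fixed KDE bandwidth (Scott factor multiplier) for the AF density curve.
_AF_KDE_BANDWIDTH = 0.05


@dataclass
class PlotSpec:
    """Where and how to render a plot."""

    output_path: str | Path
    format: str = "png"
    dpi: int = 150
    ncols: int = 4
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.format not in ("png", "pdf"):
            raise InputError(f"unsupported format {self.format!r}")
        if self.dpi < 72:
            raise InputError("dpi must be >= 72")


def _save(fig: Figure, spec: PlotSpec) -> Path:
    path = Path(spec.output_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    FigureCanvasAgg(fig)
    fig.savefig(path, format=spec.format, dpi=spec.dpi)
    return path


# ---------------------------------------------------------------------------
# AF plot

def af_figure(
    af: AlleleFrequencyMatrix,
    sample_id: str,
    kind: str = "intensity",
    genotypes: GenotypeMatrix | None = None,
    gap_table: pd.DataFrame | None = None,
    ncols: int = 4,
) -> Figure:
    """Build the per-chromosome AF scatter figure for one sample.

    One panel per chromosome: points at (position in Mb, lambda), the AF
    axis fixed to [0, 1], a smoothed AF density curve drawn along the right
    edge of each panel, and optional centromere gaps shaded when a
    ``gap_table`` (chromosome, gap_start_bp, gap_end_bp) is supplied.
    ``kind='genotype'`` plots genotype-implied AFs (1 / 0.5 / 0) instead.
    """
    if kind == "genotype":
        if genotypes is None:
            raise InputError("genotype-based AF plot needs a genotype matrix")
        af = genotype_implied_af_matrix(genotypes)
    if sample_id not in af.sample_ids:
        raise InputError(f"unknown sample {sample_id!r}")
    ann = af.annotation
    chroms = list(pd.unique(ann["chromosome"]))
    n = len(chroms)
    ncols = max(1, min(ncols, n))
    nrows = int(np.ceil(n / ncols))
    fig = Figure(figsize=(3.2 * ncols, 2.2 * nrows))
    values = af.af[sample_id]
    for i, chrom in enumerate(chroms):
        ax = fig.add_subplot(nrows, ncols, i + 1)
        mask = (ann["chromosome"] == chrom).to_numpy()
        pos_mb = ann.loc[mask, "position_bp"].to_numpy() / 1e6
        lam = values.to_numpy()[mask]
        ok = ~np.isnan(lam)
        ax.plot(pos_mb[ok], lam[ok], ".", ms=2, color="#1f4fa0", rasterized=True)
        finite = lam[ok]
        if finite.size > 3 and np.std(finite) > 0:
            grid = np.linspace(0, 1, 201)
            dens = gaussian_kde(finite, bw_method=_AF_KDE_BANDWIDTH)(grid)
            xmax = pos_mb.max() if pos_mb.size else 1.0
            span = max(xmax * 0.15, 1e-6)
            ax.plot(xmax + span * dens / dens.max(), grid, color="#e06ba0", lw=1)
        if gap_table is not None:
            gaps = gap_table[gap_table["chromosome"].astype(str) == str(chrom)]
            for _, g in gaps.iterrows():
                ax.axvspan(g["gap_start_bp"] / 1e6, g["gap_end_bp"] / 1e6, color="0.9")
        ax.set_ylim(0.0, 1.0)
        ax.set_title(f"chr {chrom}", fontsize=8)
        ax.tick_params(labelsize=6)
    fig.suptitle(f"{sample_id} — {'genotype' if kind == 'genotype' else 'intensity'}-based AF")
    fig.tight_layout()
    return fig


def plot_af(
    af: AlleleFrequencyMatrix,
    sample_id: str,
    spec: PlotSpec,
    kind: str = "intensity",
    genotypes: GenotypeMatrix | None = None,
    gap_table: pd.DataFrame | None = None,
) -> Path:
    fig = af_figure(
        af, sample_id, kind=kind, genotypes=genotypes, gap_table=gap_table, ncols=spec.ncols
    )
    return _save(fig, spec)


# ---------------------------------------------------------------------------
# QI heatmap

def qi_heatmap_figure(
    qi_table: ArrayQiTable,
    ref: QiReference,
    level: float = 0.95,
    scope: str = GENOME_SCOPE,
) -> Figure:
    """Samples x array-labels heatmap of QI values.

    The color for a cell with QI value Q under reference mean mu and SD
    sigma interpolates dark green -> white across the levels mu + k*sigma,
    k = 0..6, saturating at white above mu + 6*sigma. Cells whose QI
    strictly exceeds the stratum's upper limit carry a light-blue border
    overlay. The key lists the per-array limits.
    """
    sub = qi_table.table[qi_table.table["scope"] == scope]
    if sub.empty:
        raise InputError(f"QI table has no rows for scope {scope!r}")
    pivot = sub.pivot_table(index="sample_id", columns="array_label", values="qi_value", sort=False)
    samples = list(pivot.index)
    labels = list(pivot.columns)
    z = np.full(pivot.shape, np.nan)
    flagged = np.zeros(pivot.shape, dtype=bool)
    limits: dict[str, float] = {}
    meta = sub.iloc[0]
    for j, label in enumerate(labels):
        stratum = ref.table[
            (ref.table["array_label"] == label) & (ref.table["scope"] == scope)
        ]
        if stratum.empty:
            raise InputError(f"no QI reference stratum for array {label!r}, scope {scope!r}")
        mu = float(stratum["mu_qi"].iloc[0])
        sigma = float(stratum["sigma_qi"].iloc[0])
        limits[label] = ref.limit_for(
            label,
            level,
            scope=scope,
            index_kind=str(meta["index_kind"]),
            summary_kind=str(meta["summary_kind"]),
            rho=float(meta["rho"]),
        )
        col = pivot[label].to_numpy(dtype=float)
        z[:, j] = np.clip((col - mu) / sigma if sigma > 0 else np.inf, 0.0, 6.0)
        flagged[:, j] = col > limits[label]
    fig = Figure(figsize=(1.2 + 0.9 * len(labels), 1.0 + 0.32 * len(samples)))
    ax = fig.add_subplot(111)
    ax.imshow(z / 6.0, cmap=_HEATMAP_CMAP, vmin=0, vmax=1, aspect="auto")
    for i in range(len(samples)):
        for j in range(len(labels)):
            if flagged[i, j]:
                ax.add_patch(
                    Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False, edgecolor="#7fd4ff", lw=2.5)
                )
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, fontsize=8)
    ax.set_yticks(range(len(samples)))
    ax.set_yticklabels(samples, fontsize=7)
    key = ", ".join(f"{lab}: {lim:.3f}" for lab, lim in limits.items())
    ax.set_title(f"QI heatmap (levels mu..mu+6sigma); {level:.1%} limits {key}", fontsize=8)
    fig.tight_layout()
    return fig


def plot_qi_heatmap(
    qi_table: ArrayQiTable, ref: QiReference, spec: PlotSpec, level: float = 0.95
) -> Path:
    return _save(qi_heatmap_figure(qi_table, ref, level=level), spec)


# ---------------------------------------------------------------------------
# QI polygon (radar)

def qi_polygon_figure(
    qi_table: ArrayQiTable,
    ref: QiReference,
    sample_id: str,
    level: float = 0.95,
) -> Figure:
    """Radar chart: one vertex per chromosome at radius QI, reference circle
    at the selected per-chromosome (or genome) limit."""
    sub = qi_table.table[
        (qi_table.table["sample_id"] == sample_id)
        & (qi_table.table["scope"] != GENOME_SCOPE)
    ]
    if len(sub) < 3:
        raise InputError("polygon plot needs per-chromosome QIs for >= 3 chromosomes")
    scopes = list(sub["scope"])
    values = sub["qi_value"].to_numpy(dtype=float)
    meta = sub.iloc[0]
    radii = []
    for scope in scopes:
        try:
            radii.append(
                ref.limit_for(
                    str(meta["array_label"]),
                    level,
                    scope=scope,
                    index_kind=str(meta["index_kind"]),
                    summary_kind=str(meta["summary_kind"]),
                    rho=float(meta["rho"]),
                )
            )
        except InputError:
            radii.append(
                ref.limit_for(
                    str(meta["array_label"]),
                    level,
                    scope=GENOME_SCOPE,
                    index_kind=str(meta["index_kind"]),
                    summary_kind=str(meta["summary_kind"]),
                    rho=float(meta["rho"]),
                )
            )
    theta = np.linspace(0, 2 * np.pi, len(scopes), endpoint=False)
    fig = Figure(figsize=(5, 5))
    ax = fig.add_subplot(111, projection="polar")
    closed = np.append(theta, theta[0])
    ax.plot(closed, np.append(values, values[0]), "-o", ms=3, color="#1f4fa0")
    ax.plot(closed, np.append(radii, radii[0]), "--", color="#c03030", lw=1)
    ax.set_xticks(theta)
    ax.set_xticklabels([f"chr{s}" for s in scopes], fontsize=7)
    ax.set_title(f"{sample_id} QI polygon ({level:.1%} limit dashed)", fontsize=9)
    return fig


def plot_qi_polygon(
    qi_table: ArrayQiTable,
    ref: QiReference,
    sample_id: str,
    spec: PlotSpec,
    level: float = 0.95,
) -> Path:
    return _save(qi_polygon_figure(qi_table, ref, sample_id, level=level), spec)


# ---------------------------------------------------------------------------
# GCR plot

def gcr_figure(
    gcr: GcrTable, threshold: float | None = None, scope: str = GENOME_SCOPE
) -> Figure:
    """Per-sample genotype call rate chart with an optional threshold line."""
    sub = gcr.table[gcr.table["scope"] == scope]
    if sub.empty:
        raise InputError(f"GCR table has no rows for scope {scope!r}")
    fig = Figure(figsize=(max(4.0, 0.5 * len(sub)), 3.2))
    ax = fig.add_subplot(111)
    ax.bar(sub["sample_id"], sub["gcr"], color="#3a7d44")
    if threshold is not None:
        ax.axhline(threshold, color="#c03030", ls="--", lw=1)
    ax.set_ylim(0.0, 1.0)
    ax.set_ylabel("genotype call rate")
    ax.tick_params(axis="x", labelrotation=90, labelsize=7)
    fig.tight_layout()
    return fig


def plot_gcr(gcr: GcrTable, spec: PlotSpec, scope: str = GENOME_SCOPE) -> Path:
    return _save(gcr_figure(gcr, threshold=spec.threshold, scope=scope), spec)
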