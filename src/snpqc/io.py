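"""Plain-text (TSV) readers and writers for every snpqc artifact.

All formats are tab-separated UTF-8 with a single header line; missing
values are encoded as ``NA``. Metadata travels as leading comment lines of
the form ``# key=value``. Matrix files put the mandatory annotation columns
``snp_id, chromosome, position_bp, array_label`` first, sample columns
after; intensity files are long-format with one row per (SNP, sample).
Floats are written with 17 significant digits so write-then-read is the
identity at full stored precision.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .af_reference import AFReference, REFERENCE_GENOTYPES
from .allele_frequency import CpaTable
from .containers import (
    ANNOTATION_COLUMNS,
    AlleleFrequencyMatrix,
    GenotypeMatrix,
    IntensityMatrix,
    normalize_genotype_calls,
)
from .errors import FormatError
from .qi_distribution import QiReference
from .quality_index import ArrayQiTable, GcrTable

_FLOAT_FMT = "%.17g"
_NA = "NA"


# ---------------------------------------------------------------------------
# helpers

def _read_table(path, **kwargs) -> tuple[dict, pd.DataFrame]:
    """Read a TSV, splitting off leading ``# key=value`` metadata lines."""
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            skiprows=skip,
            na_values=[_NA],
            keep_default_na=False,
            float_precision="round_trip",
            **kwargs,
        )
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return meta, frame

def _write_table(frame: pd.DataFrame, path, metadata: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep=_NA, float_format=_FLOAT_FMT)
    return path

def _require_columns(frame: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")

def _split_annotation(frame: pd.DataFrame, path) -> tuple[pd.DataFrame, list[str]]:
    _require_columns(frame, ANNOTATION_COLUMNS, path)
    samples = [c for c in frame.columns if c not in ANNOTATION_COLUMNS]
    if not samples:
        raise FormatError(f"{path}: no sample columns after the annotation block")
    ann = frame.loc[:, list(ANNOTATION_COLUMNS)]
    if ann["snp_id"].duplicated().any():
        dup = ann.loc[ann["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise FormatError(f"{path}: duplicate snp_id {dup!r}")
    return ann, samples

def _wrap(exc_ok, builder, path):
    """Run a container constructor, re-raising its errors as FormatError."""
    try:
        return builder()
    except exc_ok as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# genotype and AF matrices (wide)

def write_genotype_matrix(matrix: GenotypeMatrix, path) -> Path:
    frame = pd.concat(
        [matrix.annotation.reset_index(drop=True), matrix.calls.reset_index(drop=True)], axis=1
    )
    return _write_table(frame, path)


def read_genotype_matrix(path) -> GenotypeMatrix:
    from .errors import InputError

    _, frame = _read_table(path, dtype=str)
    ann, samples = _split_annotation(frame, path)
    calls = frame.loc[:, samples].fillna(_NA)
    calls.index = pd.Index(ann["snp_id"].astype(str))
    calls = _wrap(InputError, lambda: normalize_genotype_calls(calls), path)
    return _wrap(InputError, lambda: GenotypeMatrix(annotation=ann, calls=calls), path)


def write_af_matrix(matrix: AlleleFrequencyMatrix, path) -> Path:
    frame = pd.concat(
        [matrix.annotation.reset_index(drop=True), matrix.af.reset_index(drop=True)], axis=1
    )
    return _write_table(frame, path)


def read_af_matrix(path) -> AlleleFrequencyMatrix:
    from .errors import InputError

    _, frame = _read_table(path)
    ann, samples = _split_annotation(frame, path)
    af = frame.loc[:, samples].astype(float)
    af.index = pd.Index(ann["snp_id"].astype(str))
    return _wrap(InputError, lambda: AlleleFrequencyMatrix(annotation=ann, af=af), path)


# ---------------------------------------------------------------------------
# intensities (long)

_INTENSITY_COLUMNS = list(ANNOTATION_COLUMNS) + ["sample_id", "intensity_a", "intensity_b"]


def write_intensity_matrix(matrix: IntensityMatrix, path) -> Path:
    ann = matrix.annotation.reset_index(drop=True)
    rows = []
    for sample in matrix.sample_ids:
        part = ann.copy()
        part["sample_id"] = sample
        part["intensity_a"] = matrix.intensity_a[sample].to_numpy()
        part["intensity_b"] = matrix.intensity_b[sample].to_numpy()
        rows.append(part)
    return _write_table(pd.concat(rows, ignore_index=True), path)


def read_intensity_matrix(path) -> IntensityMatrix:
    from .errors import InputError

    _, frame = _read_table(path)
    _require_columns(frame, _INTENSITY_COLUMNS, path)
    ann = (
        frame.loc[:, list(ANNOTATION_COLUMNS)]
        .drop_duplicates(subset="snp_id")
        .reset_index(drop=True)
    )
    conflicting = frame.loc[:, list(ANNOTATION_COLUMNS)].drop_duplicates()
    if conflicting["snp_id"].duplicated().any():
        dup = conflicting.loc[conflicting["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise FormatError(f"{path}: conflicting annotation for snp_id {dup!r}")
    if frame.duplicated(subset=["snp_id", "sample_id"]).any():
        dup = frame.loc[frame.duplicated(subset=["snp_id", "sample_id"]), "snp_id"].iloc[0]
        raise FormatError(f"{path}: duplicate (snp_id, sample_id) pair for {dup!r}")
    snp_order = ann["snp_id"].astype(str)
    ia = frame.pivot(index="snp_id", columns="sample_id", values="intensity_a")
    ib = frame.pivot(index="snp_id", columns="sample_id", values="intensity_b")
    ia = ia.reindex(snp_order)
    ib = ib.reindex(snp_order)
    ia.columns.name = ib.columns.name = None
    return _wrap(
        InputError,
        lambda: IntensityMatrix(annotation=ann, intensity_a=ia, intensity_b=ib),
        path,
    )


# ---------------------------------------------------------------------------
# AF reference

_AF_REF_COLUMNS = list(ANNOTATION_COLUMNS) + ["genotype", "mean", "sd", "n", "eligible"]


def write_af_reference(ref: AFReference, path) -> Path:
    meta = {
        "population_label": ref.population_label,
        "min_count": ref.min_count,
        "sd_floor": _FLOAT_FMT % ref.sd_floor,
    }
    cols = _AF_REF_COLUMNS
    return _write_table(ref.table.loc[:, cols], path, metadata=meta)


def read_af_reference(path) -> AFReference:
    from .errors import InputError

    meta, frame = _read_table(path)
    _require_columns(frame, _AF_REF_COLUMNS, path)
    bad_g = ~frame["genotype"].isin(REFERENCE_GENOTYPES)
    if bad_g.any():
        raise FormatError(
            f"{path}: invalid genotype {frame.loc[bad_g, 'genotype'].iloc[0]!r}"
        )
    frame = frame.copy()
    frame["eligible"] = frame["eligible"].astype(str).str.lower().isin(("true", "1"))
    return _wrap(
        InputError,
        lambda: AFReference(
            table=frame,
            population_label=meta.get("population_label", ""),
            min_count=int(meta.get("min_count", 3)),
            sd_floor=float(meta.get("sd_floor", 1e-4)),
        ),
        path,
    )


# ---------------------------------------------------------------------------
# CPA table

def write_cpa_table(cpa: CpaTable, path) -> Path:
    return _write_table(cpa.table, path, metadata={"min_het": cpa.min_het})


def read_cpa_table(path) -> CpaTable:
    from .errors import InputError

    meta, frame = _read_table(path)
    _require_columns(frame, ("snp_id", "kappa", "n_het", "fallback"), path)
    frame = frame.copy()
    frame["fallback"] = frame["fallback"].astype(str).str.lower().isin(("true", "1"))
    return _wrap(
        InputError,
        lambda: CpaTable(table=frame, min_het=int(meta.get("min_het", 3))),
        path,
    )


# ---------------------------------------------------------------------------
# QI tables, QI references, reports

_ARRAY_QI_COLUMNS = [
    "sample_id",
    "array_label",
    "scope",
    "index_kind",
    "summary_kind",
    "rho",
    "qi_value",
    "n_snps_used",
]


def write_array_qi_table(table: ArrayQiTable, path) -> Path:
    return _write_table(table.table.loc[:, _ARRAY_QI_COLUMNS], path, metadata=table.metadata)


def read_array_qi_table(path) -> ArrayQiTable:
    meta, frame = _read_table(path)
    _require_columns(frame, _ARRAY_QI_COLUMNS, path)
    return ArrayQiTable(table=frame, metadata=meta)


def write_qi_reference(ref: QiReference, path) -> Path:
    meta = {k: v for k, v in ref.metadata.items() if not isinstance(v, (list, dict))}
    return _write_table(ref.table, path, metadata=meta)


def read_qi_reference(path) -> QiReference:
    from .errors import InputError

    meta, frame = _read_table(path)
    return _wrap(InputError, lambda: QiReference(table=frame, metadata=meta), path)


def write_gcr_table(gcr: GcrTable, path) -> Path:
    return _write_table(gcr.table, path)


def write_detection_report(report: pd.DataFrame, path, metadata: dict | None = None) -> Path:
    return _write_table(report, path, metadata=metadata)


def write_detection_curve(curve, path) -> Path:
    cfg = curve.config
    meta = {
        "n_arrays": cfg.n_arrays,
        "n_snps": cfg.n_snps,
        "n_replications": cfg.n_replications,
        "rho": _FLOAT_FMT % cfg.rho,
        "index_kind": cfg.index_kind,
        "summary_kind": cfg.summary_kind,
        "threshold_mode": cfg.threshold_mode,
        "seed": cfg.seed,
    }
    for level, thr in curve.thresholds.items():
        meta[f"threshold_{level:g}"] = _FLOAT_FMT % thr
    return _write_table(curve.table, path, metadata=meta)
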