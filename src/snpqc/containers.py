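"""In-memory containers for SNP-array genotype, intensity and AF matrices.

All matrices are SNP x sample: rows are indexed by ``snp_id`` (matching an
annotation table carrying chromosome, physical position and array label),
columns by sample identifier. Genotype calls use the canonical codes
``AA``/``AB``/``BB``/``NC`` (no-call); common vendor synonyms such as
``NoCall`` are normalised at parse time. Individual-level allele frequencies
(AFs) live in [0, 1] with NaN marking missing cells.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

#: Chromosome labels accepted in annotation tables (autosomes plus X).
VALID_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)

#: Canonical genotype codes. ``NC`` is the missing-call state.
GENOTYPE_CODES: tuple[str, ...] = ("AA", "AB", "BB", "NC")

#: Mapping of common synonyms (upper-cased) to canonical genotype codes.
GENOTYPE_SYNONYMS: dict[str, str] = {
    "AA": "AA",
    "AB": "AB",
    "BA": "AB",
    "BB": "BB",
    "NC": "NC",
    "NOCALL": "NC",
    "NO CALL": "NC",
    "NN": "NC",
    "--": "NC",
    "NA": "NC",
    "./.": "NC",
}

#: Mandatory leading columns of every annotation table, in order.
ANNOTATION_COLUMNS: tuple[str, ...] = (
    "snp_id",
    "chromosome",
    "position_bp",
    "array_label",
)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a SNP annotation table.

    Returns a copy indexed by ``snp_id`` with string chromosomes and integer
    1-based positions. Raises :class:`InputError` on duplicate SNP ids,
    unknown chromosomes or non-positive positions.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise InputError(f"annotation lacks mandatory column(s): {', '.join(missing)}")
    ann = annotation.loc[:, list(ANNOTATION_COLUMNS)].copy()
    ann["snp_id"] = ann["snp_id"].astype(str)
    dup = ann["snp_id"][ann["snp_id"].duplicated()]
    if len(dup):
        raise InputError(f"duplicate snp_id in annotation: {dup.iloc[0]!r}")
    ann["chromosome"] = ann["chromosome"].astype(str)
    bad_chrom = ~ann["chromosome"].isin(VALID_CHROMOSOMES)
    if bad_chrom.any():
        offender = ann.loc[bad_chrom, "snp_id"].iloc[0]
        raise InputError(f"invalid chromosome for SNP {offender!r}")
    ann["position_bp"] = pd.to_numeric(ann["position_bp"], errors="raise").astype(np.int64)
    if (ann["position_bp"] < 1).any():
        offender = ann.loc[ann["position_bp"] < 1, "snp_id"].iloc[0]
        raise InputError(f"position_bp must be >= 1 (SNP {offender!r})")
    ann["array_label"] = ann["array_label"].astype(str)
    return ann.set_index("snp_id", drop=False)


def normalize_genotype_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Map genotype synonyms to canonical codes, erroring on unknown codes."""
    values = calls.to_numpy(dtype=object)
    mapping: dict[object, str] = {}
    for raw in pd.unique(values.ravel()):
        code = GENOTYPE_SYNONYMS.get(str(raw).strip().upper())
        if code is None:
            bad = values == raw
            i, j = np.argwhere(bad)[0]
            raise InputError(
                f"unknown genotype code {raw!r} at SNP {calls.index[i]!r}, "
                f"sample {calls.columns[j]!r}"
            )
        mapping[raw] = code
    out = np.vectorize(mapping.__getitem__, otypes=[object])(values)
    return pd.DataFrame(out, index=calls.index, columns=calls.columns)


def _check_alignment(annotation: pd.DataFrame, data: pd.DataFrame, what: str) -> None:
    if len(annotation) != len(data) or not (annotation.index == data.index).all():
        raise InputError(f"{what} rows do not match the annotation snp_ids")
    if data.columns.duplicated().any():
        raise InputError(f"duplicate sample_id in {what}")


@dataclass
class GenotypeMatrix:
    """Genotype calls G for every (SNP, sample) cell.

    ``calls`` holds one of ``AA``/``AB``/``BB``/``NC`` per cell; ``NC`` is the
    missing-call state used by the genotype call rate and skipped by the
    genotype-based quality index.
    """

    annotation: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        self.annotation = validate_annotation(self.annotation.reset_index(drop=True))
        _check_alignment(self.annotation, self.calls, "genotype matrix")
        bad = ~self.calls.isin(GENOTYPE_CODES)
        if bad.to_numpy().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise InputError(
                f"invalid genotype code at SNP {self.calls.index[i]!r}, "
                f"sample {self.calls.columns[j]!r}"
            )

    @property
    def snp_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return self.annotation.equals(other.annotation) and self.calls.equals(other.calls)


@dataclass
class AlleleFrequencyMatrix:
    """Individual-level allele frequencies lambda for every (SNP, sample) cell.

    Values are within-individual relative abundances of allele A, in [0, 1];
    NaN marks cells where the AF could not be estimated.
    """

    annotation: pd.DataFrame
    af: pd.DataFrame

    def __post_init__(self) -> None:
        self.annotation = validate_annotation(self.annotation.reset_index(drop=True))
        _check_alignment(self.annotation, self.af, "AF matrix")
        self.af = self.af.astype(float)
        vals = self.af.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 1)
        if np.nansum(bad):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise InputError(
                f"AF outside [0, 1] at SNP {self.af.index[i]!r}, "
                f"sample {self.af.columns[j]!r}"
            )

    @property
    def snp_ids(self) -> pd.Index:
        return self.af.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.af.columns)

    def equals(self, other: "AlleleFrequencyMatrix") -> bool:
        eq_af = self.af.shape == other.af.shape and np.allclose(
            self.af.to_numpy(), other.af.to_numpy(), rtol=0, atol=0, equal_nan=True
        )
        return self.annotation.equals(other.annotation) and bool(eq_af)


@dataclass
class IntensityMatrix:
    """Allele-A / allele-B hybridization intensities per (SNP, sample) cell.

    Intensities are nonnegative; a cell is usable when at least one of the
    pair is positive. NaN in both channels marks a missing pair.
    """

    annotation: pd.DataFrame
    intensity_a: pd.DataFrame
    intensity_b: pd.DataFrame

    def __post_init__(self) -> None:
        self.annotation = validate_annotation(self.annotation.reset_index(drop=True))
        _check_alignment(self.annotation, self.intensity_a, "intensity matrix (A)")
        _check_alignment(self.annotation, self.intensity_b, "intensity matrix (B)")
        if list(self.intensity_a.columns) != list(self.intensity_b.columns):
            raise InputError("intensity A and B channels have different samples")
        self.intensity_a = self.intensity_a.astype(float)
        self.intensity_b = self.intensity_b.astype(float)
        for name, frame in (("A", self.intensity_a), ("B", self.intensity_b)):
            vals = frame.to_numpy()
            with np.errstate(invalid="ignore"):
                bad = vals < 0
            if np.nansum(bad):
                i, j = np.argwhere(bad & ~np.isnan(vals))[0]
                raise InputError(
                    f"negative {name} intensity at SNP {frame.index[i]!r}, "
                    f"sample {frame.columns[j]!r}"
                )

    @property
    def snp_ids(self) -> pd.Index:
        return self.intensity_a.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensity_a.columns)
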