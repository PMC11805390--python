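"""Volumetric and tabular I/O shared by every pipeline stage.

Volumes and masks travel as :class:`Volume3D` / :class:`BinaryMask3D`,
thin wrappers around a numpy array plus a NIfTI-style affine; cohort
tables travel as pandas DataFrames validated against the exam-record
schema (one row per exam: patient, time point, covariates, PVS
measurements).

Conventions: voxel indices are 0-based; the physical volume of a voxel
is the product of the spacings in mm^3; PVS volumes are reported in
cm^3 (voxel count x voxel volume / 1000) and PVS ratios in permil of
the white-matter volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

TP_LEVELS = ("0M", "3M", "12M", "FollowUp")
SEX_LEVELS = ("F", "M")
DOSE_LEVELS = ("RD", "SD", "HD")
YESNO_LEVELS = ("no", "yes")

#: canonical column order for cohort tables
COHORT_COLUMNS = (
    "patient_id",
    "tp",
    "age_years",
    "sex",
    "dose",
    "anesthesia",
    "shunt",
    "pvs_ratio_permil",
    "pvs_volume_cm3",
)


class GridMismatchError(ValueError):
    """Raised when a volume and a mask do not share shape and spacing."""


@dataclass
class Volume3D:
    """A scalar 3D image with voxel spacing and orientation.

    Parameters
    ----------
    data
        3D array of finite scalars.
    affine
        4x4 voxel-to-world affine (NIfTI convention). Spacing is the
        column norm of the rotation/zoom block.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains NaN or Inf values")
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError(
                f"voxel spacing must be strictly positive, got {self.voxel_size_mm}"
            )

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @classmethod
    def from_spacing(cls, data: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> "Volume3D":
        aff = np.diag(list(voxel_size_mm) + [1.0])
        return cls(np.asarray(data), aff)


@dataclass
class BinaryMask3D:
    """A boolean 3D volume sharing a grid with its companion Volume3D."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3D mask, got {self.data.ndim} dimensions"
            )
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @classmethod
    def from_spacing(cls, data, voxel_size_mm=(1.0, 1.0, 1.0)) -> "BinaryMask3D":
        aff = np.diag(list(voxel_size_mm) + [1.0])
        return cls(np.asarray(data), aff)


def check_same_grid(a, b) -> None:
    """Assert two volumes/masks share shape and spacing (required before
    any operation that combines them)."""
    if a.data.shape != b.data.shape:
        raise GridMismatchError(
            f"shape mismatch: {a.data.shape} vs {b.data.shape}"
        )
    if not np.allclose(a.voxel_size_mm, b.voxel_size_mm, rtol=1e-6):
        raise GridMismatchError(
            f"spacing mismatch: {a.voxel_size_mm} vs {b.voxel_size_mm}"
        )


# ---------------------------------------------------------------------------
# volume I/O (NIfTI-1)
# ---------------------------------------------------------------------------

def read_volume(path) -> Volume3D:
    """Read a NIfTI volume. Rejects non-3D images and non-finite data."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D image, got shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(
            f"{path}: header field 'pixdim' has non-positive spacing {zooms}"
        )
    return Volume3D(np.asarray(data, dtype=np.float64), np.asarray(img.affine))


def write_volume(volume: Volume3D, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), volume.affine)
    nib.save(img, str(path))
    return path


def read_mask(path) -> BinaryMask3D:
    vol = read_volume(path)
    return BinaryMask3D(vol.data > 0.5, vol.affine)


def write_mask(mask: BinaryMask3D, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

@dataclass
class ExamRecord:
    """One MRI exam: identifiers, covariates and (optionally) measured PVS."""

    patient_id: str
    tp: str
    age_years: float
    sex: str
    dose: str
    anesthesia: str
    shunt: str
    pvs_ratio_permil: float | None = None
    pvs_volume_cm3: float | None = None

    def __post_init__(self) -> None:
        self.patient_id = str(self.patient_id)
        if self.tp not in TP_LEVELS:
            raise ValueError(f"unknown time point {self.tp!r}; expected one of {TP_LEVELS}")
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {SEX_LEVELS}")
        if self.dose not in DOSE_LEVELS:
            raise ValueError(f"unknown dose {self.dose!r}; expected one of {DOSE_LEVELS}")
        if self.anesthesia not in YESNO_LEVELS:
            raise ValueError(f"unknown anesthesia flag {self.anesthesia!r}")
        if self.shunt not in YESNO_LEVELS:
            raise ValueError(f"unknown shunt flag {self.shunt!r}")
        if not (float(self.age_years) > 0):
            raise ValueError(f"age must be positive, got {self.age_years}")


def records_to_frame(records: Iterable[ExamRecord]) -> pd.DataFrame:
    rows = [
        {c: getattr(r, c) for c in COHORT_COLUMNS}
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return df


def validate_cohort_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against the exam-record schema.

    Enforces: known categorical levels, positive ages, at most one row
    per (patient, time point). Missing pvs_* values are allowed (tables
    may predate quantification). Returns the frame in canonical column
    order with string categoricals.
    """
    missing = [c for c in COHORT_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("cohort table is empty")
    df = df.copy()
    for col in ("pvs_ratio_permil", "pvs_volume_cm3"):
        if col not in df.columns:
            df[col] = np.nan
    df["patient_id"] = df["patient_id"].astype(str)
    for col, levels in (
        ("tp", TP_LEVELS),
        ("sex", SEX_LEVELS),
        ("dose", DOSE_LEVELS),
        ("anesthesia", YESNO_LEVELS),
        ("shunt", YESNO_LEVELS),
    ):
        vals = df[col].astype(str)
        bad = ~vals.isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"column {col!r}: unknown level {vals.iloc[row]!r} at row {row}"
            )
        df[col] = vals
    df["age_years"] = pd.to_numeric(df["age_years"])
    if (df["age_years"] <= 0).any():
        raise ValueError("age_years must be positive in every row")
    dup = df.duplicated(subset=["patient_id", "tp"], keep=False)
    if dup.any():
        offenders = (
            df.loc[dup, ["patient_id", "tp"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        pairs = ", ".join(f"({p}, {t})" for p, t in offenders)
        raise ValueError(f"duplicate (patient_id, tp) rows: {pairs}")
    return df[list(COHORT_COLUMNS)]


def read_cohort_table(
    path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a cohort table from CSV or XLSX.

    ``column_map`` maps file column names to canonical names
    (``patient_id, tp, age_years, sex, dose, anesthesia, shunt,
    pvs_ratio_permil, pvs_volume_cm3``) for files whose headers differ.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if len(df) == 0:
        raise ValueError(f"{path}: cohort table is empty")
    return validate_cohort_frame(df)


def write_cohort_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
    return path


def frame_to_records(df: pd.DataFrame) -> list[ExamRecord]:
    df = validate_cohort_frame(df)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for col in ("pvs_ratio_permil", "pvs_volume_cm3"):
            if pd.isna(d[col]):
                d[col] = None
        out.append(ExamRecord(**d))
    return out
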