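"""Reading and writing of image volumes, ROI masks, feature tables and scoring models.

All modalities are assumed co-registered on a single voxel grid; world
coordinates are ignored and voxel indices are 0-based.  Volumes and masks
travel as NIfTI-1, feature tables as UTF-8 CSV with '.' decimals, and
scoring models as versioned JSON.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .scoring import ScoringModel

logger = logging.getLogger(__name__)

#: columns of a feature table that are not imaging features
METADATA_COLUMNS = ("cohort", "label", "age", "sex", "enhancement", "who_grade")

MODALITIES = ("FDG", "MET", "MRI")


class VolumeDimensionError(ValueError):
    """Raised when a NIfTI payload is not a 3D volume."""


class VolumeFormatError(ValueError):
    """Raised when a file cannot be parsed as NIfTI-1."""


class FeatureTableError(ValueError):
    """Raised for malformed feature-table CSV files."""


@dataclass
class ImageVolume:
    """A single modality's 3D intensity grid.

    Parameters
    ----------
    voxels : ndarray
        3D array of finite intensities.
    spacing_mm : tuple of float
        Voxel edge lengths per axis, all positive.
    modality : str
        One of ``FDG``, ``MET``, ``MRI``.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: str = "FDG"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise VolumeDimensionError(
                f"expected a 3D volume, got {self.voxels.ndim}D"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxel values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class RoiMask:
    """Binary region-of-interest mask on the same grid as its volume."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise VolumeDimensionError(
                f"expected a 3D mask, got {self.voxels.ndim}D"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeDimensionError(
            f"{path}: expected a 3D payload, got {data.ndim}D with shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    return np.asarray(data), tuple(float(z) for z in zooms)


def read_volume(path: str | Path, modality: str = "FDG") -> ImageVolume:
    """Read a 3D NIfTI-1 volume; spacing is taken from the header zooms."""
    data, spacing = _load_nifti(path)
    return ImageVolume(voxels=data.astype(float), spacing_mm=spacing, modality=modality)


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> RoiMask:
    """Read a binary mask; nonzero values are coerced to 1 with a warning."""
    data, spacing = _load_nifti(path)
    unique = np.unique(data)
    if not np.all(np.isin(unique, (0, 1))):
        logger.warning("mask %s has values outside {0,1}; coercing nonzero to 1", path)
    return RoiMask(voxels=data != 0, spacing_mm=spacing)


def write_mask(mask: RoiMask, path: str | Path) -> None:
    affine = np.diag(list(mask.spacing_mm) + [1.0])
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def validate_feature_table(
    table: pd.DataFrame, require_label: bool = False, allow_missing: bool = True
) -> None:
    """Check the structural invariants of a feature table.

    Feature columns (anything outside ``METADATA_COLUMNS``) must be numeric;
    the ``label`` column, when present, must be binary 0/1.  Missing values
    are tolerated by default (extraction flags unattainable direction/offset
    combinations as NaN; the selection stage drops such columns) and
    rejected with ``allow_missing=False``.
    """
    dup = table.columns[table.columns.duplicated()]
    if len(dup):
        raise FeatureTableError(f"duplicate column name(s): {sorted(set(dup))}")
    if require_label and "label" not in table.columns:
        raise FeatureTableError("required column 'label' is missing")
    feature_cols = [c for c in table.columns if c not in METADATA_COLUMNS]
    for col in feature_cols:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = values.index[values.isna() & table[col].notna()]
        if len(bad):
            raise FeatureTableError(
                f"non-numeric value in column '{col}' at row '{bad[0]}'"
            )
        if not allow_missing and values.isna().any():
            row = values.index[values.isna()][0]
            raise FeatureTableError(f"missing value in column '{col}' at row '{row}'")
    if "label" in table.columns:
        labels = set(pd.unique(table["label"].astype(int)))
        if not labels <= {0, 1}:
            raise FeatureTableError(f"label must be binary 0/1, found {sorted(labels)}")


def read_feature_table(path: str | Path, require_label: bool = False) -> pd.DataFrame:
    """Read a patients x features CSV, first column = patient id index."""
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    names = header[1:]
    seen, dups = set(), []
    for name in names:
        if name in seen:
            dups.append(name)
        seen.add(name)
    if dups:
        raise FeatureTableError(f"duplicate column name(s): {sorted(set(dups))}")
    # round_trip parsing: the default fast float parser can be off by one
    # ulp, which would break bit-exact stage resume
    table = pd.read_csv(path, index_col=0, float_precision="round_trip")
    validate_feature_table(table, require_label=require_label)
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_feature_table(table)
    table.to_csv(path, index_label=table.index.name or "id")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the imaging-feature columns of a table (metadata excluded)."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


# ---------------------------------------------------------------------------
# scoring-model persistence
# ---------------------------------------------------------------------------

def save_model(model: ScoringModel, path: str | Path) -> None:
    """Serialize a scoring model to versioned JSON (decimal-text exact)."""
    Path(path).write_text(model.to_json(), encoding="utf-8")


def load_model(path: str | Path) -> ScoringModel:
    return ScoringModel.from_json(Path(path).read_text(encoding="utf-8"))
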