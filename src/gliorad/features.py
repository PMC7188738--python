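"""Texture, shape, and PET-uptake feature extraction from masked volumes.

Gray-level co-occurrence (GLCM) and run-length (GLRLM) statistics are
computed in-plane, per axial slice, and pooled over slices: the four
directions 0/45/90/135 degrees are the classical 2D angles, ``offset`` is
the in-plane displacement (GLCM) or run-sampling stride (GLRLM) in voxels,
and ``AllDirection``/``AllDirection_SD`` denote the mean and population SD
of a feature over the four angles at fixed offset.  First-order statistics
are computed on the raw masked intensities, sphericity on the mask
geometry, and tumor-to-background ratios on PET volumes against an
explicit background-reference mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from skimage.measure import marching_cubes, mesh_surface_area

from .io import ImageVolume, RoiMask

logger = logging.getLogger(__name__)

ANGLES = (0, 45, 90, 135)
DEFAULT_OFFSETS = (1, 4, 7)

#: in-plane (row, col) unit steps for each angle
_ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_FEATURES = (
    "GLCMEnergy",
    "Inertia",
    "Correlation",
    "HaralickCorrelation",
    "ClusterShade",
    "ClusterProminence",
    "InverseDifferenceMoment",
)
GLRLM_FEATURES = (
    "ShortRunEmphasis",
    "LongRunHighGreyLevelEmphasis",
    "ShortRunLowGreyLevelEmphasis",
    "ShortRunHighGreyLevelEmphasis",
)


class EmptyMaskError(ValueError):
    """Raised when an operation requires a non-empty ROI mask."""


class EmptyGlcmError(ValueError):
    """Raised when no voxel pair exists at a direction/offset."""


@dataclass
class QuantizedRoi:
    """Gray-level quantized ROI.

    ``levels`` holds an integer level in 1..n_levels at masked voxels and
    the sentinel 0 elsewhere; the sentinel is excluded from every statistic.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass
class GlcMatrix:
    """Symmetric, normalized gray-level co-occurrence matrix."""

    p: np.ndarray
    direction: int
    offset: int


@dataclass
class GlrlMatrix:
    """Gray-level run-length count matrix (levels x run length)."""

    r: np.ndarray
    direction: int
    offset: int

    @property
    def n_runs(self) -> int:
        return int(self.r.sum())


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def quantize_roi(
    volume: ImageVolume, mask: RoiMask, n_levels: int = 64
) -> QuantizedRoi:
    """Min-max equal-width quantization of the masked voxels into 1..n_levels.

    A constant ROI maps every voxel to level 1.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    m = mask.voxels
    if not m.any():
        raise EmptyMaskError("cannot quantize an empty mask")
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    vals = volume.voxels[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        levels[m] = 1
    else:
        q = np.floor((vals - lo) / (hi - lo) * n_levels).astype(np.int32) + 1
        levels[m] = np.minimum(q, n_levels)
    return QuantizedRoi(
        levels=levels, mask=m, n_levels=n_levels, spacing_mm=volume.spacing_mm
    )


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------

def first_order_features(values: np.ndarray) -> dict[str, float]:
    """First-order statistics of the raw masked intensities.

    ``Quantile0.025`` uses linear interpolation; ``stdDeviation`` is the
    population SD; ``RelativeDeviation`` is mean(|x - mean|)/|mean| and is
    undefined (NaN, with a warning) when the mean is zero.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise EmptyMaskError("no voxels supplied")
    mean = float(x.mean())
    out = {
        "Quantile0.025": float(np.percentile(x, 2.5)),
        "RMS": float(np.sqrt(np.mean(x**2))),
        "stdDeviation": float(x.std(ddof=0)),
    }
    if x.std(ddof=0) == 0.0:
        out["RelativeDeviation"] = 0.0
    elif mean == 0.0:
        logger.warning("RelativeDeviation undefined for zero-mean ROI; flagged NaN")
        out["RelativeDeviation"] = float("nan")
    else:
        out["RelativeDeviation"] = float(np.mean(np.abs(x - mean)) / abs(mean))
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _shifted_pairs(a: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    """Views of ``a`` giving all in-plane voxel pairs displaced by (dr, dc)."""
    nr, nc = a.shape[0], a.shape[1]
    if abs(dr) >= nr or abs(dc) >= nc:
        empty = a[:0, :0]
        return empty, empty
    r0a, r0b = max(0, -dr), max(0, dr)
    c0a, c0b = max(0, -dc), max(0, dc)
    h, w = nr - abs(dr), nc - abs(dc)
    return (
        a[r0a : r0a + h, c0a : c0a + w],
        a[r0b : r0b + h, c0b : c0b + w],
    )


def compute_glcm(roi: QuantizedRoi, direction: int, offset: int) -> GlcMatrix:
    """Pooled in-plane co-occurrence matrix at one angle/offset.

    Pairs with both voxels inside the mask are counted within each axial
    slice, symmetrized (each pair in both orders), and normalized to sum 1.
    """
    if offset < 1:
        raise ValueError(f"offset must be >= 1, got {offset}")
    if direction not in _ANGLE_STEPS:
        raise ValueError(f"direction must be one of {ANGLES}, got {direction}")
    dr, dc = (s * offset for s in _ANGLE_STEPS[direction])
    ng = roi.n_levels
    a, b = _shifted_pairs(roi.levels, dr, dc)
    counts = np.zeros(ng * ng, dtype=np.int64)
    if a.size:
        valid = (a > 0) & (b > 0)
        if valid.any():
            ia, ib = a[valid].astype(np.int64) - 1, b[valid].astype(np.int64) - 1
            counts = np.bincount(ia * ng + ib, minlength=ng * ng)
    c = counts.reshape(ng, ng)
    c = c + c.T
    total = c.sum()
    if total == 0:
        raise EmptyGlcmError(
            f"no voxel pair at angle {direction}, offset {offset}"
        )
    return GlcMatrix(p=c / total, direction=direction, offset=offset)


def glcm_features(glcm: GlcMatrix) -> dict[str, float]:
    """Standard-reference Haralick-type features of a normalized GLCM.

    With zero marginal variance (single-level ROI), Correlation is defined
    as 1 (constant texture is perfectly self-correlated) and
    HaralickCorrelation as 0.
    """
    p = glcm.p
    ng = p.shape[0]
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, ng + 1)[None, :].astype(float)
    px = p.sum(axis=1)
    lv = np.arange(1, ng + 1, dtype=float)
    mu = float(px @ lv)  # symmetric: mu_x == mu_y
    var = float(px @ (lv - mu) ** 2)
    energy = float((p**2).sum())
    inertia = float(((i - j) ** 2 * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    shade = float(((i + j - 2 * mu) ** 3 * p).sum())
    prominence = float(((i + j - 2 * mu) ** 4 * p).sum())
    if var <= 0.0:
        corr, hcorr = 1.0, 0.0
    else:
        cov = float(((i - mu) * (j - mu) * p).sum())
        corr = cov / var
        hcorr = (float((i * j * p).sum()) - mu * mu) / var
    return {
        "GLCMEnergy": energy,
        "Inertia": inertia,
        "Correlation": corr,
        "HaralickCorrelation": hcorr,
        "ClusterShade": shade,
        "ClusterProminence": prominence,
        "InverseDifferenceMoment": idm,
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _sheared(levels: np.ndarray, diagonal: int) -> np.ndarray:
    """Shear each axial slice so diagonal lines become axis-0 columns.

    ``diagonal`` +1 maps 45-degree (anti-diagonal) lines, -1 maps
    135-degree (main diagonal) lines, onto constant column index.
    """
    nr, nc, nz = levels.shape
    out = np.zeros((nr, nr + nc, nz), dtype=levels.dtype)
    rows = np.arange(nr)[:, None]
    cols = np.arange(nc)[None, :]
    if diagonal > 0:
        idx = rows + cols  # r + c = const on 45-degree lines
    else:
        idx = (nc - 1) + rows - cols  # r - c = const on 135-degree lines
    out[rows, idx, :] = levels
    return out


def _run_lengths(lines: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode rows of a 2D array; 0 is the break sentinel.

    Returns (levels, lengths) of all maximal runs of a nonzero level.
    """
    if lines.size == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    sep = np.zeros((lines.shape[0], 1), dtype=lines.dtype)
    x = np.concatenate([lines, sep], axis=1).ravel()
    change = np.flatnonzero(np.diff(x) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [x.size - 1]])
    values = x[starts]
    lengths = ends - starts + 1
    keep = values > 0
    return values[keep].astype(np.int64), lengths[keep].astype(np.int64)


def compute_glrlm(roi: QuantizedRoi, direction: int, offset: int = 1) -> GlrlMatrix:
    """Pooled in-plane run-length matrix at one angle.

    Runs are maximal sequences of equal level along lines in the given
    direction, sampled with stride ``offset`` voxels (offset 1 is the
    classical run-length matrix); unmasked sampled voxels split runs, as
    do slice and line boundaries.
    """
    if not roi.mask.any():
        raise EmptyMaskError("cannot compute runs on an empty ROI")
    if offset < 1:
        raise ValueError(f"offset must be >= 1, got {offset}")
    if direction not in _ANGLE_STEPS:
        raise ValueError(f"direction must be one of {ANGLES}, got {direction}")
    lv = roi.levels
    if direction == 0:
        stacks = [np.moveaxis(lv[:, ph::offset, :], 1, -1) for ph in range(offset)]
    elif direction == 90:
        stacks = [np.moveaxis(lv[ph::offset, :, :], 0, -1) for ph in range(offset)]
    else:
        sh = _sheared(lv, +1 if direction == 45 else -1)
        stacks = [np.moveaxis(sh[ph::offset, :, :], 0, -1) for ph in range(offset)]
    all_levels, all_lengths = [], []
    for s in stacks:
        if 0 in s.shape:
            continue
        vals, lens = _run_lengths(s.reshape(-1, s.shape[-1]))
        all_levels.append(vals)
        all_lengths.append(lens)
    values = np.concatenate(all_levels) if all_levels else np.array([], dtype=np.int64)
    lengths = np.concatenate(all_lengths) if all_lengths else np.array([], dtype=np.int64)
    if values.size == 0:
        raise EmptyMaskError("no runs found (empty ROI)")
    lmax = int(lengths.max())
    r = np.bincount(
        (values - 1) * lmax + (lengths - 1), minlength=roi.n_levels * lmax
    ).reshape(roi.n_levels, lmax)
    return GlrlMatrix(r=r, direction=direction, offset=offset)


def glrlm_features(glrlm: GlrlMatrix) -> dict[str, float]:
    """Run-emphasis features of a run-length count matrix."""
    r = glrlm.r.astype(float)
    nr = r.sum()
    if nr == 0:
        raise EmptyMaskError("run-length matrix has no runs")
    i2 = (np.arange(1, r.shape[0] + 1, dtype=float) ** 2)[:, None]
    j2 = (np.arange(1, r.shape[1] + 1, dtype=float) ** 2)[None, :]
    return {
        "ShortRunEmphasis": float((r / j2).sum() / nr),
        "LongRunHighGreyLevelEmphasis": float((r * i2 * j2).sum() / nr),
        "ShortRunLowGreyLevelEmphasis": float((r / (i2 * j2)).sum() / nr),
        "ShortRunHighGreyLevelEmphasis": float((r * i2 / j2).sum() / nr),
    }


# ---------------------------------------------------------------------------
# direction aggregation
# ---------------------------------------------------------------------------

def aggregate_directions(values: Mapping[int, float]) -> dict[str, float]:
    """Mean and population SD of a feature over the defined angles.

    Angles whose value is missing (NaN, e.g. from an empty GLCM at a large
    offset) are dropped from both aggregates rather than counted as zeros;
    the SD is flagged missing when fewer than 2 angles remain.
    """
    vals = np.array(
        [v for v in values.values() if v is not None and np.isfinite(v)], dtype=float
    )
    if vals.size == 0:
        return {"AllDirection": float("nan"), "AllDirection_SD": float("nan")}
    if vals.size < len(values):
        logger.debug(
            "aggregating over %d of %d directions", vals.size, len(values)
        )
    out = {"AllDirection": float(vals.mean())}
    out["AllDirection_SD"] = float(vals.std(ddof=0)) if vals.size >= 2 else float("nan")
    return out


# ---------------------------------------------------------------------------
# shape and PET uptake
# ---------------------------------------------------------------------------

def shape_sphericity(mask: RoiMask, surface: str = "mesh") -> float:
    """Sphericity pi^(1/3) (6V)^(2/3) / A of the mask.

    ``surface='mesh'`` triangulates the 0.5 isosurface of the lightly
    smoothed mask indicator (0.8-voxel Gaussian), which removes the
    staircase-artifact area overestimate of a raw binary isosurface; small
    angular regions can exceed 1 slightly through discretization.
    ``surface='faces'`` counts exposed voxel faces (the convention under
    which a cube scores exactly (pi/6)^(1/3)).
    """
    m = mask.voxels
    if not m.any():
        raise EmptyMaskError("cannot compute sphericity of an empty mask")
    sx, sy, sz = mask.spacing_mm
    volume = m.sum() * sx * sy * sz
    if surface == "mesh":
        from scipy.ndimage import gaussian_filter

        padded = gaussian_filter(np.pad(m.astype(float), 2), sigma=0.8)
        if padded.max() <= 0.5:  # tiny mask smoothed below the isolevel
            padded = np.pad(m.astype(float), 2)
        verts, faces_, _, _ = marching_cubes(padded, level=0.5, spacing=(sx, sy, sz))
        area = mesh_surface_area(verts, faces_)
    elif surface == "faces":
        area = 0.0
        face_area = (sy * sz, sx * sz, sx * sy)
        for axis, fa in enumerate(face_area):
            p = np.pad(m, [(1, 1) if ax == axis else (0, 0) for ax in range(3)])
            area += fa * np.count_nonzero(np.diff(p.astype(np.int8), axis=axis))
    else:
        raise ValueError(f"surface must be 'mesh' or 'faces', got {surface!r}")
    return float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)


def tbr(
    pet: ImageVolume, lesion: RoiMask, background: RoiMask
) -> dict[str, float]:
    """Tumor-to-background ratios: max and mean lesion uptake over mean background."""
    if not lesion.voxels.any() or not background.voxels.any():
        raise EmptyMaskError("lesion and background masks must be non-empty")
    bg_mean = float(pet.voxels[background.voxels].mean())
    if bg_mean <= 0:
        raise ValueError(f"background mean must be positive, got {bg_mean}")
    les = pet.voxels[lesion.voxels]
    return {
        "TBRmax": float(les.max()) / bg_mean,
        "TBRmean": float(les.mean()) / bg_mean,
    }


# ---------------------------------------------------------------------------
# full per-patient extraction
# ---------------------------------------------------------------------------

@dataclass
class FeatureConfig:
    """Catalogue configuration for full feature extraction."""

    n_levels: int = 64
    offsets: tuple[int, ...] = DEFAULT_OFFSETS
    angles: tuple[int, ...] = ANGLES
    max_missing_fraction: float = 0.2


def _texture_block(roi: QuantizedRoi, config: FeatureConfig) -> dict[str, float]:
    """All GLCM/GLRLM features with per-angle and aggregated variants."""
    out: dict[str, float] = {}
    for offset in config.offsets:
        per_angle_glcm: dict[str, dict[int, float]] = {f: {} for f in GLCM_FEATURES}
        per_angle_glrlm: dict[str, dict[int, float]] = {f: {} for f in GLRLM_FEATURES}
        for angle in config.angles:
            try:
                gf = glcm_features(compute_glcm(roi, angle, offset))
            except EmptyGlcmError:
                gf = {f: float("nan") for f in GLCM_FEATURES}
            for f, v in gf.items():
                out[f"{f}_angle{angle}_offset{offset}"] = v
                per_angle_glcm[f][angle] = v
            rf = glrlm_features(compute_glrlm(roi, angle, offset))
            for f, v in rf.items():
                out[f"{f}_angle{angle}_offset{offset}"] = v
                per_angle_glrlm[f][angle] = v
        for f, vals in {**per_angle_glcm, **per_angle_glrlm}.items():
            agg = aggregate_directions(vals)
            out[f"{f}_AllDirection_offset{offset}"] = agg["AllDirection"]
            out[f"{f}_AllDirection_offset{offset}_SD"] = agg["AllDirection_SD"]
    return out


def extract_patient_features(
    volumes: Mapping[str, ImageVolume],
    lesion: RoiMask,
    background: RoiMask | None = None,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    """Extract the full feature catalogue for one patient.

    Returns a flat mapping ``{modality}__{family}__{name} -> value``.  The
    catalogue (and hence the key set) depends only on the configuration,
    never on the data; values at unattainable direction/offset combinations
    are NaN, and more than ``max_missing_fraction`` missing values raises.
    """
    config = config or FeatureConfig()
    out: dict[str, float] = {}
    for modality, vol in volumes.items():
        if vol.shape != lesion.shape:
            raise ValueError(f"{modality} volume not aligned with lesion mask")
        roi = quantize_roi(vol, lesion, config.n_levels)
        for name, v in first_order_features(vol.voxels[lesion.voxels]).items():
            out[f"{modality}__firstorder__{name}"] = v
        for name, v in _texture_block(roi, config).items():
            out[f"{modality}__texture__{name}"] = v
        out[f"{modality}__shape__Sphericity"] = shape_sphericity(lesion)
        if modality in ("FDG", "MET") and background is not None:
            for name, v in tbr(vol, lesion, background).items():
                out[f"{modality}__pet__{name}"] = v
    n_missing = sum(1 for v in out.values() if not np.isfinite(v))
    if n_missing > config.max_missing_fraction * len(out):
        raise ValueError(
            f"{n_missing}/{len(out)} features missing "
            f"(> {config.max_missing_fraction:.0%} allowed)"
        )
    return out
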