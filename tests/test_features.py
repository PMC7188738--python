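"""Texture/shape/uptake features against hand values and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliorad.features import (
    EmptyGlcmError,
    EmptyMaskError,
    FeatureConfig,
    QuantizedRoi,
    aggregate_directions,
    compute_glcm,
    compute_glrlm,
    extract_patient_features,
    first_order_features,
    glcm_features,
    glrlm_features,
    quantize_roi,
    shape_sphericity,
    tbr,
)
from gliorad.io import ImageVolume, RoiMask

# displacement per angle for brute-force pair enumeration; symmetrization
# makes the sign of the step irrelevant
ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def _roi_from_levels(levels: np.ndarray, n_levels: int) -> QuantizedRoi:
    levels = np.asarray(levels, dtype=np.int32)
    return QuantizedRoi(levels=levels, mask=levels > 0, n_levels=n_levels)


def brute_force_glcm(roi: QuantizedRoi, angle: int, offset: int) -> np.ndarray:
    """O(voxels) per-pair enumeration of the symmetric normalized GLCM."""
    dr, dc = (s * offset for s in ANGLE_STEPS[angle])
    ng = roi.n_levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    nr, nc, nz = roi.levels.shape
    for z in range(nz):
        for r in range(nr):
            for c in range(nc):
                a = roi.levels[r, c, z]
                r2, c2 = r + dr, c + dc
                if a > 0 and 0 <= r2 < nr and 0 <= c2 < nc:
                    b = roi.levels[r2, c2, z]
                    if b > 0:
                        counts[a - 1, b - 1] += 1
    counts = counts + counts.T
    return counts / counts.sum() if counts.sum() else counts.astype(float)


def brute_force_glrlm(roi: QuantizedRoi, angle: int, offset: int) -> dict:
    """Enumerate lines in the angle direction at sampling stride ``offset``
    and run-length encode them cell by cell; returns {(level, length): count}."""
    nr, nc, nz = roi.levels.shape
    lines = []
    for z in range(nz):
        sl = roi.levels[:, :, z]
        if angle == 0:
            for r in range(nr):
                for ph in range(offset):
                    lines.append([sl[r, c] for c in range(ph, nc, offset)])
        elif angle == 90:
            for c in range(nc):
                for ph in range(offset):
                    lines.append([sl[r, c] for r in range(ph, nr, offset)])
        elif angle == 45:  # r + c = const, walk increasing r
            for d in range(nr + nc - 1):
                for ph in range(offset):
                    lines.append(
                        [sl[r, d - r] for r in range(ph, nr, offset) if 0 <= d - r < nc]
                    )
        else:  # 135: r - c = const
            for d in range(-(nc - 1), nr):
                for ph in range(offset):
                    lines.append(
                        [sl[r, r - d] for r in range(ph, nr, offset) if 0 <= r - d < nc]
                    )
    runs: dict = {}
    for line in lines:
        level, length = 0, 0
        for v in line + [0]:
            if v == level:
                length += 1
            else:
                if level > 0:
                    runs[(level, length)] = runs.get((level, length), 0) + 1
                level, length = v, 1
    return runs


def _glrlm_as_dict(r: np.ndarray) -> dict:
    return {
        (i + 1, j + 1): int(r[i, j])
        for i in range(r.shape[0])
        for j in range(r.shape[1])
        if r[i, j]
    }


# -- quantization ------------------------------------------------------------

def test_quantize_integer_ramp_maps_to_consecutive_levels():
    vol = ImageVolume(np.arange(64, dtype=float).reshape(4, 4, 4), (1, 1, 1))
    mask = RoiMask(np.ones((4, 4, 4), bool), (1, 1, 1))
    roi = quantize_roi(vol, mask, n_levels=64)
    np.testing.assert_array_equal(roi.levels, np.arange(1, 65).reshape(4, 4, 4))


def test_quantize_constant_roi_maps_to_level_one():
    vol = ImageVolume(np.full((3, 3, 3), 7.0), (1, 1, 1))
    mask = RoiMask(np.ones((3, 3, 3), bool), (1, 1, 1))
    roi = quantize_roi(vol, mask, n_levels=64)
    assert set(np.unique(roi.levels[roi.mask])) == {1}


def test_quantize_zero_outside_mask_and_range_clipped(rng):
    vol = ImageVolume(rng.normal(size=(5, 5, 5)), (1, 1, 1))
    m = np.zeros((5, 5, 5), bool)
    m[1:4, 1:4, 1:4] = True
    roi = quantize_roi(vol, RoiMask(m, (1, 1, 1)), n_levels=16)
    assert (roi.levels[~m] == 0).all()
    inside = roi.levels[m]
    assert inside.min() >= 1 and inside.max() <= 16


@settings(max_examples=30, deadline=None)
@given(
    scale=st.floats(0.05, 50.0),
    shift=st.floats(-100.0, 100.0),
    seed=st.integers(0, 2**16),
)
def test_quantize_invariant_under_positive_affine_rescaling(scale, shift, seed):
    r = np.random.default_rng(seed)
    data = r.normal(size=(4, 4, 3)) * 10
    mask = RoiMask(np.ones(data.shape, bool), (1, 1, 1))
    a = quantize_roi(ImageVolume(data, (1, 1, 1)), mask, 32)
    b = quantize_roi(ImageVolume(data * scale + shift, (1, 1, 1)), mask, 32)
    np.testing.assert_array_equal(a.levels, b.levels)


def test_quantize_rejects_empty_mask_and_bad_levels():
    vol = ImageVolume(np.zeros((3, 3, 3)), (1, 1, 1))
    with pytest.raises(EmptyMaskError):
        quantize_roi(vol, RoiMask(np.zeros((3, 3, 3), bool), (1, 1, 1)), 8)
    with pytest.raises(ValueError):
        quantize_roi(vol, RoiMask(np.ones((3, 3, 3), bool), (1, 1, 1)), 1)


# -- first-order -------------------------------------------------------------

def test_first_order_hand_values():
    out = first_order_features(np.array([1.0, 2.0, 3.0, 4.0]))
    assert out["RMS"] == pytest.approx(np.sqrt(7.5))
    assert out["stdDeviation"] == pytest.approx(np.sqrt(1.25))
    assert out["RelativeDeviation"] == pytest.approx(0.4)


def test_first_order_quantile_oracle():
    out = first_order_features(np.arange(1, 1001, dtype=float))
    assert out["Quantile0.025"] == pytest.approx(25.975)


def test_first_order_degenerate_conventions():
    assert first_order_features(np.full(5, 3.0))["RelativeDeviation"] == 0.0
    zero_mean = first_order_features(np.array([-1.0, 1.0]))
    assert np.isnan(zero_mean["RelativeDeviation"])
    with pytest.raises(EmptyMaskError):
        first_order_features(np.array([]))


# -- GLCM --------------------------------------------------------------------

def test_glcm_two_voxel_hand_oracle():
    roi = _roi_from_levels(np.array([[1, 2]]).reshape(1, 2, 1), n_levels=2)
    g = compute_glcm(roi, 0, 1)
    np.testing.assert_allclose(g.p, [[0.0, 0.5], [0.5, 0.0]])
    f = glcm_features(g)
    assert f["GLCMEnergy"] == pytest.approx(0.5)
    assert f["Inertia"] == pytest.approx(1.0)
    assert f["Correlation"] == pytest.approx(-1.0)
    assert f["HaralickCorrelation"] == pytest.approx(-1.0)
    assert f["InverseDifferenceMoment"] == pytest.approx(0.5)
    assert f["ClusterShade"] == pytest.approx(0.0)
    assert f["ClusterProminence"] == pytest.approx(0.0)  # i+j-2mu = 0 off-diagonal


def test_glcm_constant_roi_degenerate_correlations():
    roi = _roi_from_levels(np.ones((2, 3, 1), int), n_levels=4)
    f = glcm_features(compute_glcm(roi, 0, 1))
    assert f["Correlation"] == 1.0
    assert f["HaralickCorrelation"] == 0.0
    assert f["GLCMEnergy"] == pytest.approx(1.0)


def test_glcm_matches_brute_force_on_random_rois(rng):
    for _ in range(20):
        levels = rng.integers(0, 5, size=(6, 6, 3))  # 0 = outside mask
        roi = _roi_from_levels(levels, n_levels=4)
        for angle in (0, 45, 90, 135):
            for offset in (1, 2, 4):
                expected = brute_force_glcm(roi, angle, offset)
                if expected.sum() == 0:
                    with pytest.raises(EmptyGlcmError):
                        compute_glcm(roi, angle, offset)
                else:
                    got = compute_glcm(roi, angle, offset).p
                    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_glcm_symmetric_and_normalized(rng):
    roi = _roi_from_levels(rng.integers(1, 9, size=(5, 5, 2)), n_levels=8)
    for angle in (0, 45, 90, 135):
        g = compute_glcm(roi, angle, 1)
        np.testing.assert_allclose(g.p, g.p.T)
        assert g.p.sum() == pytest.approx(1.0)


def test_glcm_rejects_bad_arguments():
    roi = _roi_from_levels(np.ones((2, 2, 1), int), 2)
    with pytest.raises(ValueError):
        compute_glcm(roi, 30, 1)
    with pytest.raises(ValueError):
        compute_glcm(roi, 0, 0)
    single = _roi_from_levels(np.array([[1]]).reshape(1, 1, 1), 2)
    with pytest.raises(EmptyGlcmError):
        compute_glcm(single, 0, 1)


# -- GLRLM -------------------------------------------------------------------

def test_glrlm_single_row_hand_oracle():
    roi = _roi_from_levels(np.array([[1, 1, 2]]).reshape(1, 3, 1), n_levels=2)
    g = compute_glrlm(roi, 0, 1)
    assert _glrlm_as_dict(g.r) == {(1, 2): 1, (2, 1): 1}
    f = glrlm_features(g)
    assert f["ShortRunEmphasis"] == pytest.approx((1 / 4 + 1) / 2)
    assert f["LongRunHighGreyLevelEmphasis"] == pytest.approx((1 * 4 + 4 * 1) / 2)
    assert f["ShortRunLowGreyLevelEmphasis"] == pytest.approx((1 / 4 + 1 / 4) / 2)
    assert f["ShortRunHighGreyLevelEmphasis"] == pytest.approx((1 / 4 + 4) / 2)


def test_glrlm_stride_sampling_splits_runs():
    # levels 1 1 1 1 along angle 0; stride 2 gives two phase lines 1 1 / 1 1
    roi = _roi_from_levels(np.array([[1, 1, 1, 1]]).reshape(1, 4, 1), n_levels=1)
    g = compute_glrlm(roi, 0, 2)
    assert _glrlm_as_dict(g.r) == {(1, 2): 2}


def test_glrlm_matches_brute_force_on_random_rois(rng):
    for _ in range(20):
        levels = rng.integers(0, 5, size=(6, 6, 3))
        roi = _roi_from_levels(levels, n_levels=4)
        if not roi.mask.any():
            continue
        for angle in (0, 45, 90, 135):
            for offset in (1, 2, 4):
                got = _glrlm_as_dict(compute_glrlm(roi, angle, offset).r)
                assert got == brute_force_glrlm(roi, angle, offset)


def test_glrlm_rejects_bad_arguments():
    roi = _roi_from_levels(np.ones((2, 2, 1), int), 2)
    with pytest.raises(ValueError):
        compute_glrlm(roi, 10, 1)
    with pytest.raises(ValueError):
        compute_glrlm(roi, 0, 0)
    empty = QuantizedRoi(np.zeros((2, 2, 1), np.int32), np.zeros((2, 2, 1), bool), 2)
    with pytest.raises(EmptyMaskError):
        compute_glrlm(empty, 0, 1)


# -- rotation equivariance ---------------------------------------------------

def test_inplane_rotation_swaps_angle_features(rng):
    levels = rng.integers(1, 7, size=(5, 5, 2))
    roi = _roi_from_levels(levels, n_levels=6)
    rotated = _roi_from_levels(np.rot90(levels, axes=(0, 1)), n_levels=6)
    pairs = {0: 90, 90: 0, 45: 135, 135: 45}
    for a, b in pairs.items():
        fa = glcm_features(compute_glcm(roi, a, 1))
        fb = glcm_features(compute_glcm(rotated, b, 1))
        for name in fa:
            assert fa[name] == pytest.approx(fb[name], abs=1e-12), (a, name)
        ra = glrlm_features(compute_glrlm(roi, a, 1))
        rb = glrlm_features(compute_glrlm(rotated, b, 1))
        for name in ra:
            assert ra[name] == pytest.approx(rb[name], abs=1e-12), (a, name)


# -- direction aggregation ---------------------------------------------------

def test_aggregate_directions_mean_and_population_sd():
    out = aggregate_directions({0: 1.0, 45: 2.0, 90: 3.0, 135: 4.0})
    assert out["AllDirection"] == pytest.approx(2.5)
    assert out["AllDirection_SD"] == pytest.approx(np.sqrt(1.25))


def test_aggregate_directions_drops_missing_angles():
    out = aggregate_directions({0: 1.0, 45: float("nan"), 90: 3.0, 135: float("nan")})
    assert out["AllDirection"] == pytest.approx(2.0)
    assert out["AllDirection_SD"] == pytest.approx(1.0)
    single = aggregate_directions({0: 1.0, 45: float("nan")})
    assert single["AllDirection"] == 1.0
    assert np.isnan(single["AllDirection_SD"])
    empty = aggregate_directions({0: float("nan")})
    assert np.isnan(empty["AllDirection"])


# -- shape and uptake --------------------------------------------------------

def test_cube_sphericity_face_counted_exact():
    m = np.zeros((10, 10, 10), bool)
    m[2:8, 2:8, 2:8] = True
    s = shape_sphericity(RoiMask(m, (1, 1, 1)), surface="faces")
    assert s == pytest.approx((np.pi / 6) ** (1 / 3), abs=1e-6)


def test_ball_sphericity_mesh_near_one():
    from skimage.morphology import ball

    s = shape_sphericity(RoiMask(ball(10).astype(bool), (1, 1, 1)), surface="mesh")
    assert 0.95 <= s <= 1.05


def test_sphericity_respects_anisotropic_spacing():
    # a 2x2x1-voxel box at spacing (1,1,2) is a 2x2x2 mm cube
    m = np.zeros((4, 4, 3), bool)
    m[1:3, 1:3, 1] = True
    s = shape_sphericity(RoiMask(m, (1, 1, 2)), surface="faces")
    assert s == pytest.approx((np.pi / 6) ** (1 / 3), abs=1e-6)


def test_sphericity_errors():
    with pytest.raises(EmptyMaskError):
        shape_sphericity(RoiMask(np.zeros((3, 3, 3), bool), (1, 1, 1)))
    with pytest.raises(ValueError):
        shape_sphericity(RoiMask(np.ones((3, 3, 3), bool), (1, 1, 1)), surface="voxels")


def test_tbr_hand_values():
    vox = np.zeros((2, 2, 1))
    vox[0, 0, 0], vox[0, 1, 0] = 2.0, 4.0  # lesion
    vox[1, 0, 0], vox[1, 1, 0] = 1.0, 3.0  # background
    lesion = np.zeros((2, 2, 1), bool)
    lesion[0, :, 0] = True
    bg = ~lesion
    out = tbr(ImageVolume(vox, (1, 1, 1)), RoiMask(lesion, (1, 1, 1)), RoiMask(bg, (1, 1, 1)))
    assert out["TBRmax"] == pytest.approx(2.0)
    assert out["TBRmean"] == pytest.approx(1.5)


def test_tbr_requires_positive_background():
    vox = np.zeros((2, 2, 1))
    lesion = np.zeros((2, 2, 1), bool)
    lesion[0, :, 0] = True
    with pytest.raises(ValueError, match="background"):
        tbr(ImageVolume(vox, (1, 1, 1)), RoiMask(lesion, (1, 1, 1)), RoiMask(~lesion, (1, 1, 1)))


# -- full catalogue ----------------------------------------------------------

def test_catalogue_size_and_naming(small_cohort):
    p = small_cohort[0]
    feats = extract_patient_features(
        p.volumes, p.lesion_mask_rater1, p.background_mask
    )
    assert len(feats) == 613
    per_modality = {m: sum(k.startswith(m + "__") for k in feats) for m in ("FDG", "MET", "MRI")}
    assert per_modality == {"FDG": 205, "MET": 205, "MRI": 203}
    assert "FDG__pet__TBRmean" in feats and "MET__pet__TBRmax" in feats
    assert "MRI__shape__Sphericity" in feats
    assert not any(k.startswith("MRI__pet__") for k in feats)


def test_catalogue_key_set_is_data_independent(small_cohort):
    a = extract_patient_features(
        small_cohort[0].volumes, small_cohort[0].lesion_mask_rater1,
        small_cohort[0].background_mask,
    )
    b = extract_patient_features(
        small_cohort[1].volumes, small_cohort[1].lesion_mask_rater1,
        small_cohort[1].background_mask,
    )
    assert list(a) == list(b)


def test_excess_missing_features_rejected(small_cohort):
    p = small_cohort[0]
    # a single-voxel lesion leaves most texture combinations unattainable
    single = np.zeros(p.lesion_mask_rater1.shape, bool)
    single[tuple(np.argwhere(p.lesion_mask_rater1.voxels)[0])] = True
    with pytest.raises(ValueError, match="missing"):
        extract_patient_features(
            p.volumes,
            RoiMask(single, p.lesion_mask_rater1.spacing_mm),
            p.background_mask,
            FeatureConfig(max_missing_fraction=0.05),
        )
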