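"""Image quantification: SD statistic, summaries, fits, thickness, morphology."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import brute_force_sd

from seedquant.containers import Micrograph, MicrographMeta, ZStack
from seedquant.quant import (DoseResponse, MorphologyCutoffs, TimeCourse,
                             TimeCoursePoint, classify_morphology,
                             fit_half_max, fit_sigmoid, rank_activity,
                             sd_statistic, summarize_timecourse,
                             thickness_profile)
from seedquant.quant import _boltzmann, _logistic4


# --------------------------------------------------------------------------
# SD statistic

def test_uniform_image_has_zero_sd():
    assert sd_statistic(np.full((16, 16), 37.0)) == 0.0


def test_checkerboard_sd_is_half_gap():
    a, b = 10.0, 30.0
    img = np.indices((8, 8)).sum(axis=0) % 2 * (b - a) + a
    assert sd_statistic(img) == pytest.approx((b - a) / 2, abs=1e-12)


def test_sd_matches_brute_force_on_random_grids(rng):
    for _ in range(150):
        h, w = rng.integers(1, 9, size=2)
        grid = rng.integers(0, 256, size=(h, w)).astype(float)
        expected = brute_force_sd(grid)
        assert sd_statistic(grid) == pytest.approx(expected, abs=1e-12,
                                                   rel=1e-12)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(shift=st.floats(-100, 100), scale=st.floats(0.01, 50),
       seed=st.integers(0, 2 ** 16))
def test_sd_shift_invariance_and_scale_equivariance(shift, scale, seed):
    grid = np.random.default_rng(seed).integers(0, 200, size=(6, 7)).astype(float)
    base = sd_statistic(grid)
    assert sd_statistic(grid + shift) == pytest.approx(base, abs=1e-9)
    assert sd_statistic(grid * scale) == pytest.approx(base * scale,
                                                       rel=1e-12, abs=1e-9)


def test_color_image_averaged_to_grayscale():
    rgb = np.zeros((4, 4, 3))
    rgb[..., 0] = 30.0  # only the red channel carries signal
    assert sd_statistic(rgb) == 0.0  # constant after channel mean
    m = Micrograph(pixels=rgb, bit_depth=8)
    assert m.pixels.ndim == 2


def test_non_finite_grid_rejected():
    bad = np.ones((3, 3))
    bad[1, 1] = np.nan
    with pytest.raises(ValueError):
        sd_statistic(bad)


# --------------------------------------------------------------------------
# Time course

def test_timecourse_mean_and_sem():
    # constant images with known SDs via direct construction
    imgs = []
    for rep, val in enumerate([1.0, 2.0, 3.0]):
        px = np.array([[0.0, 2 * val], [0.0, 2 * val]])  # SD = val
        imgs.append(Micrograph(pixels=px, meta=MicrographMeta(
            time_h=24.0, replicate_id=rep)))
    tc = summarize_timecourse(imgs)
    (pt,) = tc.points
    assert pt.sd_mean == pytest.approx(2.0)
    assert pt.sd_sem == pytest.approx(1.0 / math.sqrt(3))
    assert pt.n_replicates == 3


def test_single_replicate_sem_undefined():
    img = Micrograph(pixels=np.arange(4.0).reshape(2, 2),
                     meta=MicrographMeta(time_h=0.0, replicate_id=0))
    (pt,) = summarize_timecourse([img]).points
    assert math.isnan(pt.sd_sem)
    assert pt.n_replicates == 1


def test_timecourse_requires_strictly_increasing_times():
    with pytest.raises(ValueError):
        TimeCourse(points=(TimeCoursePoint(1.0, 1, 0, 3),
                           TimeCoursePoint(1.0, 2, 0, 3)))


# --------------------------------------------------------------------------
# Sigmoid fit

def test_sigmoid_recovers_noise_free_parameters():
    t = np.linspace(0, 168, 15)
    truth = (0.5, 4.0, 72.0, 0.1)
    y = _boltzmann(t, *truth)
    tc = TimeCourse(points=tuple(
        TimeCoursePoint(ti, yi, 0.0, 3) for ti, yi in zip(t, y)))
    fit = fit_sigmoid(tc)
    assert fit.baseline == pytest.approx(truth[0], rel=1e-6)
    assert fit.plateau == pytest.approx(truth[1], rel=1e-6)
    assert fit.t50 == pytest.approx(truth[2], rel=1e-6)
    assert fit.slope == pytest.approx(truth[3], rel=1e-6)
    assert fit.lag_time == pytest.approx(72.0 - 2 / 0.1, rel=1e-5)
    assert not fit.extrapolated


def test_sigmoid_flat_series_flagged():
    tc = TimeCourse(points=tuple(
        TimeCoursePoint(t, 2.5, 0.0, 3) for t in np.linspace(0, 100, 6)))
    fit = fit_sigmoid(tc)
    assert fit.plateau == pytest.approx(fit.baseline)
    assert fit.extrapolated


def test_sigmoid_needs_five_points():
    tc = TimeCourse(points=tuple(
        TimeCoursePoint(t, t, 0.0, 3) for t in [0, 1, 2, 3]))
    with pytest.raises(ValueError):
        fit_sigmoid(tc)


# --------------------------------------------------------------------------
# Half-max fit

def test_half_max_recovers_noise_free_parameters():
    x = np.array([0.0, 0.05, 0.1, 0.2, 0.3, 0.5, 0.8, 1.0])
    truth = (0.5, 4.0, 0.3, 2.0)
    y = _logistic4(x, *truth)
    dr = DoseResponse(fractions=tuple(x),
                      endpoint_sds=tuple((v,) for v in y))
    fit = fit_half_max(dr)
    assert fit.bottom == pytest.approx(truth[0], rel=1e-6, abs=1e-8)
    assert fit.top == pytest.approx(truth[1], rel=1e-6)
    assert fit.half_max_fraction == pytest.approx(truth[2], rel=1e-6)
    assert fit.hill == pytest.approx(truth[3], rel=1e-6)
    assert not fit.unidentifiable


def test_half_max_constant_response_unidentifiable():
    dr = DoseResponse(fractions=(0.1, 0.2, 0.4, 0.8),
                      endpoint_sds=((2.0,), (2.0,), (2.0,), (2.0,)))
    fit = fit_half_max(dr)
    assert fit.unidentifiable
    assert math.isnan(fit.half_max_fraction)


def test_half_max_needs_four_fractions():
    dr = DoseResponse(fractions=(0.1, 0.5, 1.0),
                      endpoint_sds=((1.0,), (2.0,), (3.0,)))
    with pytest.raises(ValueError):
        fit_half_max(dr)


# --------------------------------------------------------------------------
# Thickness

def test_constructed_block_thickness():
    # 10 of 20 slices carry a bright block; z_step 2 um -> 20 um thickness
    slices = np.zeros((20, 32, 32))
    slices[5:15, 8:24, 8:24] = 100.0
    zs = ZStack(slices=slices, z_step=2.0)
    mean_th, th_map = thickness_profile(zs)
    assert mean_th == pytest.approx(20.0)
    assert th_map[16, 16] == pytest.approx(20.0)
    assert th_map[0, 0] == 0.0


def test_thickness_all_background_is_zero():
    rng = np.random.default_rng(0)
    zs = ZStack(slices=rng.normal(500, 20, size=(8, 32, 32)), z_step=1.0)
    mean_th, th_map = thickness_profile(zs)
    assert mean_th == 0.0
    assert not th_map.any()


def test_thickness_invariant_to_slice_reversal():
    slices = np.zeros((10, 16, 16))
    slices[3:7, 4:12, 4:12] = 50.0
    a, _ = thickness_profile(ZStack(slices=slices, z_step=1.5))
    b, _ = thickness_profile(ZStack(slices=slices[::-1].copy(), z_step=1.5))
    assert a == pytest.approx(b)


# --------------------------------------------------------------------------
# Morphology

def test_single_blob_is_dotted():
    yy, xx = np.mgrid[0:64, 0:64]
    img = 500 + 800 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / 18.0)
    rep = classify_morphology(img + np.random.default_rng(0).normal(0, 5, img.shape))
    assert rep.label == "dotted"
    assert rep.n_components == 1


def test_full_frame_line_grid_is_mesh():
    img = np.full((64, 64), 500.0)
    img[::8, :] = 1500.0
    img[:, ::8] = 1500.0
    rep = classify_morphology(img + np.random.default_rng(1).normal(0, 5, img.shape))
    assert rep.label == "mesh"
    assert rep.largest_component_fraction == pytest.approx(1.0, abs=0.05)


def test_background_only_is_none():
    img = np.random.default_rng(2).normal(500, 20, size=(64, 64))
    rep = classify_morphology(img)
    assert rep.label == "none"
    assert rep.n_components == 0


def test_cutoffs_are_configurable():
    img = np.full((64, 64), 500.0)
    img[::8, :] = 1500.0
    strict = MorphologyCutoffs(min_largest_component_fraction=1.1,
                               min_skeleton_length_per_area=1.0)
    assert classify_morphology(img, strict).label == "dotted"


# --------------------------------------------------------------------------
# Ranking

def test_rank_activity_orders_by_mean():
    ranking = rank_activity({"cat": [5.0], "mouse": [4.5], "goat": [2.0],
                             "cattle": [1.9], "camel": [1.8]})
    assert [r[0] for r in ranking] == ["cat", "mouse", "goat", "cattle",
                                       "camel"]
    assert not any(r[2] for r in ranking)


def test_rank_activity_flags_ties():
    ranking = rank_activity({"b": [2.0], "a": [2.0], "c": [1.0]})
    assert [r[0] for r in ranking] == ["a", "b", "c"]
    assert ranking[0][2] and ranking[1][2] and not ranking[2][2]
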