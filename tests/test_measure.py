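"""Measurement operators: profiles, sub-sample peaks, the three metrics.

The independent oracle for the 1-D operators is a dense numerical
convolution of a thin-ring cross-section (two boxcar struts) with a
Gaussian PSF, evaluated at a step 30x finer than the measurement sampling.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stentbench.errors import (
    InvalidParameterError,
    MeasurementFailureError,
    OutOfBoundsError,
)
from stentbench.imaging import degrade
from stentbench.measure import (
    LineProfile,
    _half_max_crossings,
    blooming_percent,
    distinction_percent,
    extract_profile,
    find_peaks_subpixel,
    mean_abs_error,
    measure_blooming,
    measure_diameter,
    measure_distinction,
)
from stentbench.phantom import ImageVolume, StentSpec
from stentbench.pipeline import select_slices, simulate_clean
from stentbench.systems import SystemConfig


# --------------------------------------------------------------------------
# 1-D dense-convolution oracle


def _dense_ring_profile(radius=2.75, strut=0.15, fwhm=0.4, height=1000.0, h=0.001, half=6.0):
    """Two boxcar struts at +/-radius convolved with a Gaussian, densely."""
    x = np.arange(-half, half + h / 2, h)
    f = np.zeros_like(x)
    f[np.abs(np.abs(x) - radius) <= strut / 2] = height
    sigma = fwhm / (2 * math.sqrt(2 * math.log(2)))
    k = np.arange(-6 * sigma, 6 * sigma + h / 2, h)
    kern = np.exp(-0.5 * (k / sigma) ** 2)
    kern /= kern.sum()
    g = np.convolve(f, kern, mode="same")
    return x, g


@pytest.fixture(scope="module")
def dense_oracle():
    return _dense_ring_profile()


def test_peak_positions_match_dense_oracle(dense_oracle):
    x, g = dense_oracle
    stride = 30  # measurement samples 30x coarser than the oracle grid
    prof = LineProfile(x[::stride], g[::stride])
    peaks = find_peaks_subpixel(prof)
    assert len(peaks) == 2
    step = prof.step_mm
    right_half = x > 0
    oracle_right = x[right_half][np.argmax(g[right_half])]
    left_half = x < 0
    oracle_left = x[left_half][np.argmax(g[left_half])]
    assert abs(peaks[0][0] - oracle_left) <= step
    assert abs(peaks[1][0] - oracle_right) <= step
    # symmetric PSF leaves the isolated ridge pair centered: peak-to-peak ~ 2*radius
    assert peaks[1][0] - peaks[0][0] == pytest.approx(5.5, abs=step)


def test_half_max_radii_match_dense_oracle(dense_oracle):
    x, g = dense_oracle
    stride = 30
    m = x >= 0
    prof = LineProfile(x[m][::stride], g[m][::stride])
    peaks = find_peaks_subpixel(prof)
    (r_p, h_p) = max(peaks, key=lambda p: p[1])
    got = _half_max_crossings(prof, r_p, h_p, inner_window=(0.7, 1.6), outer_window=(4.5, 5.5))
    assert got is not None
    # dense crossings at exactly half height (baseline 0)
    xr, gr = x[m], g[m]
    i_peak = int(np.argmax(gr))
    level = gr[i_peak] / 2
    inner = xr[:i_peak][gr[:i_peak] >= level].min()
    outer = xr[i_peak:][gr[i_peak:] >= level].max()
    step = prof.step_mm
    assert got[0] == pytest.approx(inner, abs=step)
    assert got[1] == pytest.approx(outer, abs=step)


def test_trough_between_adjacent_struts_matches_oracle():
    # two struts 0.9 mm apart on one side: the dip between them
    h = 0.001
    x = np.arange(0, 8, h)
    f = np.zeros_like(x)
    for c in (2.8, 3.7):
        f[np.abs(x - c) <= 0.075] = 1000.0
    sigma = 0.35 / (2 * math.sqrt(2 * math.log(2)))
    k = np.arange(-6 * sigma, 6 * sigma, h)
    kern = np.exp(-0.5 * (k / sigma) ** 2)
    kern /= kern.sum()
    g = np.convolve(f, kern, mode="same")
    stride = 30
    prof = LineProfile(x[::stride], g[::stride])
    peaks = find_peaks_subpixel(prof, 50.0)
    assert len(peaks) == 2
    (p1, _), (p2, _) = peaks
    between = (prof.position_mm > p1) & (prof.position_mm < p2)
    got_trough = prof.hu[between].min()
    dense_between = (x > p1) & (x < p2)
    oracle_trough = g[dense_between].min()
    assert got_trough == pytest.approx(oracle_trough, abs=0.02 * g.max())


# --------------------------------------------------------------------------
# profile extraction and peak refinement


def _flat_volume(value=50.0):
    return ImageVolume(
        np.full((1, 64, 64), value, dtype=np.float32), spacing_mm=(0.25, 0.25, 1.0)
    )


def test_profile_on_uniform_image_is_constant():
    vol = _flat_volume(123.0)
    c = (vol.x_coords().mean(), vol.y_coords().mean())
    prof = extract_profile(vol, 0, c, 0.3, half_length_mm=5.0, step_mm=0.1)
    np.testing.assert_allclose(prof.hu, 123.0, atol=1e-4)


def test_profile_mirror_symmetry_on_symmetric_phantom(dense_oracle):
    # a rotationally symmetric slice gives mirror-identical opposite profiles
    x, g = dense_oracle
    n = 160
    coords = (np.arange(n) - (n - 1) / 2) * 0.1
    rr = np.hypot(coords[None, :], coords[:, None])
    sl = np.interp(rr, x[x >= 0], g[x >= 0]).astype(np.float32)
    vol = ImageVolume(sl[None], spacing_mm=(0.1, 0.1, 1.0),
                      origin_mm=(coords[0], coords[0], 0.0))
    p1 = extract_profile(vol, 0, (0, 0), 0.7, half_length_mm=5.0, step_mm=0.05)
    p2 = extract_profile(vol, 0, (0, 0), 0.7 + math.pi, half_length_mm=5.0, step_mm=0.05)
    np.testing.assert_allclose(p1.hu, p2.hu[::-1], atol=1e-3)


def test_profile_out_of_bounds_raises():
    vol = _flat_volume()
    with pytest.raises(OutOfBoundsError):
        extract_profile(vol, 0, (0.0, 0.0), 0.0, half_length_mm=100.0, step_mm=0.5)
    with pytest.raises(OutOfBoundsError):
        extract_profile(vol, 5, (8.0, 8.0), 0.0, half_length_mm=1.0, step_mm=0.5)


def test_triangle_apex_on_sample_is_exact():
    pos = np.arange(11) * 0.5
    hu = np.array([0, 1, 2, 3, 4, 5, 4, 3, 2, 1, 0], dtype=float)
    peaks = find_peaks_subpixel(LineProfile(pos, hu), 0.5)
    assert len(peaks) == 1
    assert peaks[0][0] == pytest.approx(2.5)  # exactly the apex sample


def test_gaussian_between_samples_recovered_to_tenth_step():
    step = 0.2
    true_center = 3.07  # deliberately off-grid
    pos = np.arange(0, 6.0 + step / 2, step)
    hu = 100 * np.exp(-0.5 * ((pos - true_center) / 0.5) ** 2)
    peaks = find_peaks_subpixel(LineProfile(pos, hu), 10.0)
    assert len(peaks) == 1
    assert abs(peaks[0][0] - true_center) <= step / 10


def test_monotone_profile_has_no_peaks():
    pos = np.arange(20) * 0.1
    assert find_peaks_subpixel(LineProfile(pos, pos * 7.0), 0.1) == []


# --------------------------------------------------------------------------
# metric formulas


def test_blooming_formula_hand_cases():
    assert blooming_percent(80.0, 100.0) == pytest.approx(20.0)
    assert blooming_percent(55.0, 55.0) == 0.0
    with pytest.raises(InvalidParameterError):
        blooming_percent(101.0, 100.0)
    with pytest.raises(InvalidParameterError):
        blooming_percent(10.0, 0.0)


def test_distinction_formula_hand_cases():
    assert distinction_percent(1000.0, 10.0, 10.0) == pytest.approx(100.0)
    assert distinction_percent(1000.0, 1000.0, 10.0) == pytest.approx(0.0)
    assert distinction_percent(1000.0, 400.0, 100.0) == pytest.approx(600 / 900 * 100)
    assert distinction_percent(500.0, 600.0, 0.0) == 0.0  # inverted dip clamps to 0


@given(
    a_in=st.floats(0.1, 1e3),
    extra=st.floats(0.0, 1e3),
)
def test_blooming_always_in_unit_interval(a_in, extra):
    assert 0.0 <= blooming_percent(a_in, a_in + extra) <= 100.0


@given(
    peak=st.floats(-1e3, 1e3),
    trough=st.floats(-1e3, 1e3),
    minimum=st.floats(-1e3, 1e3),
)
def test_distinction_always_in_unit_interval(peak, trough, minimum):
    assert 0.0 <= distinction_percent(peak, trough, minimum) <= 100.0


def test_mean_abs_error_arithmetic():
    assert mean_abs_error([5.5, 5.5], 5.5) == 0.0
    assert mean_abs_error([5.4, 5.8], 5.5) == pytest.approx(0.2)
    with pytest.raises(InvalidParameterError):
        mean_abs_error([], 5.5)


# --------------------------------------------------------------------------
# volume-level measurements (noiseless, small grids)


def _cfg(pixel=0.146, slice_mm=0.63, fwhm=0.4):
    return SystemConfig(
        label="meas",
        fov_mm=pixel * 512,
        matrix_n=512,
        slice_thickness_mm=slice_mm,
        psf_fwhm_mm=fwhm,
        noise_sd_hu=0.0,
        ctdi_vol_mgy=9.0,
    )


@pytest.fixture(scope="module")
def blurred_carotid(carotid_case):
    cfg = _cfg()
    vol = simulate_clean(carotid_case, cfg, extent_xy_mm=20.0)
    return carotid_case, vol


def test_diameter_recovered_after_symmetric_blur(blurred_carotid):
    # a symmetric PSF does not shift an isolated symmetric ridge
    case, vol = blurred_carotid
    slices = select_slices(vol, None, 3)
    summary, rows = measure_diameter(vol, case.spec.stents[0], slices)
    assert summary.mean == pytest.approx(5.5, abs=0.146)
    assert summary.n == 3
    assert len(rows) > 0


def test_blooming_grows_with_blur(carotid_case):
    vals = []
    for fwhm in (0.3, 0.6):
        vol = simulate_clean(carotid_case, _cfg(fwhm=fwhm), extent_xy_mm=20.0)
        slices = select_slices(vol, None, 3)
        summary, _ = measure_blooming(vol, carotid_case.spec.stents[0], slices)
        vals.append(summary.mean)
    assert vals[1] > vals[0]


def test_measurements_invariant_under_affine_hu_rescale(blurred_carotid):
    case, vol = blurred_carotid
    stent = case.spec.stents[0]
    slices = select_slices(vol, None, 3)
    d0, _ = measure_diameter(vol, stent, slices)
    b0, _ = measure_blooming(vol, stent, slices)
    rescaled = ImageVolume(
        (vol.voxels * 1.7 + 300.0).astype(np.float32),
        spacing_mm=vol.spacing_mm,
        origin_mm=vol.origin_mm,
    )
    d1, _ = measure_diameter(rescaled, stent, slices)
    b1, _ = measure_blooming(rescaled, stent, slices)
    assert d1.mean == pytest.approx(d0.mean, abs=1e-6)
    assert b1.mean == pytest.approx(b0.mean, abs=1e-6)


def test_distinction_invariant_under_affine_hu_rescale(overlap_pair_case):
    vol = simulate_clean(overlap_pair_case, _cfg(), extent_xy_mm=24.0)
    slices = select_slices(vol, None, 3)
    s0, _ = measure_distinction(vol, overlap_pair_case.spec.stents, slices)
    rescaled = ImageVolume(
        (vol.voxels * 0.4 + 1000.0).astype(np.float32),
        spacing_mm=vol.spacing_mm,
        origin_mm=vol.origin_mm,
    )
    s1, _ = measure_distinction(rescaled, overlap_pair_case.spec.stents, slices)
    assert s1.mean == pytest.approx(s0.mean, abs=1e-6)


def test_featureless_image_fails_measurement():
    vol = _flat_volume(100.0)
    stent = StentSpec(diameter_mm=5.0)
    with pytest.raises((MeasurementFailureError, InvalidParameterError)):
        measure_diameter(vol, stent, [0])
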