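import numpy as np
import pytest

from hsifuse.io import HSICube, unfold
from hsifuse.preprocessing import (
    PreprocessPlan,
    asls_baseline,
    bin_pixels,
    crop_spectral,
    despike,
    despike_spectrum,
    mask_saturated,
    resample_to_grid,
    sg_derivative,
)


def _cube(data, axis=None, pixel_size=1.0, mask=None):
    data = np.asarray(data, dtype=float)
    if axis is None:
        axis = np.arange(data.shape[2], dtype=float)
    return HSICube(
        data=data, axis=axis, pixel_size=pixel_size, modality="raman", valid_mask=mask
    )


# ---------------------------------------------------------------------- plan
def test_plan_validation():
    with pytest.raises(ValueError):
        PreprocessPlan(sg_window=4)
    with pytest.raises(ValueError):
        PreprocessPlan(asls_p=1.5)
    with pytest.raises(ValueError):
        PreprocessPlan(bin_factor=0)


# ------------------------------------------------------------ mask_saturated
def test_mask_saturated_flags_exactly_clipped_pixels(rng):
    data = rng.random((5, 5, 8)) * 100
    data[1, 2, 3] = 4095.0
    data[4, 0, :] = 4095.0
    out = mask_saturated(_cube(data), 4095.0)
    assert (~out.valid_mask).sum() == 2
    assert not out.valid_mask[1, 2] and not out.valid_mask[4, 0]
    np.testing.assert_array_equal(out.data, data)  # data untouched


def test_mask_saturated_noop_below_ceiling(rng):
    cube = _cube(rng.random((3, 3, 4)))
    assert mask_saturated(cube, 10.0).valid_mask.all()


def test_mask_saturated_all_clipped_then_unfold_raises():
    cube = _cube(np.full((2, 2, 3), 5000.0))
    out = mask_saturated(cube, 4095.0)
    with pytest.raises(ValueError):
        unfold(out)


# -------------------------------------------------------------- crop_spectral
def test_crop_keeps_analytic_channel_count():
    axis = np.arange(1000.0, 4001.0, 4.0)
    ranges = [(3000.0, 2800.0), (1800.0, 1360.0)]  # reversed order allowed
    expected = int(
        np.sum(((axis >= 2800) & (axis <= 3000)) | ((axis >= 1360) & (axis <= 1800)))
    )
    out = crop_spectral(_cube(np.ones((2, 2, axis.size)), axis), ranges)
    assert out.n_channels == expected
    assert np.all(np.diff(out.axis) > 0)  # original order preserved


def test_crop_full_range_is_identity(small_cube):
    out = crop_spectral(small_cube, [(small_cube.axis[0], small_cube.axis[-1])])
    np.testing.assert_array_equal(out.data, small_cube.data)


def test_crop_outside_span_raises(small_cube):
    with pytest.raises(ValueError):
        crop_spectral(small_cube, [(10000.0, 20000.0)])


# -------------------------------------------------------------- sg_derivative
def test_sg_second_derivative_of_quadratic():
    axis = np.arange(0.0, 50.0, 2.0)
    a, b, c = 0.3, -1.2, 7.0
    spec = a * axis**2 + b * axis + c
    cube = _cube(np.tile(spec, (2, 2, 1)), axis)
    out = sg_derivative(cube, window=7, polyorder=3, deriv_order=2)
    np.testing.assert_allclose(out.data[0, 0, 3:-3], 2 * a, rtol=1e-8)


def test_sg_derivative_removes_linear_baseline():
    axis = np.linspace(0, 100, 60)
    peak = np.exp(-0.5 * ((axis - 50) / 5) ** 2)
    c1 = _cube(peak[None, None, :], axis)
    c2 = _cube((peak + 0.8 * axis + 3.0)[None, None, :], axis)
    d1 = sg_derivative(c1, 9, 3, 2).data
    d2 = sg_derivative(c2, 9, 3, 2).data
    np.testing.assert_allclose(d1, d2, atol=1e-10)


def test_sg_derivative_matches_analytic_gaussian():
    axis = np.linspace(-6, 6, 301)
    s = 1.2
    g = np.exp(-0.5 * (axis / s) ** 2)
    true_d2 = g * (axis**2 - s**2) / s**4
    out = sg_derivative(_cube(g[None, None, :], axis), 11, 4, 2)
    np.testing.assert_allclose(out.data[0, 0, 10:-10], true_d2[10:-10], atol=2e-4)


def test_sg_derivative_window_larger_than_axis_raises():
    with pytest.raises(ValueError):
        sg_derivative(_cube(np.ones((1, 1, 5))), window=9, polyorder=3)


# ------------------------------------------------------------------- asls
def test_asls_smooth_curve_is_its_own_baseline():
    x = np.linspace(0, 1, 200)
    curve = 3.0 + 2.0 * x + 0.8 * x**2  # gentle curvature, no peaks
    z = asls_baseline(curve, lam=1e4, p=0.01)
    assert np.max(np.abs(curve - z)) < 0.05 * np.ptp(curve)


def test_asls_recovers_peaks_over_baseline():
    x = np.linspace(0, 1, 400)
    baseline = 5.0 + 3.0 * x - 2.0 * x**2
    peaks = sum(
        a * np.exp(-0.5 * ((x - c) / 0.012) ** 2)
        for a, c in [(4.0, 0.25), (6.0, 0.5), (3.0, 0.75)]
    )
    y = baseline + peaks
    corrected = y - asls_baseline(y, lam=1e4, p=0.001)
    free = peaks < 0.01
    assert np.max(np.abs(corrected[free])) < 0.15
    assert corrected[np.argmax(peaks)] == pytest.approx(peaks.max(), rel=0.1)


def test_asls_baseline_stays_below_peak_apices():
    x = np.linspace(0, 1, 300)
    y = 1.0 + 5.0 * np.exp(-0.5 * ((x - 0.5) / 0.02) ** 2)
    z = asls_baseline(y, lam=1e5, p=0.001)
    apex = np.argmax(y)
    assert z[apex] < y[apex]


def test_asls_nonfinite_raises():
    with pytest.raises(ValueError):
        asls_baseline(np.array([1.0, np.nan, 2.0]))


# ------------------------------------------------------------------ despike
def test_despike_single_spike_replaced_by_neighbor_mean(rng):
    x = np.linspace(0, 1, 80)
    base = np.exp(-0.5 * ((x - 0.5) / 0.15) ** 2) + 0.001 * rng.normal(size=80)
    y = base.copy()
    y[30] += 100 * y.max()
    r = despike_spectrum(y, zmax=8)
    assert r[30] == pytest.approx((y[29] + y[31]) / 2)
    assert np.array_equal(np.delete(r, 30), np.delete(y, 30))


def test_despike_clean_cube_is_identity(rng):
    cube = _cube(rng.random((3, 3, 40)).cumsum(axis=2) / 40)
    out = despike(cube, zmax=8)
    assert np.array_equal(out.data, cube.data)


def test_despike_edge_channel_uses_nearest_value():
    y = np.ones(30)
    y[0] = 500.0
    r = despike_spectrum(y, zmax=8)
    assert r[0] == 1.0
    assert np.array_equal(r[1:], y[1:])


def test_despike_idempotent(rng):
    for _ in range(10):
        y = rng.random(60).cumsum() / 10
        idx = rng.integers(2, 58)
        y[idx] += 50.0
        once = despike_spectrum(y, zmax=8)
        twice = despike_spectrum(once, zmax=8)
        assert np.array_equal(once, twice)


# ---------------------------------------------------------------- bin_pixels
@pytest.mark.parametrize("factor,expected", [(12, 3.0), (3, 0.75)])
def test_binning_reaches_reference_pixel_size(rng, factor, expected):
    """0.25 um fluorescence pixels: 12x binning gives the 3 um reference
    grid; 3x binning gives 0.75 um."""
    n = factor * 2
    cube = _cube(rng.random((n, n, 3)), pixel_size=0.25)
    out = bin_pixels(cube, factor)
    assert out.pixel_size == pytest.approx(expected)


def test_binning_constant_cube_preserves_value():
    cube = _cube(np.full((4, 4, 2), 3.7))
    out = bin_pixels(cube, 2)
    assert out.data.shape == (2, 2, 2)
    np.testing.assert_allclose(out.data, 3.7)


def test_binning_conserves_total_intensity(rng):
    cube = _cube(rng.random((8, 6, 3)))
    out = bin_pixels(cube, 2)
    np.testing.assert_allclose(out.data.sum() * 4, cube.data.sum(), rtol=1e-12)


def test_binning_drops_partial_tiles(rng):
    cube = _cube(rng.random((7, 5, 2)))
    out = bin_pixels(cube, 3)
    assert out.data.shape[:2] == (2, 1)


def test_binning_masked_tile_and_partial_tile_mean(rng):
    data = np.ones((4, 4, 1))
    mask = np.ones((4, 4), dtype=bool)
    mask[:2, :2] = False  # whole tile invalid
    mask[0, 2] = False  # one pixel of another tile invalid
    data[1, 3, 0] = 5.0
    out = bin_pixels(_cube(data, mask=mask), 2)
    assert not out.valid_mask[0, 0]
    # surviving tile averages only its 3 valid pixels
    assert out.data[0, 1, 0] == pytest.approx((1 + 1 + 5) / 3)


def test_binning_factor_exceeding_image_raises(rng):
    with pytest.raises(ValueError):
        bin_pixels(_cube(rng.random((4, 4, 2))), 5)


def test_binning_sum_statistic(rng):
    cube = _cube(np.ones((4, 4, 1)))
    out = bin_pixels(cube, 2, stat="sum")
    np.testing.assert_allclose(out.data, 4.0)


# ------------------------------------------------------------ resample_to_grid
def test_resample_identity_when_sizes_match(small_cube):
    out = resample_to_grid(small_cube, small_cube.pixel_size)
    np.testing.assert_array_equal(out.data, small_cube.data)


def test_resample_constant_image_stays_constant():
    cube = _cube(np.full((6, 6, 2), 2.5), pixel_size=2.0)
    out = resample_to_grid(cube, 3.0)
    assert out.data.shape[:2] == (4, 4)
    np.testing.assert_allclose(out.data, 2.5, rtol=1e-12)
    assert out.pixel_size == 3.0


def _overlap_oracle(data, s_in, s_out):
    """Brute-force overlap-area mean per output pixel (1-D intervals)."""
    ny, nx, J = data.shape
    oy = int(np.floor(ny * s_in / s_out + 1e-9))
    ox = int(np.floor(nx * s_in / s_out + 1e-9))
    out = np.zeros((oy, ox, J))
    for i in range(oy):
        for j in range(ox):
            acc = np.zeros(J)
            wtot = 0.0
            for a in range(ny):
                ovy = min((i + 1) * s_out, (a + 1) * s_in) - max(i * s_out, a * s_in)
                if ovy <= 0:
                    continue
                for b in range(nx):
                    ovx = min((j + 1) * s_out, (b + 1) * s_in) - max(
                        j * s_out, b * s_in
                    )
                    if ovx <= 0:
                        continue
                    acc += ovy * ovx * data[a, b]
                    wtot += ovy * ovx
            out[i, j] = acc / wtot
    return out


def test_resample_step_pattern_matches_overlap_oracle():
    data = np.zeros((6, 6, 2))
    data[:, :3, 0] = 1.0  # vertical step
    data[3:, :, 1] = 2.0  # horizontal step
    cube = _cube(data, pixel_size=2.0)
    out = resample_to_grid(cube, 3.0)
    np.testing.assert_allclose(out.data, _overlap_oracle(data, 2.0, 3.0), rtol=1e-12)


def test_resample_upsampling_raises(small_cube):
    with pytest.raises(ValueError):
        resample_to_grid(small_cube, small_cube.pixel_size / 2)


def test_resample_masked_pixels_carry_zero_weight():
    data = np.ones((6, 6, 1))
    data[0, 0, 0] = 100.0
    mask = np.ones((6, 6), dtype=bool)
    mask[0, 0] = False
    out = resample_to_grid(_cube(data, pixel_size=2.0, mask=mask), 3.0)
    # output (0,0) covers input pixels (0..1, 0..1) minus the masked one
    assert out.data[0, 0, 0] == pytest.approx(1.0)
    assert out.valid_mask.all()
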