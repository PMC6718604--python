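"""Lineshape model, linewidth estimation and the pO2 calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oxymap as ox
from oxymap.spectral import Spectrum, _GAMMA_PER_LWPP


@pytest.mark.parametrize("percent,expected", [(0.0, 0.0), (3.0, 22.8), (21.0, 159.6)])
def test_percent_o2_to_torr_at_standard_pressure(percent, expected):
    assert ox.percent_o2_to_po2(percent) == pytest.approx(expected, abs=1e-12)


def test_percent_o2_rejects_out_of_range():
    with pytest.raises(ValueError):
        ox.percent_o2_to_po2(-1.0)
    with pytest.raises(ValueError):
        ox.percent_o2_to_po2(101.0)


class TestFitCalibration:
    def test_two_point_line_is_exact(self):
        curve = ox.fit_calibration([(0.0, 1.0), (100.0, 2.0)])
        assert curve.intercept == pytest.approx(1.0, abs=1e-12)
        assert curve.slope == pytest.approx(0.01, abs=1e-12)
        assert curve.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_collinear_three_points(self):
        curve = ox.fit_calibration([(0.0, 1.0), (22.8, 1.228), (159.6, 2.596)])
        assert curve.slope == pytest.approx(0.01, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            po2 = rng.uniform(0, 160, size=rng.integers(3, 8))
            lw = 0.8 + 0.01 * po2 + rng.normal(0, 0.02, size=po2.size)
            lw = np.abs(lw) + 0.01
            curve = ox.fit_calibration(list(zip(po2, lw)))
            # closed-form normal equations, evaluated independently
            sx, sy = po2.sum(), lw.sum()
            sxx, sxy = (po2**2).sum(), (po2 * lw).sum()
            n = po2.size
            slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
            intercept = (sy - slope * sx) / n
            assert curve.slope == pytest.approx(slope, abs=1e-10)
            assert curve.intercept == pytest.approx(intercept, abs=1e-10)

    @pytest.mark.parametrize("points,err", [
        ([(5.0, 1.0)], "at least two"),
        ([(5.0, 1.0), (5.0, 1.2)], "degenerate"),
        ([(0.0, 2.0), (100.0, 1.0)], "non-positive"),
        ([(0.0, -1.0), (100.0, 1.0)], "positive"),
    ])
    def test_rejects_bad_inputs(self, points, err):
        with pytest.raises(ValueError, match=err):
            ox.fit_calibration(points)


@settings(max_examples=50, derandomize=True)
@given(po2=st.floats(0.0, 160.0), intercept=st.floats(0.5, 2.0), slope=st.floats(1e-3, 0.05))
def test_calibration_round_trip_identity(po2, intercept, slope):
    curve = ox.CalibrationCurve(intercept=intercept, slope=slope)
    back, clamped = ox.po2_from_linewidth(curve, ox.linewidth_from_po2(curve, po2))
    assert not clamped
    assert abs(back - po2) < 1e-9


def test_linewidth_monotone_in_po2(cal):
    po2 = np.linspace(0, 160, 50)
    lw = cal.linewidth(po2)
    assert np.all(np.diff(lw) > 0)


def test_sub_intercept_linewidth_clamps_to_zero(cal):
    po2, clamped = ox.po2_from_linewidth(cal, cal.intercept * 0.9)
    assert po2 == 0.0
    assert clamped


class TestDerivativeLorentzian:
    axis = np.linspace(388.0, 394.0, 256)

    def test_extrema_separation_equals_lw_pp(self):
        spec = ox.derivative_lorentzian(self.axis, 390.95, 1.7, 1.0)
        est = ox.estimate_linewidth_pp(spec)
        assert est.lw_pp == pytest.approx(1.7, abs=0.5 * spec.step)

    def test_antisymmetric_about_center(self):
        # center on an axis point so symmetry is exact on samples
        axis = np.linspace(-3, 3, 257) + 390.0
        spec = ox.derivative_lorentzian(axis, 390.0, 1.2, 2.0)
        assert spec.intensity[128] == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(spec.intensity[:128], -spec.intensity[129:][::-1],
                                   rtol=1e-12)

    def test_amplitude_scales_linearly(self):
        a = ox.derivative_lorentzian(self.axis, 390.95, 1.2, 1.0).intensity
        b = ox.derivative_lorentzian(self.axis, 390.95, 1.2, 2.0).intensity
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-14)

    def test_under_resolved_flagged(self):
        spec = ox.derivative_lorentzian(self.axis, 390.95, 0.01, 1.0)
        assert "under_resolved" in spec.flags

    def test_rejects_center_off_axis(self):
        with pytest.raises(ValueError):
            ox.derivative_lorentzian(self.axis, 500.0, 1.0, 1.0)


class TestEstimateLinewidth:
    def test_noiseless_lines_recovered_within_half_step(self):
        """100 random (center, lw) draws on a 128-point 5-G axis."""
        rng = np.random.default_rng(3)
        axis = 390.95 + np.linspace(-2.5, 2.5, 128)
        step = axis[1] - axis[0]
        for _ in range(100):
            lw = rng.uniform(4 * step, 2.0)
            center = rng.uniform(390.0, 391.9)
            spec = ox.derivative_lorentzian(axis, center, lw, rng.uniform(0.5, 2))
            est = ox.estimate_linewidth_pp(spec)
            assert est.ok
            assert abs(est.lw_pp - lw) <= 0.5 * step

    def test_superposed_identical_lines_keep_linewidth(self):
        axis = 390.95 + np.linspace(-2.5, 2.5, 128)
        one = ox.derivative_lorentzian(axis, 390.95, 1.5, 1.0)
        two = Spectrum(field_axis=axis, intensity=2.0 * one.intensity)
        assert ox.estimate_linewidth_pp(two).lw_pp == pytest.approx(
            ox.estimate_linewidth_pp(one).lw_pp, abs=1e-12)

    def test_white_noise_flagged_low_signal(self):
        rng = np.random.default_rng(11)
        axis = np.linspace(388, 394, 128)
        spec = Spectrum(field_axis=axis, intensity=rng.normal(0, 1, 128))
        est = ox.estimate_linewidth_pp(spec)
        assert "low_signal" in est.flags

    def test_flat_spectrum_fails(self):
        axis = np.linspace(388, 394, 64)
        est = ox.estimate_linewidth_pp(Spectrum(field_axis=axis, intensity=np.zeros(64)))
        assert not est.ok
        assert "flat" in est.flags

    def test_inverted_phase_flagged(self):
        axis = 390.95 + np.linspace(-2.5, 2.5, 128)
        line = ox.derivative_lorentzian(axis, 390.95, 1.2, 1.0)
        est = ox.estimate_linewidth_pp(Spectrum(field_axis=axis, intensity=-line.intensity))
        assert "inverted" in est.flags

    def test_bounded_search_ignores_distant_artifact(self):
        axis = 390.95 + np.linspace(-2.5, 2.5, 256)
        line = ox.derivative_lorentzian(axis, 390.95, 1.2, 1.0).intensity
        artifact = np.zeros_like(line)
        artifact[5] = 2 * line.max()  # spurious spike near the sweep edge
        spec = Spectrum(field_axis=axis, intensity=line + artifact)
        est = ox.estimate_linewidth_pp(spec, center=390.95, search_halfwidth=1.5)
        assert est.lw_pp == pytest.approx(1.2, abs=0.5 * spec.step)


def test_gamma_lwpp_relation():
    """HWHM = sqrt(3)/2 * peak-to-peak width for a Lorentzian derivative."""
    assert _GAMMA_PER_LWPP == pytest.approx(math.sqrt(3) / 2)


def test_default_calibration_uses_three_oxygen_fractions(cal):
    po2s = sorted(p for p, _ in cal.fit_points)
    assert po2s == pytest.approx([0.0, 22.8, 159.6])
    assert cal.slope > 0
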