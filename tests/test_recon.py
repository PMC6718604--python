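"""Two-stage filtered back-projection and its processing chain."""

import math

import numpy as np
import pytest

import oxymap as ox
from oxymap.recon import _centered_axis, fbp_parallel
from oxymap.spectral import Spectrum


class TestResampleSpectrum:
    def test_constant_row_preserved(self):
        row = np.ones(512)
        np.testing.assert_array_equal(ox.resample_spectrum(row, 128), np.ones(128))

    def test_block_means(self):
        np.testing.assert_array_equal(ox.resample_spectrum(np.array([1.0, 3, 5, 7]), 2), [2.0, 6.0])

    def test_mean_preserved_to_machine_precision(self):
        rng = np.random.default_rng(2)
        row = rng.normal(size=512)
        out = ox.resample_spectrum(row, 128)
        assert out.mean() == pytest.approx(row.mean(), abs=1e-12)

    def test_non_divisible_length_rejected(self):
        with pytest.raises(ValueError):
            ox.resample_spectrum(np.ones(100), 33)


class TestInterpolateProjections:
    def test_factor_one_is_identity(self, small_projection_set):
        out = ox.interpolate_projections(small_projection_set, 1)
        assert out is small_projection_set

    def test_identical_projections_stay_identical(self, small_scheme):
        ps = ox.ProjectionSet(scheme=small_scheme,
                              spectra=np.ones((small_scheme.n_projections, small_scheme.n_points)))
        out = ox.interpolate_projections(ps, 3)
        np.testing.assert_allclose(out.spectra, 1.0, rtol=1e-12)

    def test_midpoint_is_pointwise_mean_along_alpha(self, small_projection_set):
        out = ox.interpolate_projections(small_projection_set, 2)
        sch, osch = small_projection_set.scheme, out.scheme
        a = small_projection_set.spectra.reshape(sch.n_spatial, sch.n_spectral, -1)
        b = out.spectra.reshape(osch.n_spatial, osch.n_spectral, -1)
        # original alpha k maps to index 2k; the inserted row 2k+1 is the mean
        np.testing.assert_allclose(b[0, 1], 0.5 * (a[0, 0] + a[0, 1]), rtol=1e-12)
        # originals appear unchanged (theta index 0 maps to 0 as well)
        np.testing.assert_allclose(b[0, 0], a[0, 0], rtol=1e-15)
        np.testing.assert_allclose(b[0, -1], a[0, -1], rtol=1e-15)

    def test_counts_scale_per_dimension(self, small_projection_set):
        out = ox.interpolate_projections(small_projection_set, 4)
        sch = small_projection_set.scheme
        assert out.scheme.n_spatial == sch.n_spatial * 4
        assert out.scheme.n_spectral == (sch.n_spectral - 1) * 4 + 1


class TestRamLakFilter:
    def test_constant_row_suppressed(self):
        out = ox.ramlak_filter(np.full(128, 3.7), cutoff=0.5)
        assert np.max(np.abs(out)) < 1e-10 * 3.7

    def test_impulse_response_matches_direct_dft_oracle(self):
        n = 64
        row = np.zeros(n)
        row[10] = 1.0
        cutoff = 0.5
        out = ox.ramlak_filter(row, cutoff, spacing=1.0)
        # direct discrete-frequency evaluation
        freqs = np.fft.fftfreq(n)
        ramp = np.abs(freqs)
        ramp[np.abs(freqs) > cutoff * 0.5] = 0.0
        expected = np.real(np.fft.ifft(np.fft.fft(row) * ramp))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=128), rng.normal(size=128)
        lhs = ox.ramlak_filter(a + b, 0.5)
        rhs = ox.ramlak_filter(a, 0.5) + ox.ramlak_filter(b, 0.5)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_rejects_bad_cutoff(self):
        with pytest.raises(ValueError):
            ox.ramlak_filter(np.ones(16), 0.0)


def test_fbp_parallel_agrees_with_skimage_iradon():
    """Cross-check the parallel-beam FBP against an independent
    implementation on a smooth object (compared by correlation: the two
    implementations use different normalization conventions)."""
    skimage_transform = pytest.importorskip("skimage.transform")
    n = 64
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    blob = np.exp(-(((xx - c) ** 2 + (yy - c) ** 2)) / (2 * (0.15 * n) ** 2))
    angles_deg = np.arange(0, 180, 3)
    sino = skimage_transform.radon(blob, theta=angles_deg)  # (ray, angle)
    ref = skimage_transform.iradon(sino, theta=angles_deg, filter_name="ramp",
                                   output_size=n, circle=False)
    r_axis = (np.arange(sino.shape[0]) - (sino.shape[0] - 1) / 2) / n
    out_axis = _centered_axis(n)
    ours = fbp_parallel(sino.T, np.deg2rad(angles_deg), r_axis,
                        out_y=out_axis, out_x=out_axis, cutoff=1.0)
    corr = np.corrcoef(ours.ravel(), ref.ravel())[0, 1]
    assert corr > 0.99


class TestReconstruct:
    def test_all_zero_projections_give_zero_cube(self, small_scheme):
        ps = ox.ProjectionSet(scheme=small_scheme,
                              spectra=np.zeros((small_scheme.n_projections, small_scheme.n_points)))
        cube = ox.reconstruct(ps, ox.ReconConfig(image_size=32))
        np.testing.assert_array_equal(cube.values, 0.0)

    def test_point_source_localized(self, cal):
        w = 33
        po2 = np.full((w, w), 20.0)
        dens = np.zeros((w, w)); dens[10, 22] = 1.0
        ph = ox.OxygenPhantom(po2, dens, dens > 0, 4.24 / w, None)
        scheme = ox.build_scheme(16, 8, 3.0, 4.24, 5.0, 256, 390.95)
        cube = ox.reconstruct(ox.forward_project(ph, cal, scheme), ox.ReconConfig(image_size=w))
        amp = np.abs(cube.values).max(axis=2)
        iy, ix = np.unravel_index(np.argmax(amp), amp.shape)
        assert abs(iy - 10) <= 1 and abs(ix - 22) <= 1

    def test_shift_equivariance(self, cal):
        w = 32
        scheme = ox.build_scheme(16, 8, 3.0, 4.24, 5.0, 256, 390.95)

        def peak_of(dy, dx):
            po2 = np.full((w, w), 20.0)
            dens = np.zeros((w, w)); dens[12 + dy, 14 + dx] = 1.0
            ph = ox.OxygenPhantom(po2, dens, dens > 0, 4.24 / w, None)
            cube = ox.reconstruct(ox.forward_project(ph, cal, scheme), ox.ReconConfig(image_size=w))
            amp = np.abs(cube.values).max(axis=2)
            return np.unravel_index(np.argmax(amp), amp.shape)

        y0, x0 = peak_of(0, 0)
        y1, x1 = peak_of(3, -4)
        assert abs((y1 - y0) - 3) <= 1
        assert abs((x1 - x0) - (-4)) <= 1

    def test_two_point_sources_resolved(self, cal):
        """Sources 3 mm apart at the instrument FOV separate into two peaks."""
        w = 64
        po2 = np.full((w, w), 20.0)
        dens = np.zeros((w, w))
        sep_px = int(round(0.3 / (4.24 / w)))  # 3 mm
        dens[32, 32 - sep_px // 2] = 1.0
        dens[32, 32 + (sep_px - sep_px // 2)] = 1.0
        ph = ox.OxygenPhantom(po2, dens, dens > 0, 4.24 / w, None)
        scheme = ox.build_scheme(16, 8, 3.0, 4.24, 5.0, 256, 390.95)
        cube = ox.reconstruct(ox.forward_project(ph, cal, scheme), ox.ReconConfig(image_size=128))
        amp = np.abs(cube.values).max(axis=2)
        row = amp[64]
        # count strict local maxima above half the global max
        peaks = [i for i in range(1, 127)
                 if row[i] > row[i - 1] and row[i] >= row[i + 1] and row[i] > 0.5 * row.max()]
        assert len(peaks) >= 2

    def test_density_amplitude_correlation(self, cal):
        """Round-trip fidelity on a phantom whose features span >= 3 pixels
        (the density edge is tapered: a binary edge is a sub-pixel feature)."""
        w = 32
        yy, xx = np.mgrid[0:w, 0:w]
        r = np.sqrt((xx - (w - 1) / 2) ** 2 + (yy - (w - 1) / 2) ** 2)
        dens = np.clip((0.4 * w - r) / 3.0, 0, 1)
        dens = 0.5 - 0.5 * np.cos(np.pi * dens)
        ph = ox.OxygenPhantom(np.full((w, w), 20.0), dens, dens > 0, 4.24 / w, None)
        scheme = ox.build_scheme(16, 8, 3.0, 4.24, 5.0, 256, 390.95)
        cube = ox.reconstruct(ox.forward_project(ph, cal, scheme), ox.ReconConfig(image_size=64))
        amp = np.abs(cube.values).max(axis=2)
        truth = np.kron(dens, np.ones((2, 2)))
        corr = np.corrcoef(amp.ravel(), truth.ravel())[0, 1]
        assert corr >= 0.95

    def test_linewidth_recovery_with_complete_fan(self, cal):
        """With pseudo-angles spanning the full range the chain recovers the
        linewidth to a fraction of a spectral step (isolates the inversion
        from the instrument's missing-cone limitation)."""
        ph = ox.make_uniform_phantom(32, po2=20.0)
        g_full = math.tan(1.535) * 5.0 / 4.24
        scheme = ox.build_scheme(16, 28, g_full, 4.24, 5.0, 256, 390.95)
        cube = ox.reconstruct(ox.forward_project(ph, cal, scheme), ox.ReconConfig(image_size=32))
        axis = cube.spectral_axis
        dv = axis[1] - axis[0]
        true_lw = cal.linewidth(20.0)
        errors = []
        for iy in range(32):
            for ix in range(32):
                if ph.density_grid[iy, ix] > 0:
                    est = ox.estimate_linewidth_pp(Spectrum(axis, cube.values[iy, ix]))
                    if est.ok:
                        errors.append(abs(est.lw_pp - true_lw))
        assert np.median(errors) <= 0.5 * dv

    def test_needs_two_angles_per_dimension(self, cal, uniform_disc):
        scheme = ox.build_scheme(1, 1, 3.0, 4.24, 5.0, 256, 390.95)
        ps = ox.forward_project(uniform_disc, cal, scheme)
        with pytest.raises(ValueError):
            ox.reconstruct(ps)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ox.ReconConfig(filter_cutoff=1.5)
        with pytest.raises(ValueError):
            ox.ReconConfig(missing_cone="mirror")
        with pytest.raises(ValueError):
            ox.ReconConfig(interp_factor=0)
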