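import numpy as np
import pytest
from scipy.signal import lfilter

from oisiwc import wavelet
from oisiwc.wavelet import (
    arrow_components,
    build_scale_grid,
    cwt,
    fit_ar1,
    fourier_factor,
    mc_significance,
    morlet_fourier_normalized,
    phase_summary,
    smooth,
    wavelet_coherence,
    xwt,
)


def direct_cwt(x, s, dt, omega0=6.0):
    """Brute-force time-domain convolution with the sampled Morlet wavelet."""
    n = len(x)
    W = np.zeros(n, dtype=complex)
    for i in range(n):
        tau = (np.arange(n) - i) * dt / s
        psi = np.pi ** -0.25 * np.exp(1j * omega0 * tau) * np.exp(-tau ** 2 / 2)
        W[i] = np.sum(x * np.conj(psi)) * np.sqrt(dt / s)
    return W


def ar1_series(seed, n, phi=0.7):
    rng = np.random.default_rng(seed)
    return lfilter([1.0], [1.0, -phi], rng.standard_normal(n + 50))[50:]


class TestScaleGrid:
    def test_two_octave_span_has_25_scales(self):
        g = build_scale_grid(1.0, fmin=1 / 16, fmax=1 / 4, dj=1 / 12)
        assert g.n_scales == 25

    def test_fourier_wavelength_per_unit_scale(self):
        assert fourier_factor(6.0) == pytest.approx(1.0330436, abs=1e-6)
        g = build_scale_grid(10.0)
        np.testing.assert_allclose(g.fourier_freqs,
                                   1.0 / (fourier_factor(6.0) * g.scales))

    def test_grid_spans_requested_band(self):
        g = build_scale_grid(10.0, fmin=0.05, fmax=4.5)
        assert g.fourier_freqs[0] == pytest.approx(4.5)
        assert g.fourier_freqs[-1] <= 0.05 + 1e-12
        assert np.all(np.diff(g.scales) > 0)

    def test_single_scale_when_fmin_equals_fmax(self):
        g = build_scale_grid(10.0, fmin=1.0, fmax=1.0)
        assert g.n_scales == 1

    def test_fmax_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            build_scale_grid(4.0, fmax=4.5)


class TestMorletWavelet:
    def test_zero_for_nonpositive_frequencies(self):
        w = morlet_fourier_normalized(2.0, np.array([-1.0, 0.0, 1.0]), 1.0)
        assert w[0] == 0.0 and w[1] == 0.0 and w[2] > 0.0

    def test_peak_location_and_unnormalized_value(self):
        s, dt = 3.0, 1.0
        om = np.linspace(0.01, 10, 20000)
        w = morlet_fourier_normalized(s, om, dt)
        norm = np.sqrt(2 * np.pi * s / dt)
        peak = om[np.argmax(w)]
        assert peak * s == pytest.approx(6.0, rel=1e-3)
        assert w.max() / norm == pytest.approx(np.pi ** -0.25, rel=1e-6)

    def test_energy_normalization(self):
        n = 1024
        om = 2 * np.pi * np.fft.fftfreq(n, d=1.0)
        for s in (4.0, 8.0, 16.0):
            energy = np.sum(morlet_fourier_normalized(s, om, 1.0) ** 2)
            assert energy / n == pytest.approx(1.0, rel=0.01)


class TestCWT:
    def test_fft_equals_direct_convolution(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(64)
        x = (x - x.mean()) / x.std()
        grid = build_scale_grid(1.0, fmin=1 / 16, fmax=1 / 4, dj=1 / 12)
        spec = cwt(x, grid, detrend=False, standardize=False)
        for j, s in enumerate(grid.scales):
            d = direct_cwt(x, s, 1.0)
            assert np.abs(spec.W[j] - d).max() < 1e-8

    def test_pure_tone_scale_recovery(self):
        fs = 10.0
        t = np.arange(3000) / fs
        grid = build_scale_grid(fs)
        spec = cwt(np.sin(2 * np.pi * 1.67 * t), grid)
        mean_pow = spec.power.mean(axis=1)
        f_at_max = grid.fourier_freqs[np.argmax(mean_pow)]
        step = grid.fourier_freqs[0] / grid.fourier_freqs[1]
        assert 1.67 / step <= f_at_max <= 1.67 * step

    def test_constant_series_warns_and_returns_zeros(self):
        grid = build_scale_grid(10.0, fmin=0.5, fmax=4.0)
        with pytest.warns(UserWarning, match="constant"):
            spec = cwt(np.full(100, 3.0), grid)
        assert np.all(spec.W == 0)

    def test_coi_symmetric_about_center(self):
        grid = build_scale_grid(10.0, fmin=0.5, fmax=4.0)
        spec = cwt(np.random.default_rng(0).normal(size=201), grid)
        np.testing.assert_allclose(spec.coi_scale, spec.coi_scale[::-1])


class TestXWT:
    grid = build_scale_grid(10.0, fmin=0.2, fmax=4.0)

    def test_self_cross_spectrum_phase_zero(self, rng):
        x = rng.normal(size=500)
        wm = cwt(x, self.grid)
        cs = xwt(wm, wm)
        np.testing.assert_allclose(cs.phase, 0.0, atol=1e-12)
        np.testing.assert_allclose(cs.power, np.abs(wm.W) ** 2, rtol=1e-12)

    def test_sign_flip_gives_phase_pi(self, rng):
        x = rng.normal(size=500)
        wm, wn = cwt(x, self.grid), cwt(-x, self.grid)
        cs = xwt(wm, wn)
        pw = cs.power > 1e-12
        assert np.all(np.isclose(np.abs(cs.phase[pw]), np.pi))

    def test_quarter_period_lag_gives_half_pi_phase(self):
        fs, f0 = 10.0, 1.0
        t = np.arange(1500) / fs
        m = np.sin(2 * np.pi * f0 * t)
        n = np.sin(2 * np.pi * f0 * (t - 0.25 / f0))   # first series leads
        wm, wn = cwt(m, self.grid), cwt(n, self.grid)
        cs = xwt(wm, wn)
        j = np.argmin(np.abs(self.grid.fourier_freqs - f0))
        inside = wm.coi_mask()[j]
        mean_phase = np.angle(np.exp(1j * cs.phase[j][inside]).mean())
        assert mean_phase == pytest.approx(np.pi / 2, abs=0.05)
        assert np.angle(np.exp(1j * xwt(wn, wm).phase[j][inside]).mean()) == \
            pytest.approx(-np.pi / 2, abs=0.05)

    def test_grid_mismatch_rejected(self, rng):
        other = build_scale_grid(10.0, fmin=0.5, fmax=4.0)
        with pytest.raises(ValueError):
            xwt(cwt(rng.normal(size=300), self.grid),
                cwt(rng.normal(size=300), other))


class TestSmoothing:
    grid = build_scale_grid(1.0, fmin=0.05, fmax=0.4)

    def test_constant_field_unchanged(self):
        field = np.full((self.grid.n_scales, 150), 2.5)
        np.testing.assert_allclose(smooth(field, self.grid), 2.5, atol=1e-12)

    def test_linearity_under_scalar_multiplication(self, rng):
        field = rng.normal(size=(self.grid.n_scales, 120))
        np.testing.assert_allclose(smooth(3.0 * field, self.grid),
                                   3.0 * smooth(field, self.grid), atol=1e-12)

    def test_impulse_spread_grows_with_scale(self):
        n = 400
        widths = []
        for j in (2, self.grid.n_scales - 3):
            field = np.zeros((self.grid.n_scales, n))
            field[j, n // 2] = 1.0
            out = smooth(field, self.grid)
            row = out[j]
            t = np.arange(n)
            mu = (row * t).sum() / row.sum()
            widths.append(np.sqrt((row * (t - mu) ** 2).sum() / row.sum()))
        assert widths[1] > widths[0]


class TestCoherence:
    grid = build_scale_grid(10.0)

    def test_self_coherence_is_one_inside_coi(self, rng):
        x = rng.normal(size=1500)
        cm = wavelet_coherence(x, x, self.grid)
        assert cm.r2[cm.coi_mask()].min() >= 0.999

    def test_sign_flip_preserves_r2_with_phase_pi(self, rng):
        x = rng.normal(size=1200)
        cm1 = wavelet_coherence(x, x, self.grid)
        cm2 = wavelet_coherence(x, -x, self.grid)
        np.testing.assert_allclose(cm2.r2, cm1.r2, atol=1e-10)
        inside = cm2.coi_mask()
        assert np.all(np.isclose(np.abs(cm2.phase[inside]), np.pi))

    def test_r2_invariant_to_linear_rescaling(self, rng):
        a, b = rng.normal(size=(2, 800))
        cm1 = wavelet_coherence(a, b, self.grid)
        cm2 = wavelet_coherence(5.0 * a + 2.0, -0.3 * b + 1.0, self.grid)
        np.testing.assert_allclose(cm2.r2, cm1.r2, atol=1e-9)

    def test_symmetry_under_argument_swap(self, rng):
        a, b = rng.normal(size=(2, 600))
        cm1 = wavelet_coherence(a, b, self.grid)
        cm2 = wavelet_coherence(b, a, self.grid)
        np.testing.assert_allclose(cm1.r2, cm2.r2, atol=1e-10)
        pw = cm1.r2 > 1e-6
        diff = np.angle(np.exp(1j * (cm1.phase[pw] + cm2.phase[pw])))
        np.testing.assert_allclose(diff, 0.0, atol=1e-8)

    def test_shared_tone_coherence_approaches_one_as_noise_vanishes(self):
        fs = 10.0
        t = np.arange(2000) / fs
        tone = np.sin(2 * np.pi * 0.5 * t)
        rng = np.random.default_rng(3)
        j = np.argmin(np.abs(self.grid.fourier_freqs - 0.5))
        vals = []
        for noise in (1.0, 0.1, 0.001):
            a = tone + noise * rng.normal(size=len(t))
            b = tone + noise * rng.normal(size=len(t))
            cm = wavelet_coherence(a, b, self.grid)
            vals.append(cm.r2[j][cm.coi_mask()[j]].mean())
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] > 0.99

    def test_common_signal_raises_coherence_over_independent_pairs(self):
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 1200
            shared = ar1_series(1000 + seed, n)
            a, b = ar1_series(2 * seed, n), ar1_series(2 * seed + 1, n)
            coupled_a = np.sqrt(0.8) * shared + np.sqrt(0.2) * a
            coupled_b = np.sqrt(0.8) * shared + np.sqrt(0.2) * b
            cm_ind = wavelet_coherence(a, b, self.grid)
            cm_cpl = wavelet_coherence(coupled_a, coupled_b, self.grid)
            inside = cm_ind.coi_mask()
            diffs.append(cm_cpl.r2[inside].mean() - cm_ind.r2[inside].mean())
        assert np.mean(diffs) > 0
        assert np.sum(np.array(diffs) > 0) >= 19


class TestMCSignificance:
    grid = build_scale_grid(10.0, fmin=0.1, fmax=4.0)

    def test_identical_series_flagged_almost_everywhere(self):
        x = ar1_series(5, 800)
        res = mc_significance(x, x, self.grid, n_surrogates=60, seed=0)
        cm = wavelet_coherence(x, x, self.grid)
        assert res.mask[cm.coi_mask()].mean() > 0.95

    def test_mask_confined_to_coi_when_filtering(self):
        a, b = ar1_series(7, 600), ar1_series(8, 600)
        res = mc_significance(a, b, self.grid, n_surrogates=40, seed=0)
        cm = wavelet_coherence(a, b, self.grid)
        assert not np.any(res.mask & ~cm.coi_mask())

    def test_zero_surrogates_rejected(self):
        x = ar1_series(1, 300)
        with pytest.raises(ValueError):
            mc_significance(x, x, self.grid, n_surrogates=0)

    def test_ar1_fit_recovers_phi(self):
        phis = [fit_ar1(ar1_series(s, 20000)) for s in range(5)]
        assert np.mean(phis) == pytest.approx(0.7, abs=0.02)
        rng = np.random.default_rng(0)
        assert fit_ar1(rng.normal(size=20000)) == pytest.approx(0.0, abs=0.03)


class TestPhaseConventions:
    def test_arrow_mapping(self):
        u, v = arrow_components(np.array([0.0, np.pi, np.pi / 2, -np.pi / 2]))
        np.testing.assert_allclose(u, [1, -1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(v, [0, 0, -1, 1], atol=1e-12)

    def test_identical_series_mean_angle_zero(self, rng):
        grid = build_scale_grid(10.0, fmin=0.2, fmax=4.0)
        x = rng.normal(size=800)
        cm = wavelet_coherence(x, x, grid)
        angle, _ = phase_summary(cm, (10, 70), (0.3, 3.0))
        assert angle == pytest.approx(0.0, abs=1e-9)

    def test_leading_series_gives_downward_arrows(self):
        fs, f0 = 10.0, 1.0
        grid = build_scale_grid(fs, fmin=0.2, fmax=4.0)
        t = np.arange(1500) / fs
        m = np.sin(2 * np.pi * f0 * t)
        n = np.sin(2 * np.pi * f0 * (t - 0.25 / f0))
        cm = wavelet_coherence(m, n, grid)
        angle, (u, v) = phase_summary(cm, (30, 120), (0.8, 1.25))
        assert angle == pytest.approx(np.pi / 2, abs=0.1)
        au, av = arrow_components(angle)
        assert av < -0.99 and abs(au) < 0.1     # downward: first series leads

    def test_empty_region_rejected(self, rng):
        grid = build_scale_grid(10.0, fmin=0.2, fmax=4.0)
        cm = wavelet_coherence(rng.normal(size=300), rng.normal(size=300), grid)
        with pytest.raises(ValueError):
            phase_summary(cm, (100.0, 200.0), (0.3, 3.0))
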