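"""Wavelet bank, convolution, binning, baseline normalization, ITPC."""

import numpy as np
import pytest

from tempopred import (align, band_window_average, baseline_normalize,
                       build_bank, convolve, itpc, power_binned)
from tempopred.spectral import BinnedMap, ComplexTFR, EventWindows


def _tfr_from_phases(phases, n_ch=2, n_f=3, n_t=50, freqs=None):
    """Coefficient stack with prescribed per-trial phases (unit magnitude)."""
    n_tr = len(phases)
    coef = np.exp(1j * np.asarray(phases))[:, None, None, None] * \
        np.ones((n_tr, n_ch, n_f, n_t))
    times = np.arange(n_t) * 4.0 - 100.0
    freqs = freqs if freqs is not None else np.array([2.0, 10.0, 20.0])
    valid = np.ones((n_tr, n_f, n_t), bool)
    return ComplexTFR(coef, times, freqs, valid)


class TestBank:
    def test_defaults_are_the_printed_grid(self):
        b = build_bank()
        assert b.n_freqs == 40
        assert b.freqs[0] == 0.5 and b.freqs[-1] == 100.0
        assert b.cycles[0] == 2.0 and b.cycles[-1] == 10.0
        assert np.all(np.diff(b.freqs) > 0)

    def test_two_wavelets_endpoints_only(self):
        b = build_bank(n=2)
        np.testing.assert_allclose(b.freqs, [0.5, 100.0])
        np.testing.assert_allclose(b.cycles, [2.0, 10.0])

    def test_log_spacing_closed_form(self):
        b = build_bank()
        assert b.freqs[20] == pytest.approx(0.5 * 200 ** (20 / 39), rel=1e-12)

    def test_unit_energy_kernels(self):
        b = build_bank(n=10, fs=500)
        for k in b.kernels:
            assert np.sum(np.abs(k) ** 2) == pytest.approx(1.0, abs=1e-12)

    def test_kernel_autocorrelation_peaks_at_zero_lag(self):
        b = build_bank(n=5, fs=500)
        k = b.kernels[3]
        ac = np.correlate(k, k, mode="full")
        mid = len(ac) // 2
        assert np.abs(ac).argmax() == mid
        assert np.abs(ac[mid]) == pytest.approx(1.0, abs=1e-12)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            build_bank(f_max=200.0, fs=250)


class TestConvolve:
    def test_sinusoid_peaks_at_nearest_center(self):
        fs = 500.0
        t = np.arange(4000) / fs
        ep = np.sin(2 * np.pi * 10 * t)[None, :]
        b = build_bank(2, 50, 16, fs=fs)
        c, v = convolve(ep, b)
        pw = (np.abs(c[0]) ** 2)[:, 1500:2500].mean(axis=1)
        est = b.freqs[pw.argmax()]
        grid_step = b.freqs[1] / b.freqs[0]
        assert 10.0 / grid_step <= est <= 10.0 * grid_step

    def test_amplitude_doubling_quadruples_power(self):
        fs = 250.0
        rng = np.random.default_rng(3)
        ep = rng.standard_normal((2, 2000))
        b = build_bank(2, 40, 6, fs=fs)
        c1, _ = convolve(ep, b)
        c2, _ = convolve(2 * ep, b)
        np.testing.assert_allclose(np.abs(c2) ** 2, 4 * np.abs(c1) ** 2,
                                   rtol=1e-10)

    def test_dc_epoch_near_zero_power(self):
        fs = 250.0
        b = build_bank(1, 40, 6, fs=fs)
        t = np.arange(3000) / fs
        dc, _ = convolve(np.full((1, 3000), 7.0), b)
        sine, _ = convolve(7.0 * np.sin(2 * np.pi * 5 * t)[None, :], b)
        mid = slice(1200, 1800)
        assert (np.abs(dc[0, :, mid]) ** 2).max() < \
            1e-3 * (np.abs(sine[0, :, mid]) ** 2).max()

    def test_edge_mask_tracks_kernel_support(self):
        b = build_bank(1, 40, 6, fs=250)
        _, v = convolve(np.zeros((1, 2000)), b)
        hw_samples = (np.array([len(k) for k in b.kernels]) - 1) // 2
        for i, hw in enumerate(hw_samples):
            assert v[i, :hw].sum() == 0
            assert v[i, hw] if hw < 2000 else True
        # masked set grows toward low frequencies
        assert v.sum(axis=1)[0] <= v.sum(axis=1)[-1]


class TestBinning:
    def _map(self, window, fs=1000.0):
        n_t = int((window[1] - window[0]) * fs / 1000)
        coef = np.ones((3, 2, 4, n_t), complex)
        times = window[0] + np.arange(n_t) * 1000.0 / fs
        tfr = ComplexTFR(coef, times, np.array([1.0, 4, 10, 20]),
                         np.ones((3, 4, n_t), bool))
        return power_binned(tfr)

    def test_movement_window_has_10_bins(self):
        assert self._map((-50.0, 950.0)).values.shape[-1] == 10

    def test_reappearance_window_has_8_bins(self):
        assert self._map((-350.0, 450.0)).values.shape[-1] == 8

    def test_bin_centers_at_left_plus_50(self):
        mp = self._map((-50.0, 950.0))
        assert mp.bin_centers_ms[0] == 0.0
        np.testing.assert_allclose(np.diff(mp.bin_centers_ms), 100.0)

    def test_identical_trials_average_equals_single(self, rng):
        coef = rng.standard_normal((1, 2, 3, 200)) + \
            1j * rng.standard_normal((1, 2, 3, 200))
        coef = np.repeat(coef, 5, axis=0)
        times = np.arange(200.0)
        tfr1 = ComplexTFR(coef[:1], times, np.arange(3) + 1.0,
                          np.ones((1, 3, 200), bool))
        tfr5 = ComplexTFR(coef, times, np.arange(3) + 1.0,
                          np.ones((5, 3, 200), bool))
        np.testing.assert_allclose(power_binned(tfr5).values,
                                   power_binned(tfr1).values)


class TestBaseline:
    def _maps(self, P, B):
        freqs = np.array([10.0])
        mk = lambda vals: BinnedMap(np.asarray(vals, float), np.arange(
            vals.shape[-1]) * 100.0 + 50, freqs, "power",
            np.ones((1, vals.shape[-1]), bool))
        return mk(P), mk(B)

    def test_equal_to_baseline_gives_zero(self):
        P = np.full((2, 1, 5), 3.0)
        mp, base = self._maps(P, P)
        out = baseline_normalize(mp, base, "relative")
        np.testing.assert_allclose(out.values, 0.0)

    def test_doubling_gives_3db(self):
        B = np.full((1, 1, 4), 2.0)
        mp, base = self._maps(2 * B, B)
        out = baseline_normalize(mp, base, "db")
        np.testing.assert_allclose(out.values, 10 * np.log10(2), rtol=1e-12)

    def test_zscore_standardizes(self):
        rng = np.random.default_rng(0)
        B = rng.uniform(1, 2, (1, 1, 6))
        mp, base = self._maps(B.copy(), B)
        out = baseline_normalize(mp, base, "zscore")
        assert out.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.values.std() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_baseline_rejected(self):
        B = np.zeros((1, 1, 3))
        mp, base = self._maps(np.ones((1, 1, 3)), B)
        with pytest.raises(ValueError):
            baseline_normalize(mp, base, "relative")


class TestITPC:
    def test_identical_trials_is_exactly_one(self):
        tfr = _tfr_from_phases([0.7] * 20)
        assert np.all(itpc(tfr).values == 1.0)

    def test_common_rotation_invariance(self, rng):
        phases = rng.uniform(-np.pi, np.pi, 15)
        a = itpc(_tfr_from_phases(phases)).values
        b = itpc(_tfr_from_phases(phases + 1.234)).values
        np.testing.assert_array_equal(a, b)

    def test_trial_order_invariance(self, rng):
        phases = rng.uniform(-np.pi, np.pi, 12)
        a = itpc(_tfr_from_phases(phases)).values
        b = itpc(_tfr_from_phases(phases[::-1])).values
        np.testing.assert_allclose(a, b, atol=1e-15)

    @pytest.mark.parametrize("n_trials", [20, 470])
    def test_uniform_phase_expectation(self, n_trials):
        """E[ITPC] for iid uniform phases approaches sqrt(pi)/(2 sqrt(N))."""
        rng = np.random.default_rng(n_trials)
        vals = []
        for _ in range(400):
            ph = rng.uniform(-np.pi, np.pi, n_trials)
            vals.append(np.abs(np.exp(1j * ph).mean()))
        expect = np.sqrt(np.pi) / (2 * np.sqrt(n_trials))
        sem = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expect) < 4 * sem

    def test_bounded(self, rng):
        tfr = _tfr_from_phases(rng.uniform(-np.pi, np.pi, 30))
        v = itpc(tfr).values
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            itpc(_tfr_from_phases([0.0]))


class TestBandWindowAverage:
    def _map(self):
        freqs = np.array([1.0, 2.0, 4.0, 10.0, 20.0])
        vals = np.arange(2 * 5 * 6, dtype=float).reshape(2, 5, 6)
        centers = np.arange(6) * 100.0 - 250.0
        return BinnedMap(vals, centers, freqs, "itpc", np.ones((5, 6), bool))

    def test_single_cell_identity(self):
        mp = self._map()
        out = band_window_average(mp, (10.0, 10.0), (-250.0, -250.0))
        np.testing.assert_allclose(out, mp.values[:, 3, 0])

    def test_uniform_map_gives_constant(self):
        mp = self._map()
        mp.values[:] = 5.5
        np.testing.assert_allclose(
            band_window_average(mp, (1, 20), (-250, 250)), 5.5)

    def test_delta_selection_count_on_default_grid(self):
        """#frequencies <= 4 Hz on the 40-point log grid: floor(39 log(8)/log(200)) + 1."""
        b = build_bank()
        expected = int(np.floor(39 * np.log(4 / 0.5) / np.log(200))) + 1
        assert ((b.freqs >= 0.5) & (b.freqs <= 4.0)).sum() == expected

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            band_window_average(self._map(), (100.0, 200.0), (-250, 250))


class TestWindows:
    def test_printed_windows(self):
        w = EventWindows()
        assert w.baseline == (-550.0, -50.0)
        assert w.movement == (-50.0, 950.0)
        assert w.disappearance == (-350.0, 950.0)
        assert w.reappearance == (-350.0, 450.0)
        assert w.norm_baseline == (-500.0, -200.0)

    def test_hdf5_roundtrip(self, tmp_path, rng):
        vals = rng.standard_normal((3, 4, 5))
        mp = BinnedMap(vals, np.arange(5) * 100.0, np.arange(4) + 1.0,
                       "power", np.ones((4, 5), bool))
        p = str(tmp_path / "maps.h5")
        mp.to_hdf5(p)
        back = BinnedMap.from_hdf5(p)
        np.testing.assert_array_equal(back.values, vals)
        assert back.kind == "power"
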