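"""FSC computation, SNR conversion, Ne regression and power-law fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doseweight import (
    FSCCurve,
    SNRSeries,
    compute_fsc,
    estimate_critical_exposure,
    fit_power_law,
    fsc_to_snr,
    resolution_at_threshold,
    snr_to_fsc,
)


class TestComputeFSC:
    def test_self_correlation_is_one(self, small_reference):
        curve = compute_fsc(small_reference, small_reference, 1.0)
        np.testing.assert_allclose(curve.fsc, 1.0, atol=1e-10)

    def test_independent_noise_near_zero(self, rng):
        fscs = []
        for _ in range(30):
            a = rng.normal(size=(32, 32))
            b = rng.normal(size=(32, 32))
            fscs.append(compute_fsc(a, b, 1.0).fsc)
        fscs = np.array(fscs)
        curve = compute_fsc(rng.normal(size=(32, 32)),
                            rng.normal(size=(32, 32)), 1.0)
        sigma = 1.0 / np.sqrt(curve.n_voxels / 2.0)
        # mean near zero, spread on the order of 1/sqrt(n/2)
        assert np.all(np.abs(fscs.mean(axis=0)) < 4 * sigma / np.sqrt(30))
        mid = slice(4, 12)
        assert np.all(fscs.std(axis=0)[mid] < 2.5 * sigma[mid])

    def test_known_snr_matches_closed_form(self, small_reference, rng):
        # shared signal + independent noise: E[FSC] = s / (s + 1) with s
        # the per-map shell SNR
        signal = small_reference
        sigma = 0.5
        fscs = []
        for _ in range(60):
            a = signal + rng.normal(0, sigma, signal.shape)
            b = signal + rng.normal(0, sigma, signal.shape)
            fscs.append(compute_fsc(a, b, 1.0).fsc)
        mean_fsc = np.mean(fscs, axis=0)
        curve = compute_fsc(signal, signal, 1.0)
        fa = np.fft.fft2(signal)
        from doseweight.movie_io import ShellIndex

        shells = ShellIndex.for_shape(signal.shape, 1.0)
        p_sig = shells.sum_per_shell(np.abs(fa) ** 2)[1:] / \
            shells.counts[1:]
        p_noise = sigma**2 * signal.size
        s = p_sig / p_noise
        expected = s / (s + 1)
        mid = slice(2, 20)
        np.testing.assert_allclose(mean_fsc[mid], expected[mid], atol=0.06)

    def test_mask_applied_and_validated(self, small_reference, rng):
        mask = np.ones_like(small_reference)
        curve = compute_fsc(small_reference, small_reference, 1.0,
                            mask=mask)
        np.testing.assert_allclose(curve.fsc, 1.0, atol=1e-10)
        with pytest.raises(ValueError, match="0, 1|\\[0, 1\\]"):
            compute_fsc(small_reference, small_reference, 1.0,
                        mask=2 * mask)

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            compute_fsc(rng.normal(size=(16, 16)),
                        rng.normal(size=(32, 32)), 1.0)

    def test_works_in_3d(self, rng):
        vol = rng.normal(size=(16, 16, 16))
        curve = compute_fsc(vol, vol, 2.0)
        np.testing.assert_allclose(curve.fsc, 1.0, atol=1e-10)
        assert curve.frequencies[-1] == pytest.approx(8 / (16 * 2.0))


class TestFSCToSNR:
    @pytest.mark.parametrize("fsc,snr", [(0.5, 2.0), (1 / 3, 1.0),
                                         (0.0, 0.0)])
    def test_direct_substitutions(self, fsc, snr):
        assert fsc_to_snr(fsc) == pytest.approx(snr)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-0.99, 0.999))
    def test_round_trip_identity(self, fsc):
        assert snr_to_fsc(fsc_to_snr(fsc)) == pytest.approx(fsc, abs=1e-12)

    def test_saturation_and_domain(self):
        with pytest.warns(UserWarning):
            assert fsc_to_snr(1.0) == np.inf
        with pytest.raises(ValueError):
            fsc_to_snr(-1.0)

    def test_monotone(self):
        values = fsc_to_snr(np.linspace(-0.5, 0.9, 20))
        assert np.all(np.diff(values) > 0)


class TestResolutionAtThreshold:
    def _curve(self, freqs, fsc):
        return FSCCurve(frequencies=np.asarray(freqs),
                        fsc=np.asarray(fsc),
                        n_voxels=np.full(len(freqs), 100))

    def test_step_drop_at_known_frequency(self):
        k_cross = 1 / 2.59
        freqs = np.linspace(0.01, 0.49, 100)
        fsc = np.where(freqs < k_cross, 0.9, 0.0)
        res = resolution_at_threshold(self._curve(freqs, fsc), 0.143)
        assert res == pytest.approx(2.59, abs=0.05)

    def test_interpolated_crossing_matches_closed_form(self):
        # linear FSC: fsc = 1 - 2k crosses 0.5 exactly at k = 0.25
        freqs = np.linspace(0.05, 0.45, 9)
        fsc = 1 - 2 * freqs
        res = resolution_at_threshold(self._curve(freqs, fsc), 0.5)
        assert res == pytest.approx(4.0, rel=1e-6)

    def test_never_crossing_reports_nyquist_with_warning(self):
        freqs = np.linspace(0.05, 0.5, 10)
        with pytest.warns(UserWarning, match="Nyquist"):
            res = resolution_at_threshold(
                self._curve(freqs, np.full(10, 0.9)), 0.5)
        assert res == pytest.approx(2.0)

    def test_bad_threshold_rejected(self):
        curve = self._curve([0.1, 0.2], [0.9, 0.1])
        with pytest.raises(ValueError):
            resolution_at_threshold(curve, 1.5)


class TestFSCCurveCSV:
    def test_round_trip(self, tmp_path):
        curve = FSCCurve(frequencies=np.array([0.1, 0.2, 0.3]),
                         fsc=np.array([0.9, 0.5, 0.1]),
                         n_voxels=np.array([10, 20, 30]),
                         exposure=12.5)
        path = tmp_path / "fsc.csv"
        curve.to_csv(path)
        again = FSCCurve.from_csv(path)
        np.testing.assert_allclose(again.fsc, curve.fsc)
        assert again.exposure == pytest.approx(12.5)


class TestEstimateCriticalExposure:
    def _series(self, ne_per_shell, exposures, s0=100.0):
        freqs = np.linspace(0.05, 0.4, len(ne_per_shell))
        snr = s0 * np.exp(-np.asarray(exposures)[None, :]
                          / np.asarray(ne_per_shell)[:, None])
        return SNRSeries(frequencies=freqs, exposures=np.asarray(exposures),
                         snr=snr, n_voxels=np.full(len(freqs), 500))

    def test_exact_exponential_recovered_to_machine_precision(self):
        series = self._series([5.0, 12.0], np.linspace(1, 30, 15))
        fit = estimate_critical_exposure(series)
        np.testing.assert_allclose(fit.ne, [5.0, 12.0], rtol=1e-10)
        assert np.all(fit.shells[fit.shells["retained"]]["slope"] < 0)

    def test_noisy_monte_carlo_recovery(self, rng):
        # 100 replicates with multiplicative SNR noise: mean Ne within 5%
        exposures = np.linspace(1, 60, 30)
        estimates = []
        for _ in range(100):
            snr = 50.0 * np.exp(-exposures / 10.0) \
                * np.exp(rng.normal(0, 0.2, exposures.shape))
            series = SNRSeries(frequencies=np.array([0.2]),
                               exposures=exposures, snr=snr[None, :],
                               n_voxels=np.array([500]))
            fit = estimate_critical_exposure(series)
            estimates.append(fit.ne[0])
        assert np.mean(estimates) == pytest.approx(10.0, rel=0.05)

    def test_flat_series_dropped(self):
        exposures = np.linspace(1, 30, 10)
        snr = np.full((1, 10), 4.0)
        series = SNRSeries(frequencies=np.array([0.2]),
                           exposures=exposures, snr=snr,
                           n_voxels=np.array([500]))
        with pytest.raises(ValueError, match="no shell"):
            estimate_critical_exposure(series)

    def test_start_exposure_excludes_early_points(self):
        # early points corrupted (motion-like): excluding them fixes Ne
        exposures = np.linspace(1, 40, 20)
        snr = 100 * np.exp(-exposures / 8.0)
        snr[exposures < 10] *= 0.2  # early-frame degradation
        series = SNRSeries(frequencies=np.array([0.2]),
                           exposures=exposures, snr=snr[None, :],
                           n_voxels=np.array([500]))
        biased = estimate_critical_exposure(series).ne[0]
        clean = estimate_critical_exposure(series, start_exposure=10.0).ne[0]
        assert abs(clean - 8.0) < 1e-9
        assert abs(biased - 8.0) > 0.1

    def test_censoring_respects_noise_floor(self):
        exposures = np.linspace(1, 50, 25)
        snr = 10 * np.exp(-exposures / 5.0)
        series = SNRSeries(frequencies=np.array([0.2]),
                           exposures=exposures, snr=snr[None, :],
                           n_voxels=np.array([50]))
        fit = estimate_critical_exposure(series, noise_sigma_mult=3.0)
        floor = series.noise_floor_snr(3.0)[0]
        used = fit.shells.iloc[0]["n_points"]
        assert used == int(np.sum(snr > floor))

    def test_weighted_variant_close_on_clean_data(self):
        series = self._series([7.0], np.linspace(1, 30, 12))
        plain = estimate_critical_exposure(series).ne[0]
        weighted = estimate_critical_exposure(series, weighted=True).ne[0]
        assert plain == pytest.approx(7.0, rel=1e-9)
        assert weighted == pytest.approx(7.0, rel=1e-9)


class TestFitPowerLaw:
    def test_exact_samples_recovered(self):
        k = np.linspace(0.05, 0.45, 20)
        ne = 0.245 * k**-1.665 + 2.81
        fit = fit_power_law(k, ne)
        assert fit.a == pytest.approx(0.245, rel=1e-5)
        assert fit.b == pytest.approx(-1.665, rel=1e-5)
        assert fit.c == pytest.approx(2.81, rel=1e-5)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert not fit.degenerate

    def test_constant_input_flagged_degenerate(self):
        k = np.linspace(0.05, 0.45, 10)
        fit = fit_power_law(k, np.full(10, 3.0))
        assert fit.degenerate

    def test_noisy_monte_carlo_medians(self, rng):
        k = np.linspace(0.05, 0.45, 25)
        truth = 0.245 * k**-1.665 + 2.81
        results = []
        for _ in range(50):
            ne = truth * np.exp(rng.normal(0, 0.05, k.shape))
            fit = fit_power_law(k, ne)
            results.append((fit.a, fit.b, fit.c))
        med = np.median(results, axis=0)
        assert med[0] == pytest.approx(0.245, rel=0.1)
        assert med[1] == pytest.approx(-1.665, rel=0.1)
        assert med[2] == pytest.approx(2.81, rel=0.1)

    def test_too_few_shells_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([0.1, 0.2, 0.3], [5, 4, 3])

    def test_sigma_weighting_prefers_precise_shells(self):
        k = np.linspace(0.05, 0.45, 12)
        ne = 0.245 * k**-1.665 + 2.81
        ne_corrupt = ne.copy()
        ne_corrupt[-1] *= 2.0  # one wild shell with huge stated error
        sigma = np.full(12, 0.01)
        sigma[-1] = 10.0
        fit = fit_power_law(k, ne_corrupt, sigma=sigma)
        assert fit.c == pytest.approx(2.81, rel=0.02)
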