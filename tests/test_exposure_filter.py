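"""Exposure filter: weights, filtered sums, Wiener/CTF combinations."""

import numpy as np
import pytest

from doseweight import (
    DoseModelParams,
    ExposureSchedule,
    FrameFourier,
    ShellIndex,
    attenuation_factor,
    critical_exposure,
    filter_movie,
    filtered_sum,
    frame_weights,
    frames_from_stack,
    reconstruction_weights,
    relative_snr_of_plain_sum,
    wiener_filtered_sum,
)
from doseweight.exposure_filter import per_shell_weight_table
from doseweight.movie_io import MovieStack, radial_frequency_grid


def _frames(images, exposures, ctfs=None):
    out = []
    for i, (img, n) in enumerate(zip(images, exposures)):
        ctf = None if ctfs is None else ctfs[i]
        out.append(FrameFourier(ft=np.fft.fft2(img), exposure=n, ctf=ctf))
    return out


class TestFrameWeights:
    def test_zero_exposure_unit_weight(self):
        k = np.array([0.05, 0.2, 0.4])
        w = frame_weights(k, [0.0, 10.0])
        np.testing.assert_allclose(w[0], 1.0)

    def test_double_monotonicity(self):
        k = np.array([0.05, 0.4])
        w = frame_weights(k, [5.0, 40.0])
        assert w[1, 1] < w[0, 1] < w[0, 0]  # later frame, higher k decay
        assert w[1, 1] < w[1, 0]

    def test_composes_with_dose_model_oracle(self):
        w = frame_weights(np.array([1 / 3]), [53.0])
        assert w[0, 0] == pytest.approx(
            np.exp(-53.0 / (2 * 4.336064794317294)), rel=1e-9)


class TestFilteredSum:
    def test_single_frame_identity(self, rng):
        img = rng.normal(size=(32, 32))
        out = filtered_sum(_frames([img], [7.0]), pixel_size=1.0)
        np.testing.assert_allclose(out, img, atol=1e-10)

    def test_equal_exposures_reduce_to_scaled_plain_sum(self, rng):
        # identical exposures make every weight equal: sum / sqrt(n)
        imgs = [rng.normal(size=(16, 16)) for _ in range(4)]
        frames = [FrameFourier(np.fft.fft2(im), exposure=5.0)
                  for im in imgs]
        out = filtered_sum(frames, pixel_size=1.0)
        np.testing.assert_allclose(out, np.sum(imgs, axis=0) / 2.0,
                                   atol=1e-6)

    def test_unit_noise_variance_preserved(self, rng):
        # Monte Carlo: white-noise frames with a real exposure schedule;
        # the sqrt normalization keeps output variance at 1
        n, n_frames = 64, 10
        exposures = ExposureSchedule(per_frame=5.3).accumulated_all(n_frames)
        variances = []
        for _ in range(30):
            imgs = [rng.normal(size=(n, n)) for _ in range(n_frames)]
            frames = _frames(imgs, exposures)
            out = filtered_sum(frames, pixel_size=1.0)
            variances.append(out.var())
        assert np.mean(variances) == pytest.approx(1.0, abs=0.02)

    def test_nosqrt_variant_differs(self, rng):
        imgs = [rng.normal(size=(16, 16)) for _ in range(3)]
        frames = _frames(imgs, [1.0, 2.0, 3.0])
        a = filtered_sum(frames, 1.0, variant="sqrt")
        b = filtered_sum(frames, 1.0, variant="nosqrt")
        assert not np.allclose(a, b)

    def test_empty_and_mismatched_inputs(self, rng):
        with pytest.raises(ValueError):
            filtered_sum([], pixel_size=1.0)
        f1 = FrameFourier(np.fft.fft2(rng.normal(size=(8, 8))), 1.0)
        f2 = FrameFourier(np.fft.fft2(rng.normal(size=(16, 16))), 2.0)
        with pytest.raises(ValueError):
            filtered_sum([f1, f2], pixel_size=1.0)

    def test_matched_filter_is_optimal(self):
        # at fixed frequency, SNR(w) = (sum w q)^2 / sum w^2 is
        # maximized by w proportional to q: compare against a random
        # search over 4-frame weight vectors
        rng = np.random.default_rng(1)
        k = 0.3
        exposures = np.array([5.0, 15.0, 25.0, 35.0])
        q = attenuation_factor(k, exposures)
        snr = lambda w: (w @ q) ** 2 / (w @ w)
        best_random = max(snr(rng.uniform(0, 1, 4)) for _ in range(2000))
        assert snr(q) >= best_random - 1e-12
        assert snr(q) == pytest.approx(q @ q)  # Cauchy-Schwarz equality


class TestWienerFilteredSum:
    def test_infinite_snr_limit(self, rng):
        imgs = [rng.normal(size=(16, 16)) for _ in range(3)]
        frames = _frames(imgs, [2.0, 4.0, 6.0])
        out = wiener_filtered_sum(frames, 1.0, snr=np.inf)
        k = radial_frequency_grid((16, 16), 1.0)
        q = frame_weights(k, [2.0, 4.0, 6.0])
        expected = np.fft.ifft2(
            sum(qi * f.ft for qi, f in zip(q, frames)) / (q**2).sum(axis=0)
        ).real
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_zero_snr_limit_is_zero_not_nan(self, rng):
        imgs = [rng.normal(size=(16, 16)) for _ in range(2)]
        frames = _frames(imgs, [1.0, 2.0])
        out = wiener_filtered_sum(frames, 1.0, snr=0.0)
        assert np.all(np.isfinite(out))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_small_snr_proportional_to_weighted_sum(self, rng):
        # as SNR -> 0 the output tends to SNR * sum(q F) per shell
        imgs = [rng.normal(size=(16, 16)) for _ in range(2)]
        frames = _frames(imgs, [1.0, 2.0])
        eps = 1e-6
        out = wiener_filtered_sum(frames, 1.0, snr=eps)
        k = radial_frequency_grid((16, 16), 1.0)
        q = frame_weights(k, [1.0, 2.0])
        expected = np.fft.ifft2(
            eps * sum(qi * f.ft for qi, f in zip(q, frames))).real
        np.testing.assert_allclose(out, expected, rtol=1e-4, atol=1e-12)

    def test_two_frame_hand_evaluated(self):
        # 2x2 toy in Fourier space directly, scalar mid-range SNR
        f1 = np.array([[4.0 + 0j, 2.0], [2.0, 1.0]])
        f2 = np.array([[2.0 + 0j, 1.0], [1.0, 0.5]])
        frames = [FrameFourier(f1, 0.0), FrameFourier(f2, 10.0)]
        px = 1.0
        k = radial_frequency_grid((2, 2), px)
        q1 = np.asarray(attenuation_factor(k, 0.0))
        q2 = np.asarray(attenuation_factor(k, 10.0))
        snr = 3.0
        expected_ft = (q1 * f1 + q2 * f2) / (q1**2 + q2**2 + 1 / snr)
        out = wiener_filtered_sum(frames, px, snr=snr)
        np.testing.assert_allclose(out, np.fft.ifft2(expected_ft).real,
                                   atol=1e-12)


class TestReconstructionWeights:
    def test_unit_ctf_reduces_to_wiener(self, rng):
        imgs = [rng.normal(size=(16, 16)) for _ in range(3)]
        ones = np.ones((16, 16))
        frames = _frames(imgs, [1.0, 5.0, 9.0], ctfs=[ones] * 3)
        combined = reconstruction_weights(frames, 1.0, snr=4.0)
        wiener = wiener_filtered_sum(frames, 1.0, snr=4.0)
        np.testing.assert_allclose(np.fft.ifft2(combined).real, wiener,
                                   atol=1e-10)

    def test_single_frame_huge_snr_divides_ctf(self, rng):
        img = rng.normal(size=(16, 16))
        ctf = 0.3 + 0.6 * np.abs(np.cos(
            np.linspace(0, 4, 256).reshape(16, 16)))
        frames = _frames([img], [3.0], ctfs=[ctf])
        combined = reconstruction_weights(frames, 1.0, snr=np.inf)
        k = radial_frequency_grid((16, 16), 1.0)
        q = np.asarray(attenuation_factor(k, 3.0))
        np.testing.assert_allclose(combined, np.fft.fft2(img) / (ctf * q),
                                   rtol=1e-8)

    def test_two_frames_opposite_ctf_signs_hand_evaluated(self):
        f1 = np.full((2, 2), 2.0 + 0j)
        f2 = np.full((2, 2), 3.0 + 0j)
        c1 = np.full((2, 2), 0.8)
        c2 = np.full((2, 2), -0.6)
        frames = [FrameFourier(f1, 0.0, ctf=c1),
                  FrameFourier(f2, 5.0, ctf=c2)]
        k = radial_frequency_grid((2, 2), 1.0)
        q1 = np.asarray(attenuation_factor(k, 0.0))
        q2 = np.asarray(attenuation_factor(k, 5.0))
        snr = 2.0
        expected = (c1 * q1 * f1 + c2 * q2 * f2) / (
            (np.abs(c1) * q1)**2 + (np.abs(c2) * q2)**2 + 1 / snr)
        out = reconstruction_weights(frames, 1.0, snr=snr)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_missing_ctf_rejected(self, rng):
        frames = _frames([rng.normal(size=(8, 8))], [1.0])
        with pytest.raises(ValueError, match="CTF"):
            reconstruction_weights(frames, 1.0, snr=1.0)


class TestRelativeSNR:
    def test_equal_weights_give_unity(self):
        assert relative_snr_of_plain_sum([3.0] * 5, k=0.2) \
            == pytest.approx(1.0)

    def test_one_dead_frame_halves(self):
        # second frame at effectively infinite exposure: q = (1, 0)
        params = DoseModelParams()
        exposures = [1e-9, 1e9]
        assert relative_snr_of_plain_sum(exposures, 0.3, params) == \
            pytest.approx(0.5, abs=1e-6)

    def test_proteasome_schedule_at_3A(self):
        exposures = ExposureSchedule(per_frame=53 / 38).accumulated_all(38)
        ratio = relative_snr_of_plain_sum(exposures, 1 / 3)
        assert ratio == pytest.approx(0.3265042276488094, rel=1e-9)


class TestMovieLevel:
    def test_filter_commutes_with_shifting(self, rng):
        # weighting and sub-pixel shifting are both diagonal in Fourier
        # space, so filter-then-shift equals shift-then-filter
        from doseweight import ShiftTrajectory, shift_image

        frames = rng.normal(size=(3, 16, 16)).astype(np.float32)
        stack = MovieStack(frames, pixel_size=1.0)
        sched = ExposureSchedule(per_frame=2.0)
        traj = ShiftTrajectory(np.array([[0.5, -0.25], [0.0, 0.0],
                                         [-0.5, 0.25]]), pixel_size=1.0)
        shifted_first = MovieStack(
            np.stack([shift_image(f.astype(float), *traj.shifts_px[i])
                      for i, f in enumerate(frames)]).astype(np.float32),
            pixel_size=1.0)
        a = filter_movie(stack, sched, traj=traj)
        b = filter_movie(shifted_first, sched, traj=None)
        np.testing.assert_allclose(a, b, atol=1e-4)

    def test_weight_table_shape_and_dc(self):
        shells = ShellIndex.for_shape((32, 32), 1.0)
        table = per_shell_weight_table(shells, [1.0, 2.0])
        assert list(table.columns) == ["frequency_invA", "q_frame_1",
                                       "q_frame_2"]
        assert len(table) == shells.n_shells
        # DC row uses the first shell's weight, never more than it
        assert table["q_frame_2"].iloc[0] == pytest.approx(
            table["q_frame_2"].iloc[1])

    def test_frame_exposures_follow_schedule(self):
        sched = ExposureSchedule(per_frame=0.77)
        frames = frames_from_stack(
            MovieStack(np.zeros((3, 8, 8), dtype=np.float32) + 1.0, 1.0),
            sched)
        assert frames[2].exposure == pytest.approx(2.31)
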