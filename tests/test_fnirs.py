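"""Optical preprocessing: decimation, MA detection, Beer-Lambert, filters."""

import numpy as np
import pytest

import nirsdecode as nd
from nirsdecode.fnirs import (
    FS_PROC,
    MA_WINDOW,
    detect_motion_artifacts,
    downsample_fnirs,
    highpass_dct,
    intensity_to_od,
    lowpass_chebyshev,
    normalize_session,
    od_to_hemoglobin,
    preprocess_fnirs,
)
from nirsdecode.protocol import N_FNIRS_CHANNELS, OpticalGeometry


def sine(freq_hz, fs, duration_s, amp=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t)


class TestDownsample:
    def test_constant_preserved(self):
        out = downsample_fnirs(np.full(1000, 3.7))
        assert out.shape == (100,)
        np.testing.assert_allclose(out, 3.7, rtol=1e-9)

    def test_passband_amplitude_preserved(self):
        out = downsample_fnirs(10.0 + sine(0.1, 50.0, 600.0))
        interior = out[50:-50]
        amp = (interior.max() - interior.min()) / 2
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuated(self):
        out = downsample_fnirs(sine(10.0, 50.0, 600.0))
        assert np.abs(out[50:-50]).max() < 0.1

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            downsample_fnirs(np.ones(5))


class TestMotionArtifactDetection:
    @staticmethod
    def _noise_recording(n, seed=0, sd=0.01):
        rng = np.random.default_rng(seed)
        return 1.0 + rng.normal(0, sd, size=(N_FNIRS_CHANNELS, n))

    def test_false_positive_rate_below_1pct(self):
        x = self._noise_recording(10_000)
        mask = detect_motion_artifacts(x)
        n_windows = (10_000 - MA_WINDOW) // 24 + 1
        flagged_windows = mask.mask.any(axis=0).sum() / MA_WINDOW
        assert flagged_windows / n_windows < 0.01

    def test_large_step_flagged(self):
        x = self._noise_recording(2000, sd=0.01)
        x[0:8, 1000:] += 0.1                      # 10-SD step on probe 0
        mask = detect_motion_artifacts(x)
        assert mask.mask[0, 995:1005].any()
        assert not mask.mask[1].any()             # other probe untouched

    def test_constant_signal_warns_not_flagged(self):
        x = np.ones((N_FNIRS_CHANNELS, 500))
        with pytest.warns(UserWarning, match="constant"):
            mask = detect_motion_artifacts(x)
        assert not mask.mask.any()

    def test_first_half_only_variant_matches_printed_rule(self):
        """halves='first' flags steps landing in a window's trailing half."""
        x = self._noise_recording(2000, sd=0.01)
        x[0:8, 1012:] += 0.1                      # inside second half of the
        mask = detect_motion_artifacts(x, halves="first")   # window at 996
        assert mask.mask[0, 1000:1010].any()


class TestIntensityToOD:
    def test_constant_gives_zero(self):
        np.testing.assert_array_equal(intensity_to_od(np.full(10, 2.0)),
                                      np.zeros(9))

    def test_halving_gives_ln2(self):
        out = intensity_to_od(np.array([1.0, 0.5, 0.5]))
        assert out[0] == pytest.approx(np.log(2.0))
        assert out[1] == 0.0

    def test_telescoping_identity(self):
        rng = np.random.default_rng(1)
        i = np.exp(rng.normal(0, 0.1, 200))
        od = intensity_to_od(i)
        np.testing.assert_allclose(np.cumsum(od), -np.log(i[1:] / i[0]),
                                   atol=1e-12)

    def test_non_positive_rejected_with_location(self):
        with pytest.raises(ValueError, match="index"):
            intensity_to_od(np.array([1.0, -1.0, 1.0]))


class TestBeerLambert:
    geometry = OpticalGeometry()

    def test_zero_od_gives_zero(self):
        o2, hh = od_to_hemoglobin(np.zeros(5), np.zeros(5), self.geometry, 1)
        np.testing.assert_array_equal(o2, np.zeros(6))
        np.testing.assert_array_equal(hh, np.zeros(6))

    def test_matches_independent_linear_solve(self):
        """Single increment (0.01, 0.01) at l_p=2: dense 2x2 solve oracle."""
        o2, hh = od_to_hemoglobin(np.array([0.01]), np.array([0.01]),
                                  self.geometry, 1)
        eps = np.array([[0.9556, 4.8538], [2.3671, 1.7891]])
        rhs = np.array([0.01 / 6.51, 0.01 / 5.86])
        expected = np.linalg.solve(eps, rhs) / 2.0
        assert o2[1] == pytest.approx(expected[0], abs=1e-12)
        assert hh[1] == pytest.approx(expected[1], abs=1e-12)

    @pytest.mark.parametrize("path", [1, 2, 3, 4])
    def test_forward_inverse_round_trip(self, path):
        rng = np.random.default_rng(path)
        d_o2, d_hh = rng.normal(0, 1e-3, (2, 50))
        eps = self.geometry.extinction_matrix()
        l_p = self.geometry.path_lengths_cm[path - 1]
        dod = np.empty((2, 50))
        for w in range(2):
            dod[w] = ((eps[w, 0] * d_o2 + eps[w, 1] * d_hh)
                      * l_p * self.geometry.dpf[w])
        o2, hh = od_to_hemoglobin(dod[0], dod[1], self.geometry, path)
        np.testing.assert_allclose(np.diff(o2), d_o2, atol=1e-10)
        np.testing.assert_allclose(np.diff(hh), d_hh, atol=1e-10)

    def test_invalid_path_rejected(self):
        with pytest.raises(ValueError):
            od_to_hemoglobin(np.zeros(3), np.zeros(3), self.geometry, 5)


class TestNormalize:
    def test_small_example(self):
        out = normalize_session(np.array([1.0, 2.0, 3.0]))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, abs=1e-12)

    def test_sessions_normalized_independently(self):
        a, b = np.arange(10.0), 100 + 5 * np.arange(10.0)
        na, nb = normalize_session(a), normalize_session(b)
        for x in (na, nb):
            assert x.mean() == pytest.approx(0.0, abs=1e-9)
            assert x.std() == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3, 2, 500)
        once = normalize_session(x)
        np.testing.assert_allclose(normalize_session(once), once, atol=1e-12)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            normalize_session(np.ones(10))


class TestFilters:
    def test_lowpass_dc_unchanged(self):
        out = lowpass_chebyshev(np.full(2000, 1.5))
        np.testing.assert_allclose(out, 1.5, atol=1e-9)

    def test_lowpass_stopband_40db(self):
        x = sine(1.0, FS_PROC, 600.0)
        out = lowpass_chebyshev(x)
        assert np.abs(out[200:-200]).max() < 10 ** (-40 / 20)

    def test_lowpass_passband_matches_designed_response(self):
        """Measured gain at 0.05 Hz equals the design's |H|^2 within 1%.

        A 2nd-order type-II filter with its 40 dB stopband edge at 0.5 Hz
        has an analytic zero-phase (forward-backward) gain of ~0.82 at
        0.05 Hz; the implementation must match that design value.
        """
        from scipy import signal as sps
        x = sine(0.05, FS_PROC, 600.0)
        out = lowpass_chebyshev(x)
        amp = (out[200:-200].max() - out[200:-200].min()) / 2
        sos = sps.cheby2(2, 40.0, 0.5, btype="low", fs=FS_PROC, output="sos")
        _, h = sps.sosfreqz(sos, worN=[0.05], fs=FS_PROC)
        expected = np.abs(h[0]) ** 2        # forward-backward application
        assert amp == pytest.approx(expected, rel=0.01)

    def test_dct_highpass_removes_constant(self):
        np.testing.assert_allclose(highpass_dct(np.full(1000, 4.2)),
                                   np.zeros(1000), atol=1e-9)

    def test_dct_highpass_suppresses_below_cutoff(self):
        x = sine(0.005, FS_PROC, 600.0)
        out = highpass_dct(x)
        assert np.sum(out ** 2) < 0.01 * np.sum(x ** 2)

    def test_dct_highpass_passes_above_cutoff(self):
        x = sine(0.1, FS_PROC, 600.0)
        out = highpass_dct(x)
        assert np.sum(out ** 2) == pytest.approx(np.sum(x ** 2), rel=0.05)


class TestPreprocessPipeline:
    def test_shapes_and_determinism(self, small_recording):
        a = preprocess_fnirs(small_recording)
        b = preprocess_fnirs(small_recording)
        assert len(a.sessions) == 2
        assert a.sessions[0].shape[0] == 16
        assert a.sessions[0].shape[1] == a.masks[0].mask.shape[1]
        np.testing.assert_array_equal(a.sessions[0], b.sessions[0])
        np.testing.assert_array_equal(a.masks[0].mask, b.masks[0].mask)

    def test_active_exceeds_rest_for_o2hb(self, noiseless_recording,
                                          small_timeline):
        proc = preprocess_fnirs(noiseless_recording)
        fs = proc.fs
        diffs = []
        for si in range(2):
            sig = proc.sessions[si][0]            # O2Hb, M1, path 1
            for trial in small_timeline.motor_trials(si):
                a0 = int((trial.pinch_onset_s + 5) * fs)
                r0 = int(trial.rest_start_s * fs)
                diffs.append(sig[a0:a0 + 75].mean() - sig[r0:r0 + 75].mean())
        # the drift high-pass redistributes slow block structure, so single
        # trials may dip; the task contrast must dominate on average
        assert np.mean(diffs) > 0
        assert np.mean(np.asarray(diffs) > 0) > 0.5

    def test_null_recording_shows_no_effect(self, small_timeline):
        from scipy import stats
        rec = nd.simulate_recording(
            small_timeline, nd.SimulationConfig(seed=8, null_mode=True),
            include_biosignals=False)
        proc = preprocess_fnirs(rec)
        diffs = []
        for si in range(2):
            sig = proc.sessions[si][0]
            for trial in small_timeline.motor_trials(si):
                a0 = int((trial.pinch_onset_s + 5) * proc.fs)
                r0 = int(trial.rest_start_s * proc.fs)
                diffs.append(sig[a0:a0 + 75].mean() - sig[r0:r0 + 75].mean())
        _, p = stats.ttest_1samp(diffs, 0.0)
        assert p > 0.01


class TestPropertyInvariants:
    """Algebraic invariants over arbitrary well-formed inputs."""

    from hypothesis import given, settings, strategies as st
    from hypothesis.extra import numpy as hnp

    positive_series = hnp.arrays(
        np.float64, st.integers(min_value=3, max_value=50),
        elements=st.floats(min_value=0.1, max_value=10.0))

    @given(positive_series)
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_od_telescoping(self, intensities):
        od = intensity_to_od(intensities)
        np.testing.assert_allclose(np.cumsum(od),
                                   -np.log(intensities[1:] / intensities[0]),
                                   atol=1e-10)

    @given(positive_series)
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_normalization_idempotent(self, series):
        from hypothesis import assume
        assume(series.std() > 1e-6)
        once = normalize_session(series)
        np.testing.assert_allclose(normalize_session(once), once, atol=1e-9)
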