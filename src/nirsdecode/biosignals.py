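"""Autonomic biosignal preprocessing: ECG/respiration/BP/SC to 5 Hz features.

Four normalized feature series are produced per session: mean blood pressure
(BP), heart rate (HR), breathing rate (BR) and phasic skin conductance
response (SCR).  Event detection (QRS complexes, breaths) uses an adaptive
threshold on the squared derivative: a running, exponentially decaying
maximum envelope (time constant 5 s) scaled by 0.4, with a refractory
period.  HR is fused from ECG and the pulsatile blood-pressure waveform for
robustness against missed QRS complexes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .protocol import FS_BIO, RawRecording, SessionTimeline
from .fnirs import FS_PROC, normalize_session

ANS_NAMES = ("BP", "HR", "BR", "SCR")

RR_BOUNDS_S = (0.3, 2.0)
BREATH_BOUNDS_S = (0.48, 10.0)


@dataclass(frozen=True)
class DetectorConfig:
    """Adaptive-threshold event detector settings.

    ``emphasis_band_hz`` isolates the band where the event's slope energy
    lives (5-15 Hz for the QRS complex) before differentiation;
    ``integration_s`` is the moving-window integration applied to the squared
    derivative, concentrating the event energy and averaging out wide-band
    noise.  Both are what make the 0.4 x decaying-running-max threshold
    robust at low SNR.
    """

    threshold_fraction: float = 0.4
    envelope_tau_s: float = 5.0
    refractory_s: float = 0.25
    integration_s: float = 0.12
    emphasis_band_hz: tuple[float, float] | None = (5.0, 15.0)
    min_envelope: float = 1e-12


ECG_DETECTOR = DetectorConfig(refractory_s=0.25)
#: the pulse wave carries its slope energy near the heart rate, not the
#: QRS band
BP_DETECTOR = DetectorConfig(refractory_s=0.25, emphasis_band_hz=None)
RESP_DETECTOR = DetectorConfig(refractory_s=1.5, emphasis_band_hz=None)


@dataclass
class BeatSeries:
    """Strictly increasing event times (s) of heartbeats or breaths."""

    times_s: np.ndarray
    source: str

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly increasing")
        self.times_s = t


@dataclass
class ANSFeatures:
    """Session-wise normalized 5 Hz feature series, rows (BP, HR, BR, SCR)."""

    sessions: list[np.ndarray]   # each (4, n) at 5 Hz
    names: tuple[str, ...] = ANS_NAMES
    fs: float = FS_PROC


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

def decaying_running_max(x: np.ndarray, decay_per_sample: float) -> np.ndarray:
    """y[i] = max(x[i], y[i-1] * decay), vectorized by chunked rescaling."""
    x = np.asarray(x, dtype=float)
    n = x.size
    y = np.empty(n)
    chunk = 4096
    log_d = np.log(decay_per_sample)
    carry = 0.0
    for start in range(0, n, chunk):
        seg = x[start:start + chunk]
        m = seg.size
        up = np.exp(-log_d * np.arange(m))        # decay^-i, bounded per chunk
        down = np.exp(log_d * np.arange(m))       # decay^i
        # fold in the previous chunk's running max, decayed into this chunk
        scaled = np.maximum(seg * up, carry * decay_per_sample)
        run = np.maximum.accumulate(scaled)
        y[start:start + m] = run * down
        carry = y[start + m - 1]
    return y


def _squared_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    d = np.gradient(np.asarray(x, dtype=float)) * fs
    return d * d


def detect_beats(sig: np.ndarray, fs: float = FS_BIO,
                 config: DetectorConfig = ECG_DETECTOR,
                 bandpass_hz: tuple[float, float] | None = (0.01, 40.0),
                 band_order: int = 4, source: str = "ECG") -> BeatSeries:
    """Adaptive-threshold event detection on the squared derivative.

    The signal is optionally band-pass filtered (4th-order Butterworth,
    0.01-40 Hz for ECG), differentiated and squared; a sample triggers an
    event when the squared derivative exceeds ``threshold_fraction`` times
    the exponentially decaying running maximum, subject to the refractory
    period.  The event time is refined to the local maximum of the squared
    derivative within the refractory span.
    """
    x = np.asarray(sig, dtype=float)
    if x.size < fs:
        raise ValueError("signal shorter than one second")
    if bandpass_hz is not None:
        sos = signal.butter(band_order, bandpass_hz, btype="band", fs=fs,
                            output="sos")
        x = signal.sosfiltfilt(sos, x)
    if config.emphasis_band_hz is not None:
        sos = signal.butter(2, config.emphasis_band_hz, btype="band", fs=fs,
                            output="sos")
        x = signal.sosfiltfilt(sos, x)
    sqd = _squared_derivative(x, fs)
    width = max(1, int(round(config.integration_s * fs)))
    if width > 1:
        sqd = uniform_filter1d(sqd, size=width)
    if sqd.max() <= config.min_envelope:
        raise ValueError(f"no events detected in {source} signal "
                         "(flat input?); review detector parameters")
    decay = np.exp(-1.0 / (fs * config.envelope_tau_s))
    envelope = decaying_running_max(sqd, decay)
    triggers = sqd >= config.threshold_fraction * np.maximum(envelope,
                                                             config.min_envelope)
    onsets = np.flatnonzero(triggers[1:] & ~triggers[:-1]) + 1
    if triggers[0]:
        onsets = np.concatenate([[0], onsets])
    refractory = int(round(config.refractory_s * fs))
    events = []
    last = -np.inf
    for i in onsets:
        if i - last < refractory:
            continue
        j = i + int(np.argmax(sqd[i:i + refractory]))
        events.append(j)
        last = j
    if not events:
        raise ValueError(f"no events detected in {source} signal; "
                         "review detector parameters")
    return BeatSeries(times_s=np.asarray(events) / fs, source=source)


def _rate_step_series(times_s: np.ndarray, grid_s: np.ndarray,
                      bounds_s: tuple[float, float],
                      relative_gate: tuple[float, float] | None = None
                      ) -> np.ndarray:
    """Previous-interval instantaneous rate (events/min) on a uniform grid.

    Intervals outside ``bounds_s`` are marked NaN (implausible).  With
    ``relative_gate=(lo, hi)``, intervals outside that multiple of the
    running-median interval (missed or spurious events) are also rejected.
    """
    out = np.full(grid_s.size, np.nan)
    if times_s.size < 2:
        return out
    intervals = np.diff(times_s)
    rate = 60.0 / intervals
    rate[(intervals < bounds_s[0]) | (intervals > bounds_s[1])] = np.nan
    if relative_gate is not None and intervals.size >= 5:
        med = signal.medfilt(intervals, kernel_size=min(
            9, intervals.size - (1 - intervals.size % 2)))
        bad = ((intervals < relative_gate[0] * med)
               | (intervals > relative_gate[1] * med))
        rate[bad] = np.nan
    idx = np.searchsorted(times_s, grid_s, side="right") - 1
    valid = (idx >= 0) & (idx < rate.size)
    out[valid] = rate[idx[valid]]
    return out


def _fill_and_smooth(series: np.ndarray, fs: float,
                     smooth_hz: float = 0.25) -> np.ndarray:
    """Interpolate NaN gaps, then low-pass the rate series at 0.25 Hz."""
    x = series.copy()
    nan = np.isnan(x)
    if nan.all():
        raise ValueError("rate series is empty")
    if nan.any():
        idx = np.arange(x.size)
        x[nan] = np.interp(idx[nan], idx[~nan], x[~nan])
    sos = signal.butter(2, smooth_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


# --------------------------------------------------------------------------
# per-channel pipelines
# --------------------------------------------------------------------------

def preprocess_bp(raw_bp: np.ndarray, fs: float = FS_BIO) -> np.ndarray:
    """Mean blood pressure: linear detrend then 1st-order low-pass at 0.1 Hz."""
    x = np.asarray(raw_bp, dtype=float)
    if x.size < 10 * fs:
        raise ValueError("blood-pressure session shorter than 10 s")
    x = signal.detrend(x, type="linear")
    sos = signal.butter(1, 0.1, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def fuse_heart_rate(ecg_beats: BeatSeries, bp_beats: BeatSeries | None,
                    duration_s: float, fs_out: float = FS_PROC) -> np.ndarray:
    """Instantaneous HR (bpm) on a 5 Hz grid, ECG-primary with BP fallback.

    Where the ECG-derived RR interval is missing or implausible — outside
    0.3-2.0 s, or deviating from the running-median RR by more than
    (0.7, 1.4)x, the signature of a missed or spurious beat — the
    blood-pressure-derived estimate substitutes; remaining gaps are
    interpolated, and the series is smoothed with a 0.25 Hz low-pass.
    """
    grid = np.arange(int(round(duration_s * fs_out))) / fs_out
    hr_ecg = (_rate_step_series(ecg_beats.times_s, grid, RR_BOUNDS_S,
                                relative_gate=(0.7, 1.4))
              if ecg_beats is not None else np.full(grid.size, np.nan))
    if bp_beats is not None:
        hr_bp = _rate_step_series(bp_beats.times_s, grid, RR_BOUNDS_S,
                                  relative_gate=(0.7, 1.4))
        gaps = np.isnan(hr_ecg)
        hr_ecg[gaps] = hr_bp[gaps]
    if np.isnan(hr_ecg).all():
        raise ValueError("no usable beats from either ECG or blood pressure")
    return _fill_and_smooth(hr_ecg, fs_out)


def compute_br(raw_resp: np.ndarray, fs: float = FS_BIO,
               fs_out: float = FS_PROC) -> np.ndarray:
    """Breathing rate (breaths/min) at 5 Hz from the respiration flow signal.

    The flow is band-passed (8th-order Butterworth, 0.1-2.1 Hz) and breaths
    are detected on the derivative with the adaptive threshold (refractory
    1.5 s).
    """
    x = np.asarray(raw_resp, dtype=float)
    sos = signal.butter(8, (0.1, 2.1), btype="band", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    beats = detect_beats(x, fs=fs, config=RESP_DETECTOR, bandpass_hz=None,
                         source="respiration")
    duration = x.size / fs
    grid = np.arange(int(round(duration * fs_out))) / fs_out
    br = _rate_step_series(beats.times_s, grid, BREATH_BOUNDS_S)
    if np.isnan(br).all():
        raise ValueError("no plausible breath intervals detected")
    return _fill_and_smooth(br, fs_out)


def preprocess_scr(raw_sc: np.ndarray, session: SessionTimeline,
                   fs: float = FS_BIO) -> np.ndarray:
    """Phasic skin conductance: 30 Hz low-pass, piecewise-linear detrend.

    The tonic level is removed by subtracting a continuous piecewise-linear
    fit with breakpoints at the start of each trial; with fewer than two
    breakpoints a global linear detrend is used instead (with a warning).
    """
    x = np.asarray(raw_sc, dtype=float)
    sos = signal.butter(8, 30.0, btype="low", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    t = np.arange(x.size) / fs
    breakpoints = [tr.rest_start_s for tr in session.trials
                   if 0.0 < tr.rest_start_s < t[-1]]
    if len(breakpoints) < 2:
        warnings.warn("fewer than 2 trial breakpoints; "
                      "falling back to global linear detrend")
        return signal.detrend(x, type="linear")
    # continuous piecewise-linear basis: intercept, slope, hinge per breakpoint
    basis = [np.ones_like(t), t]
    basis += [np.maximum(t - b, 0.0) for b in breakpoints]
    design = np.column_stack(basis)
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ coef


def _downsample_bio(x: np.ndarray, fs_in: float = FS_BIO,
                    fs_out: float = FS_PROC) -> np.ndarray:
    factor = int(round(fs_in / fs_out))
    return signal.resample_poly(np.asarray(x, dtype=float), up=1, down=factor)


def assemble_biosignals(recording: RawRecording) -> ANSFeatures:
    """Run all four channel pipelines and z-normalize per session."""
    sessions = []
    for si, sess in enumerate(recording.sessions):
        if sess.biosignals is None:
            raise ValueError(f"session {si}: biosignal channels are missing")
        if sess.biosignals.shape[0] != 4:
            raise ValueError(f"session {si}: expected 4 biosignal channels "
                             f"(ECG, respiration, BP, SC)")
        ecg, resp, bp_raw, sc = sess.biosignals
        session_tl = recording.timeline.sessions[si]
        n5 = int(round(sess.biosignals.shape[1] / recording.fs_bio * FS_PROC))

        bp = _downsample_bio(preprocess_bp(bp_raw, recording.fs_bio))[:n5]
        ecg_beats = detect_beats(ecg, fs=recording.fs_bio, config=ECG_DETECTOR,
                                 source="ECG")
        try:
            bp_beats = detect_beats(bp_raw, fs=recording.fs_bio,
                                    config=BP_DETECTOR,
                                    bandpass_hz=(0.5, 10.0), source="BP")
        except ValueError:
            bp_beats = None
        duration = sess.biosignals.shape[1] / recording.fs_bio
        hr = fuse_heart_rate(ecg_beats, bp_beats, duration)[:n5]
        br = compute_br(resp, recording.fs_bio)[:n5]
        scr = _downsample_bio(preprocess_scr(sc, session_tl,
                                             recording.fs_bio))[:n5]

        n = min(map(len, (bp, hr, br, scr)))
        stack = np.vstack([bp[:n], hr[:n], br[:n], scr[:n]])
        sessions.append(normalize_session(stack))
    return ANSFeatures(sessions=sessions)
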