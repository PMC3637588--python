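"""Optical preprocessing: raw intensities to normalized hemoglobin at 5 Hz.

Pipeline order (as run): downsample 50 Hz -> 5 Hz, motion-artifact detection
on raw 5 Hz intensities, incremental optical-density changes
``dOD_k = -ln(I_{k+1} / I_k)``, modified Beer-Lambert conversion to
(dO2Hb, dHHb) increments, cumulative summation, session-wise z-normalization,
Chebyshev type-II low-pass (40 dB at 0.5 Hz, suppressing pulsation and
respiration), and a DCT-domain high-pass at 1/54 Hz removing drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.fft import dct, idct

from .protocol import (
    LOCATIONS,
    N_FNIRS_CHANNELS,
    N_PATHS,
    OpticalGeometry,
    RawRecording,
    fnirs_channel_index,
)

FS_PROC = 5.0
DOWNSAMPLE_FACTOR = 10

#: motion-artifact sliding-window parameters: 32 samples (6.4 s at 5 Hz)
#: with 25% overlap between consecutive windows
MA_WINDOW = 32
MA_OVERLAP = 0.25
MA_THRESHOLD = 3.0


def processed_channel_names() -> list[str]:
    names = []
    for loc in LOCATIONS:
        for chromo in ("O2Hb", "HHb"):
            for p in range(1, N_PATHS + 1):
                names.append(f"{chromo}_{loc}_p{p}")
    return names


def processed_channel_index(location: int, chromophore: str, path: int) -> int:
    """Index into the 16 processed channels ([O2Hb p1..4, HHb p1..4] per probe)."""
    offset = 0 if chromophore == "O2Hb" else 4
    return location * 8 + offset + (path - 1)


@dataclass
class ArtifactMask:
    """Per-location boolean mask at 5 Hz; True marks MA-affected samples."""

    mask: np.ndarray          # (2, n) bool
    window: int = MA_WINDOW
    overlap: float = MA_OVERLAP

    def any_location(self) -> np.ndarray:
        return self.mask.any(axis=0)


@dataclass
class ProcessedFNIRS:
    """Session-wise preprocessed hemoglobin channels and artifact masks."""

    sessions: list[np.ndarray]          # each (16, n) at 5 Hz
    masks: list[ArtifactMask]
    channel_names: list[str] = field(default_factory=processed_channel_names)
    fs: float = FS_PROC


def downsample_fnirs(intensity_50hz: np.ndarray,
                     factor: int = DOWNSAMPLE_FACTOR) -> np.ndarray:
    """Anti-aliased decimation 50 Hz -> 5 Hz (zero-phase FIR, cutoff 2.5 Hz).

    The FIR anti-aliasing filter has exactly unit DC gain, so constant
    signals are preserved bit-for-bit up to rounding.  Accepts a 1-D series
    or a (channels, n) array; operates on the last axis.
    """
    x = np.asarray(intensity_50hz, dtype=float)
    if x.shape[-1] < factor:
        raise ValueError("input too short to downsample")
    # reflect-pad past the filter length so edge transients never reach the
    # retained samples
    pad = factor * min(20, (x.shape[-1] - 1) // factor)
    width = [(0, 0)] * (x.ndim - 1) + [(pad, pad)]
    padded = np.pad(x, width, mode="reflect")
    out = signal.decimate(padded, factor, ftype="fir", zero_phase=True,
                          axis=-1)
    n_lead = pad // factor
    n_out = int(np.ceil(x.shape[-1] / factor))
    return out[..., n_lead:n_lead + n_out]


def _inverse_z(x: np.ndarray) -> float:
    """Reciprocal coefficient of variation mean/SD of a window."""
    sd = x.std()
    if sd == 0:
        return np.nan
    return float(x.mean() / sd)


def detect_motion_artifacts(intensity_5hz: np.ndarray,
                            threshold: float = MA_THRESHOLD,
                            window: int = MA_WINDOW,
                            overlap: float = MA_OVERLAP,
                            halves: str = "both") -> ArtifactMask:
    """Flag motion-artifact windows on the raw (downsampled) intensities.

    For each sliding window (length 32 samples, 25% overlap) and each
    location-wavelength combination, the inverse z-score s = mean/SD is
    computed over the full window and over its leading half; the window is
    flagged when the mean over the 4 light paths of the ratio
    (half s)/(full s) exceeds ``threshold``.  A 5-point median filter is
    applied first to suppress single-sample noise.

    ``halves`` selects which half-windows are tested: ``"first"`` is the
    leading half only; the default ``"both"`` also tests the time-mirrored
    ratio on the trailing half, making the detector symmetric to transients
    anywhere within the window.  Zero-variance (constant) windows cannot
    carry an artifact and are skipped with a warning.
    """
    x = np.asarray(intensity_5hz, dtype=float)
    if x.ndim != 2 or x.shape[0] != N_FNIRS_CHANNELS:
        raise ValueError("expected a (16, n) intensity array")
    if halves not in ("first", "both"):
        raise ValueError("halves must be 'first' or 'both'")
    n = x.shape[1]
    med = signal.medfilt(x, kernel_size=(1, 5))
    step = max(1, int(round(window * (1.0 - overlap))))
    half = window // 2
    mask = np.zeros((2, n), dtype=bool)
    degenerate = False
    for start in range(0, max(1, n - window + 1), step):
        stop = start + window
        if stop > n:
            break
        for loc in range(2):
            flagged = False
            for w in range(2):
                ratios = []
                for p in range(1, N_PATHS + 1):
                    seg = med[fnirs_channel_index(loc, p, w), start:stop]
                    s_full = _inverse_z(seg)
                    if np.isnan(s_full) or s_full == 0:
                        degenerate = True
                        continue
                    candidates = [seg[:half]]
                    if halves == "both":
                        candidates.append(seg[-half:])
                    r_best = -np.inf
                    for sub in candidates:
                        s_half = _inverse_z(sub)
                        if np.isnan(s_half):
                            degenerate = True
                            continue
                        r_best = max(r_best, s_half / s_full)
                    if np.isfinite(r_best):
                        ratios.append(r_best)
                if ratios and np.mean(ratios) > threshold:
                    flagged = True
            if flagged:
                mask[loc, start:stop] = True
    if degenerate:
        warnings.warn("constant window(s) encountered during motion-artifact "
                      "detection; treated as artifact-free")
    return ArtifactMask(mask=mask, window=window, overlap=overlap)


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """Incremental optical-density changes ``-ln(I_{k+1}/I_k)`` (length n-1).

    The cumulative sum of the output telescopes to ``-ln(I_k / I_0)``.
    """
    x = np.asarray(intensity, dtype=float)
    if np.any(x <= 0):
        bad = np.argwhere(x <= 0)[0]
        raise ValueError(f"non-positive intensity at index {tuple(bad)}")
    return -np.diff(np.log(x), axis=-1)


def od_to_hemoglobin(dod_l1: np.ndarray, dod_l2: np.ndarray,
                     geometry: OpticalGeometry, path: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Beer-Lambert inversion of per-wavelength dOD increments for one path.

    Applies ``(1/l_p) * E^-1 * diag(1/DPF) * dOD`` with E the 2x2 extinction
    matrix; returns cumulative (dO2Hb, dHHb) time courses in mM anchored at 0
    (one sample longer than the increments).
    """
    if path not in range(1, N_PATHS + 1):
        raise ValueError("path index must be in 1..4")
    eps_inv = np.linalg.inv(geometry.extinction_matrix())
    l_p = geometry.path_lengths_cm[path - 1]
    scaled = np.vstack([np.asarray(dod_l1) / geometry.dpf[0],
                        np.asarray(dod_l2) / geometry.dpf[1]])
    increments = (eps_inv @ scaled) / l_p
    courses = np.concatenate([np.zeros((2, 1)), np.cumsum(increments, axis=1)],
                             axis=1)
    return courses[0], courses[1]


def normalize_session(series: np.ndarray) -> np.ndarray:
    """Zero-mean unit-SD normalization along the last axis (one session)."""
    x = np.asarray(series, dtype=float)
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot normalize a constant series (zero SD)")
    return (x - x.mean(axis=-1, keepdims=True)) / sd


def lowpass_chebyshev(series: np.ndarray, fs: float = FS_PROC,
                      stop_hz: float = 0.5, attenuation_db: float = 40.0
                      ) -> np.ndarray:
    """Zero-phase 2nd-order Chebyshev type-II low-pass (40 dB at 0.5 Hz)."""
    sos = signal.cheby2(2, attenuation_db, stop_hz, btype="low", fs=fs,
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=-1)


def highpass_dct(series: np.ndarray, cutoff_hz: float = 1.0 / 54.0,
                 fs: float = FS_PROC) -> np.ndarray:
    """High-pass by zeroing DCT coefficients below ``cutoff_hz`` (incl. DC).

    DCT-II coefficient k of an n-sample series corresponds to frequency
    ``k * fs / (2n)``.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    coef = dct(x, type=2, norm="ortho", axis=-1)
    freqs = np.arange(n) * fs / (2.0 * n)
    coef[..., freqs < cutoff_hz] = 0.0
    return idct(coef, type=2, norm="ortho", axis=-1)


def hemoglobin_courses(recording: RawRecording) -> list[np.ndarray]:
    """Un-normalized cumulative hemoglobin (mM) per session at 5 Hz.

    Stops the pipeline after the Beer-Lambert step; used for forward/inverse
    consistency checks against simulator ground truth.
    """
    out = []
    for sess in recording.sessions:
        intensity = downsample_fnirs(sess.fnirs)
        channels = np.empty((N_FNIRS_CHANNELS, intensity.shape[1]))
        for loc in range(2):
            for p in range(1, N_PATHS + 1):
                dod1 = intensity_to_od(intensity[fnirs_channel_index(loc, p, 0)])
                dod2 = intensity_to_od(intensity[fnirs_channel_index(loc, p, 1)])
                o2hb, hhb = od_to_hemoglobin(dod1, dod2, recording.geometry, p)
                channels[processed_channel_index(loc, "O2Hb", p)] = o2hb
                channels[processed_channel_index(loc, "HHb", p)] = hhb
        out.append(channels)
    return out


def preprocess_fnirs(recording: RawRecording,
                     ma_threshold: float = MA_THRESHOLD,
                     ma_halves: str = "both") -> ProcessedFNIRS:
    """Full optical pipeline: 16 preprocessed channels + artifact masks."""
    sessions, masks = [], []
    for sess in recording.sessions:
        intensity = downsample_fnirs(sess.fnirs)
        masks.append(detect_motion_artifacts(intensity, threshold=ma_threshold,
                                             halves=ma_halves))
        channels = np.empty((N_FNIRS_CHANNELS, intensity.shape[1]))
        for loc in range(2):
            for p in range(1, N_PATHS + 1):
                dod1 = intensity_to_od(intensity[fnirs_channel_index(loc, p, 0)])
                dod2 = intensity_to_od(intensity[fnirs_channel_index(loc, p, 1)])
                o2hb, hhb = od_to_hemoglobin(dod1, dod2, recording.geometry, p)
                channels[processed_channel_index(loc, "O2Hb", p)] = o2hb
                channels[processed_channel_index(loc, "HHb", p)] = hhb
        channels = normalize_session(channels)
        channels = lowpass_chebyshev(channels)
        channels = highpass_dct(channels)
        sessions.append(channels)
    return ProcessedFNIRS(sessions=sessions, masks=masks)
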