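"""Experimental protocol timelines and synthetic raw recordings.

The decoder operates on two-session recordings of an isometric finger-pinching
experiment: 16 raw fNIRS intensity channels (2 probe locations x 4
source-detector paths x 2 wavelengths) sampled at 50 Hz, and four autonomic
biosignals (ECG, respiration flow, continuous blood pressure, skin
conductance) sampled at 600 Hz.  This module generates randomized timelines
that follow the protocol (randomized condition order, 20 s pinches, 15-24 s
rest periods, 180/120 s lead-in/lead-out baselines) and simulates raw
recordings with the statistical structure the decoder assumes:

* task-locked hemoglobin concentration changes (boxcar over pinch periods
  convolved with a canonical double-gamma hemodynamic response), mapped to
  optical intensities through the modified Beer-Lambert forward model
  ``I = I0 * exp(-dOD)`` with ``dOD = (eps_O2Hb*dO2Hb + eps_HHb*dHHb) * l_p * DPF``;
* systemic contaminants (cardiac pulsation ~1.1 Hz, respiration ~0.27 Hz,
  Mayer waves ~0.1 Hz), slow drift and white measurement noise;
* stimulus-locked autonomic responses (HR/BR/mean-BP steps, phasic skin
  conductance responses) riding on plausible resting signals;
* optional step-like motion artifacts applied jointly to the 8 channels of
  one probe.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

FS_FNIRS = 50.0
FS_BIO = 600.0

LOCATIONS = ("M1", "PMv")
WAVELENGTHS_NM = (692.0, 834.0)
N_PATHS = 4
N_FNIRS_CHANNELS = 16

#: pinch duration is fixed for every motor condition
PINCH_DURATION_S = 20.0
#: per-condition cue durations; condition 3 is a sham (cue, no pinch),
#: condition 4 is uncued pinching
CUE_DURATION_S = {1: 10.0, 2: 5.0, 3: 10.0, 4: 0.0}
MOTOR_CONDITIONS = (1, 2, 4)
BIOSIGNAL_NAMES = ("ECG", "RESP", "BP", "SC")


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalGeometry:
    """Probe geometry and chromophore optics for the Beer-Lambert model.

    Extinction coefficients are in (cm mM)^-1, path lengths in cm; the
    differential pathlength factor (DPF) is wavelength specific and
    dimensionless.
    """

    wavelengths_nm: tuple[float, float] = WAVELENGTHS_NM
    path_lengths_cm: tuple[float, ...] = (2.0, 2.5, 3.5, 4.0)
    dpf: tuple[float, float] = (6.51, 5.86)
    eps_o2hb: tuple[float, float] = (0.9556, 2.3671)
    eps_hhb: tuple[float, float] = (4.8538, 1.7891)

    def __post_init__(self) -> None:
        values = (
            *self.wavelengths_nm, *self.path_lengths_cm, *self.dpf,
            *self.eps_o2hb, *self.eps_hhb,
        )
        if any(v <= 0 for v in values):
            raise ValueError("all geometry entries must be strictly positive")
        if abs(np.linalg.det(self.extinction_matrix())) < 1e-12:
            raise ValueError("extinction matrix is singular")

    def extinction_matrix(self) -> np.ndarray:
        """2x2 matrix mapping (dO2Hb, dHHb) to per-wavelength absorbance."""
        return np.array(
            [[self.eps_o2hb[0], self.eps_hhb[0]],
             [self.eps_o2hb[1], self.eps_hhb[1]]]
        )


def fnirs_channel_index(location: int, path: int, wavelength: int) -> int:
    """Row index of raw intensity channel (location, path 1..4, wavelength 0/1)."""
    return location * 8 + (path - 1) * 2 + wavelength


def fnirs_channel_names() -> list[str]:
    names = []
    for loc in LOCATIONS:
        for p in range(1, N_PATHS + 1):
            for lam in WAVELENGTHS_NM:
                names.append(f"I_{loc}_p{p}_{int(lam)}nm")
    return names


# --------------------------------------------------------------------------
# timeline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    """One condition presentation, timed relative to session start (seconds).

    ``rest_end_s`` marks the end of the preceding rest period (= cue onset,
    or pinch onset for the uncued condition).  Sham trials (condition 3)
    carry no pinch interval.
    """

    condition: int
    rest_start_s: float
    rest_end_s: float
    pinch_onset_s: float | None
    pinch_end_s: float | None

    @property
    def cue_duration_s(self) -> float:
        return CUE_DURATION_S[self.condition]

    @property
    def is_motor(self) -> bool:
        return self.condition in MOTOR_CONDITIONS

    @property
    def end_s(self) -> float:
        if self.is_motor:
            return float(self.pinch_end_s)
        return self.rest_end_s + self.cue_duration_s


@dataclass(frozen=True)
class SessionTimeline:
    baseline_start_s: float
    baseline_end_s: float
    trials: tuple[Trial, ...]

    @property
    def duration_s(self) -> float:
        last = self.trials[-1].end_s if self.trials else self.baseline_start_s
        return last + self.baseline_end_s


@dataclass(frozen=True)
class EventTimeline:
    sessions: tuple[SessionTimeline, ...]

    def motor_trials(self, session: int) -> list[Trial]:
        return [t for t in self.sessions[session].trials if t.is_motor]

    @property
    def n_motor_trials(self) -> int:
        return sum(len(self.motor_trials(i)) for i in range(len(self.sessions)))

    def validate(self) -> None:
        for sess in self.sessions:
            prev_end = sess.baseline_start_s
            for tr in sess.trials:
                if tr.rest_start_s + 1e-9 < prev_end - 1e-9:
                    raise ValueError("trials overlap or are out of order")
                rest = tr.rest_end_s - tr.rest_start_s
                if not (15.0 - 1e-9 <= rest <= 24.0 + 1e-9):
                    raise ValueError(f"rest duration {rest:.2f}s outside [15, 24]")
                if tr.is_motor:
                    dur = tr.pinch_end_s - tr.pinch_onset_s
                    if abs(dur - PINCH_DURATION_S) > 1e-9:
                        raise ValueError("pinch duration must be exactly 20 s")
                prev_end = tr.end_s


@dataclass(frozen=True)
class ProtocolConfig:
    """Knobs of the randomized protocol.

    Defaults reproduce the study conditions: two ~20 min sessions, five
    blocks of the four shuffled conditions per session (30 pinch trials in
    total), rest periods drawn uniformly from [15, 24] s.
    """

    n_sessions: int = 2
    blocks_per_session: int = 5
    baseline_start_s: float = 180.0
    baseline_end_s: float = 120.0
    rest_range_s: tuple[float, float] = (15.0, 24.0)
    conditions: tuple[int, ...] = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        if self.n_sessions < 0 or self.blocks_per_session < 0:
            raise ValueError("session/block counts must be non-negative")
        if self.baseline_start_s < 0 or self.baseline_end_s < 0:
            raise ValueError("baseline durations must be non-negative")


def generate_timeline(config: ProtocolConfig | None = None,
                      seed: int | np.random.Generator = 0) -> EventTimeline:
    """Draw a randomized event timeline.

    Condition order is shuffled without replacement within each block; rest
    durations are uniform on ``config.rest_range_s``.  Deterministic for a
    fixed seed.
    """
    config = config or ProtocolConfig()
    rng = np.random.default_rng(seed)
    lo, hi = config.rest_range_s
    sessions = []
    for _ in range(config.n_sessions):
        t = config.baseline_start_s
        trials = []
        for _ in range(config.blocks_per_session):
            order = rng.permutation(np.asarray(config.conditions))
            for cond in order:
                cond = int(cond)
                rest = rng.uniform(lo, hi)
                rest_end = t + rest
                if cond in MOTOR_CONDITIONS:
                    onset = rest_end + CUE_DURATION_S[cond]
                    trial = Trial(cond, t, rest_end, onset, onset + PINCH_DURATION_S)
                else:
                    trial = Trial(cond, t, rest_end, None, None)
                trials.append(trial)
                t = trial.end_s
        sessions.append(SessionTimeline(config.baseline_start_s,
                                        config.baseline_end_s, tuple(trials)))
    timeline = EventTimeline(tuple(sessions))
    timeline.validate()
    return timeline


# --------------------------------------------------------------------------
# simulation config
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Effect sizes, contaminant amplitudes and noise levels of the simulator.

    Hemoglobin amplitudes are in mM (0.5 uM peak oxygenation increase is a
    typical contralateral-M1 motor response; the deoxy response is smaller and
    inverted).  Systemic oscillations are expressed as equivalent O2Hb
    concentration oscillations; a fraction ``contaminant_hhb_fraction`` leaks
    into HHb.  Autonomic steps are in their native units (bpm, breaths/min,
    mmHg, uS) before the pipeline's normalization removes units.
    ``null_mode`` zeroes every task-locked effect while keeping noise and
    contaminants, providing a chance-level control subject.
    """

    seed: int = 0
    baseline_intensity: float = 1.0
    # hemodynamic response (canonical double gamma)
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    # task effect sizes
    o2hb_amp_mM: float = 5e-4
    hhb_amp_mM: float = -5e-4 / 3.0
    pmv_scale: float = 0.7
    hr_step_bpm: float = 5.0
    br_step_bpm: float = 2.0
    bp_step_mmhg: float = 5.0
    scr_amp_uS: float = 0.5
    ans_tau_s: float = 3.0
    scr_latency_range_s: tuple[float, float] = (1.0, 3.0)
    # systemic contaminants (equivalent mM oscillation of O2Hb)
    cardiac_freq_hz: float = 1.1
    cardiac_amp_mM: float = 3e-4
    resp_freq_hz: float = 0.27
    resp_amp_mM: float = 1e-4
    mayer_freq_hz: float = 0.1
    mayer_amp_mM: float = 5e-5
    contaminant_hhb_fraction: float = 0.25
    # noise and drift (optical-density units at 50 Hz)
    od_noise_sd: float = 5e-4
    od_drift_sd: float = 2e-6
    # resting autonomic levels
    hr_base_bpm: float = 65.0
    br_base_bpm: float = 16.0
    bp_base_mmhg: float = 90.0
    bp_pulse_amp_mmhg: float = 3.0
    sc_base_uS: float = 5.0
    sc_drift_uS_per_s: float = 2e-3
    bio_noise_sd: float = 0.02
    # motion artifacts (optical-density step size)
    motion_rate_per_s: float = 0.0
    motion_amplitude_od: float = 0.0
    null_mode: bool = False

    def __post_init__(self) -> None:
        for name in ("o2hb_amp_mM", "hr_step_bpm", "br_step_bpm", "bp_step_mmhg",
                     "scr_amp_uS", "cardiac_amp_mM", "resp_amp_mM", "mayer_amp_mM",
                     "od_noise_sd", "od_drift_sd", "bio_noise_sd",
                     "motion_rate_per_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def effective(self) -> "SimulationConfig":
        """Config with all task-locked effects forced to zero in null mode."""
        if not self.null_mode:
            return self
        return replace(self, o2hb_amp_mM=0.0, hhb_amp_mM=0.0, hr_step_bpm=0.0,
                       br_step_bpm=0.0, bp_step_mmhg=0.0, scr_amp_uS=0.0,
                       null_mode=True)


# --------------------------------------------------------------------------
# recording container
# --------------------------------------------------------------------------

@dataclass
class SessionRecording:
    fnirs: np.ndarray                 # (16, n) raw intensities at 50 Hz
    biosignals: np.ndarray | None     # (4, m) ECG/RESP/BP/SC at 600 Hz

    @property
    def n_fnirs(self) -> int:
        return self.fnirs.shape[1]


@dataclass
class MotionArtifact:
    session: int
    time_s: float
    location: int
    sign: int


@dataclass
class RawRecording:
    """Per-session raw signal arrays plus timeline and geometry."""

    sessions: list[SessionRecording]
    timeline: EventTimeline
    geometry: OpticalGeometry
    config: SimulationConfig | None = None
    fs_fnirs: float = FS_FNIRS
    fs_bio: float = FS_BIO
    artifacts: list[MotionArtifact] = field(default_factory=list)
    #: noise-free per-location hemoglobin courses at 50 Hz, for round-trip
    #: checks: {"dO2Hb": (2, n), "dHHb": (2, n)} per session
    ground_truth: list[dict] | None = None

    def validate(self) -> None:
        for sess in self.sessions:
            if sess.fnirs.shape[0] != N_FNIRS_CHANNELS:
                raise ValueError("expected 16 fNIRS channels")
            if np.any(sess.fnirs <= 0):
                raise ValueError("fNIRS intensities must be strictly positive")
            if sess.biosignals is not None and sess.biosignals.shape[0] != 4:
                raise ValueError("expected 4 biosignal channels")


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0,
                     undershoot_s: float = 16.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak, on times t (s)."""
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t, dtype=float)
    # shape parameters chosen so the modes sit at peak_s and undershoot_s
    # with unit scale (SPM convention)
    h = (gamma_dist.pdf(t, peak_s + 1.0)
         - undershoot_ratio * gamma_dist.pdf(t, undershoot_s + 1.0))
    peak = h.max()
    return h / peak if peak > 0 else h


def task_boxcar(session: SessionTimeline, fs: float, n: int) -> np.ndarray:
    """1 during pinch periods, 0 otherwise."""
    box = np.zeros(n)
    for tr in session.trials:
        if tr.is_motor:
            i0 = int(round(tr.pinch_onset_s * fs))
            i1 = int(round(tr.pinch_end_s * fs))
            box[i0:min(i1, n)] = 1.0
    return box


def _smooth_step(box: np.ndarray, fs: float, tau_s: float) -> np.ndarray:
    """First-order (exponential) response of the autonomic drive to the task."""
    if tau_s <= 0:
        return box
    alpha = 1.0 - np.exp(-1.0 / (fs * tau_s))
    from scipy.signal import lfilter
    return lfilter([alpha], [1.0, -(1.0 - alpha)], box)


def _bateman(t: np.ndarray, rise_s: float = 0.75, decay_s: float = 4.0) -> np.ndarray:
    """Unit-peak biexponential kernel of a phasic skin conductance response."""
    h = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    h[t < 0] = 0.0
    m = h.max()
    return h / m if m > 0 else h


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def _simulate_fnirs_session(session: SessionTimeline, cfg: SimulationConfig,
                            geometry: OpticalGeometry,
                            rng: np.random.Generator):
    fs = FS_FNIRS
    n = int(round(session.duration_s * fs))
    t = np.arange(n) / fs

    hrf_t = np.arange(0.0, 32.0, 1.0 / fs)
    hrf = double_gamma_hrf(hrf_t, cfg.hrf_peak_s, cfg.hrf_undershoot_s,
                           cfg.hrf_undershoot_ratio)
    box = task_boxcar(session, fs, n)
    response = np.convolve(box, hrf)[:n]
    # normalize so a sustained 20 s pinch reaches roughly the nominal amplitude
    plateau = np.convolve(np.ones(int(PINCH_DURATION_S * fs)), hrf).max()
    response /= plateau

    phases = rng.uniform(0, 2 * np.pi, size=3)
    contaminant = (
        cfg.cardiac_amp_mM * np.sin(2 * np.pi * cfg.cardiac_freq_hz * t + phases[0])
        + cfg.resp_amp_mM * np.sin(2 * np.pi * cfg.resp_freq_hz * t + phases[1])
        + cfg.mayer_amp_mM * np.sin(2 * np.pi * cfg.mayer_freq_hz * t + phases[2])
    )

    loc_scale = {0: 1.0, 1: cfg.pmv_scale}
    truth_o2hb = np.zeros((2, n))
    truth_hhb = np.zeros((2, n))
    for loc in range(2):
        truth_o2hb[loc] = (cfg.o2hb_amp_mM * loc_scale[loc] * response
                           + contaminant)
        truth_hhb[loc] = (cfg.hhb_amp_mM * loc_scale[loc] * response
                          + cfg.contaminant_hhb_fraction * contaminant)

    eps = geometry.extinction_matrix()
    intensities = np.empty((N_FNIRS_CHANNELS, n))
    for loc in range(2):
        for p in range(1, N_PATHS + 1):
            l_p = geometry.path_lengths_cm[p - 1]
            for w in range(2):
                dod = ((eps[w, 0] * truth_o2hb[loc]
                        + eps[w, 1] * truth_hhb[loc])
                       * l_p * geometry.dpf[w])
                if cfg.od_drift_sd > 0:
                    dod = dod + np.cumsum(rng.normal(0, cfg.od_drift_sd, n))
                if cfg.od_noise_sd > 0:
                    dod = dod + rng.normal(0, cfg.od_noise_sd, n)
                ch = fnirs_channel_index(loc, p, w)
                intensities[ch] = cfg.baseline_intensity * np.exp(-dod)
    truth = {"dO2Hb": truth_o2hb, "dHHb": truth_hhb}
    return intensities, truth


def _simulate_bio_session(session: SessionTimeline, cfg: SimulationConfig,
                          rng: np.random.Generator) -> np.ndarray:
    fs = FS_BIO
    n = int(round(session.duration_s * fs))
    t = np.arange(n) / fs
    box = task_boxcar(session, fs, n)
    drive = _smooth_step(box, fs, cfg.ans_tau_s)

    # heart rate -> integrate-and-fire beat train -> Gaussian QRS template
    hr = (cfg.hr_base_bpm + cfg.hr_step_bpm * drive
          + 1.5 * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi)))
    cardiac_phase = np.cumsum(hr / 60.0) / fs
    beat_idx = np.flatnonzero(np.diff(np.floor(cardiac_phase)) > 0)
    ecg = np.zeros(n)
    half = int(0.02 * fs)  # ~20 ms half-width QRS
    kernel = np.exp(-0.5 * (np.arange(-3 * half, 3 * half + 1) / half) ** 2)
    for b in beat_idx:
        lo = max(0, b - 3 * half)
        hi = min(n, b + 3 * half + 1)
        ecg[lo:hi] += kernel[(lo - (b - 3 * half)):(hi - (b - 3 * half))]
    ecg += rng.normal(0, cfg.bio_noise_sd, n)

    # respiration flow: frequency-modulated sinusoid
    br = cfg.br_base_bpm + cfg.br_step_bpm * drive
    resp_phase = np.cumsum(br / 60.0) / fs
    resp = np.sin(2 * np.pi * resp_phase) + rng.normal(0, cfg.bio_noise_sd, n)

    # blood pressure: mean level step + Mayer wave + cardiac pulsatility
    bp = (cfg.bp_base_mmhg + cfg.bp_step_mmhg * drive
          + 2.0 * np.sin(2 * np.pi * cfg.mayer_freq_hz * t + rng.uniform(0, 2 * np.pi))
          + cfg.bp_pulse_amp_mmhg * np.sin(2 * np.pi * cardiac_phase)
          + rng.normal(0, 10 * cfg.bio_noise_sd, n))

    # skin conductance: tonic drift + stimulus-locked Bateman responses
    sc = (cfg.sc_base_uS + cfg.sc_drift_uS_per_s * t
          + 0.2 * np.sin(2 * np.pi * t / session.duration_s)
          + rng.normal(0, cfg.bio_noise_sd / 2, n))
    if cfg.scr_amp_uS > 0:
        kernel_t = np.arange(0.0, 30.0, 1.0 / fs)
        scr_kernel = _bateman(kernel_t)
        for tr in session.trials:
            if tr.is_motor:
                lat = rng.uniform(*cfg.scr_latency_range_s)
                onset = int(round((tr.pinch_onset_s + lat) * fs))
                amp = cfg.scr_amp_uS * rng.uniform(0.7, 1.3)
                hi = min(n, onset + scr_kernel.size)
                if onset < n:
                    sc[onset:hi] += amp * scr_kernel[:hi - onset]
    return np.vstack([ecg, resp, bp, sc])


def simulate_recording(timeline: EventTimeline,
                       sim_config: SimulationConfig | None = None,
                       geometry: OpticalGeometry | None = None,
                       include_biosignals: bool = True) -> RawRecording:
    """Simulate a raw recording for every session of ``timeline``.

    Deterministic for a fixed ``sim_config.seed``.  The injected noise-free
    hemoglobin courses are stored in ``RawRecording.ground_truth`` for
    forward/inverse consistency checks.
    """
    cfg = (sim_config or SimulationConfig()).effective()
    geometry = geometry or OpticalGeometry()
    rng = np.random.default_rng(cfg.seed)
    sessions, truths = [], []
    for session in timeline.sessions:
        fnirs, truth = _simulate_fnirs_session(session, cfg, geometry, rng)
        bio = _simulate_bio_session(session, cfg, rng) if include_biosignals else None
        sessions.append(SessionRecording(fnirs=fnirs, biosignals=bio))
        truths.append(truth)
    rec = RawRecording(sessions=sessions, timeline=timeline, geometry=geometry,
                       config=cfg, ground_truth=truths)
    rec.validate()
    return rec


def inject_motion_artifacts(recording: RawRecording, rate_per_s: float,
                            amplitude_od: float,
                            seed: int | np.random.Generator = 0) -> RawRecording:
    """Insert step transients at Poisson times on all 8 channels of one probe.

    Steps are applied as optical-density offsets (intensity multiplied by
    ``exp(-/+amplitude)``) from the artifact time onward; ground-truth times
    are appended to ``recording.artifacts``.  The input is not modified.
    """
    if rate_per_s < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(recording)
    for si, sess in enumerate(out.sessions):
        n = sess.n_fnirs
        duration = n / out.fs_fnirs
        n_events = rng.poisson(rate_per_s * duration)
        times = np.sort(rng.uniform(0, duration, n_events))
        for time_s in times:
            loc = int(rng.integers(0, 2))
            sign = int(rng.choice([-1, 1]))
            idx = int(round(time_s * out.fs_fnirs))
            if idx >= n:
                continue
            factor = np.exp(-sign * amplitude_od)
            sess.fnirs[loc * 8:(loc + 1) * 8, idx:] *= factor
            out.artifacts.append(MotionArtifact(si, float(time_s), loc, sign))
    if out.artifacts and amplitude_od == 0:
        warnings.warn("motion artifacts injected with zero amplitude; "
                      "recording unchanged but times logged")
    return out
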