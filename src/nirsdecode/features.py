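"""Segment extraction, least-squares spatial weighting and observations.

For every pinching trial an associated rest/active segment pair is cut from
the 5 Hz signals: windows of N_W = 75 samples (15 s, the shortest rest
interval), shifted forward by N_delta = 25 samples (5 s) to absorb the
hemodynamic delay.  Per probe location, the 8 hemoglobin channels are
collapsed to one feature signal by weights beta minimizing
``|| M @ beta - y ||^2`` where M stacks the training segments and y is 1 on
active rows, 0 on rest rows.  Observations are N_W x d matrices: d=2 for the
fNIRS-only decoder (M1, PMv feature signals), d=6 when the four autonomic
series are appended (no further feature extraction on those).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .biosignals import ANSFeatures
from .fnirs import ProcessedFNIRS
from .protocol import EventTimeline

MODES = ("fnirs_only", "combined")


@dataclass(frozen=True)
class SegmentSpec:
    """Window geometry in samples at 5 Hz."""

    n_window: int = 75
    n_shift: int = 25

    def __post_init__(self) -> None:
        if self.n_window <= 0:
            raise ValueError("window length must be positive")
        if self.n_shift < 0:
            raise ValueError("shift must be non-negative")


@dataclass(frozen=True)
class TrialPair:
    """Associated rest/active segment windows of one pinching trial.

    Windows are half-open sample ranges [start, stop) into the session's
    5 Hz series.  The active window starts ``n_shift`` past the pinch onset;
    the rest window ends ``n_shift`` past the end of the preceding rest
    period, so both windows carry the same forward shift.
    """

    pair_id: int
    session: int
    active_start: int
    rest_start: int
    n_window: int
    ma_affected: bool = False

    @property
    def active_slice(self) -> slice:
        return slice(self.active_start, self.active_start + self.n_window)

    @property
    def rest_slice(self) -> slice:
        return slice(self.rest_start, self.rest_start + self.n_window)


@dataclass
class FeatureWeights:
    """8 least-squares weights per probe location over (O2Hb, HHb) x paths."""

    beta: dict[int, np.ndarray]   # location index -> (8,)

    def __post_init__(self) -> None:
        for loc, b in self.beta.items():
            if not np.all(np.isfinite(b)):
                raise ValueError(f"non-finite weights for location {loc}")


@dataclass
class Observation:
    """Fixed-length multichannel segment with class label and pair identity."""

    data: np.ndarray      # (n_window, d)
    label: str            # "active" | "rest"
    pair_id: int


def extract_trial_pairs(timeline: EventTimeline, processed: ProcessedFNIRS,
                        spec: SegmentSpec | None = None) -> list[TrialPair]:
    """One rest/active pair per pinching trial; sham trials contribute none.

    Pairs are flagged ``ma_affected`` when either window intersects the
    motion-artifact mask of any probe location; windows that would exceed
    the recording bounds are dropped with a warning.
    """
    spec = spec or SegmentSpec()
    fs = processed.fs
    pairs = []
    pair_id = 0
    for si, session in enumerate(timeline.sessions):
        n = processed.sessions[si].shape[1]
        mask = processed.masks[si].any_location()
        for trial in session.trials:
            if not trial.is_motor:
                continue
            onset = int(round(trial.pinch_onset_s * fs))
            rest_end = int(round(trial.rest_end_s * fs))
            active_start = onset + spec.n_shift
            rest_start = rest_end - spec.n_window + spec.n_shift
            if rest_start < 0 or active_start + spec.n_window > n:
                warnings.warn(f"trial at {trial.pinch_onset_s:.1f}s in session "
                              f"{si} exceeds recording bounds; pair dropped")
                continue
            affected = bool(
                mask[active_start:active_start + spec.n_window].any()
                or mask[rest_start:rest_start + spec.n_window].any()
            )
            pairs.append(TrialPair(pair_id, si, active_start, rest_start,
                                   spec.n_window, affected))
            pair_id += 1
    return pairs


def _location_channels(processed_session: np.ndarray, location: int) -> np.ndarray:
    """(n, 8) matrix of one location's channels, samples as rows."""
    return processed_session[location * 8:(location + 1) * 8].T


def fit_weights(training_pairs: list[TrialPair], processed: ProcessedFNIRS,
                location: int,
                seed: int | np.random.Generator = 0) -> np.ndarray:
    """Least-squares weights separating rest and active training segments.

    Rest and active segments of unflagged training pairs are concatenated in
    random order into M (8 columns); the target y is 1 on active rows and 0
    on rest rows.  Solved with the minimum-norm least-squares solution (rank
    deficiency safe).  The concatenation order does not affect the solution.
    """
    rng = np.random.default_rng(seed)
    usable = [p for p in training_pairs if not p.ma_affected]
    if not usable:
        raise ValueError("no unflagged training pairs to fit weights on")
    segments = []
    for pair in usable:
        chans = _location_channels(processed.sessions[pair.session], location)
        segments.append((chans[pair.active_slice], 1.0))
        segments.append((chans[pair.rest_slice], 0.0))
    order = rng.permutation(len(segments))
    m_rows = np.vstack([segments[i][0] for i in order])
    y = np.concatenate([np.full(segments[i][0].shape[0], segments[i][1])
                        for i in order])
    beta, *_ = np.linalg.lstsq(m_rows, y, rcond=None)
    return beta


def fit_feature_weights(training_pairs: list[TrialPair],
                        processed: ProcessedFNIRS,
                        seed: int | np.random.Generator = 0) -> FeatureWeights:
    """Fit the per-location weight vectors on training pairs only."""
    rng = np.random.default_rng(seed)
    return FeatureWeights(beta={loc: fit_weights(training_pairs, processed,
                                                 loc, rng)
                                for loc in range(2)})


def apply_weights(processed: ProcessedFNIRS,
                  weights: FeatureWeights) -> list[np.ndarray]:
    """Per-session (2, n) fNIRS feature signals: weighted channel sums."""
    out = []
    for sess in processed.sessions:
        feats = np.empty((2, sess.shape[1]))
        for loc, beta in weights.beta.items():
            if beta.shape[0] != 8:
                raise ValueError("expected 8 weights per location")
            feats[loc] = _location_channels(sess, loc) @ beta
        out.append(feats)
    return out


def build_observations(pairs: list[TrialPair],
                       feature_signals: list[np.ndarray],
                       ans_features: ANSFeatures | None,
                       mode: str = "fnirs_only") -> list[Observation]:
    """Per clean pair, one rest and one active observation (N_W x d).

    ``combined`` mode horizontally concatenates the two fNIRS feature columns
    with the four autonomic columns (BP, HR, BR, SCR); MA-flagged pairs are
    excluded from both.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "combined" and ans_features is None:
        raise ValueError("combined mode requested but biosignal features are "
                         "missing; fall back to fnirs_only")
    observations = []
    for pair in pairs:
        if pair.ma_affected:
            continue
        feats = feature_signals[pair.session]
        for label, sl in (("rest", pair.rest_slice),
                          ("active", pair.active_slice)):
            cols = [feats[:, sl].T]
            if mode == "combined":
                ans = ans_features.sessions[pair.session]
                if sl.stop > ans.shape[1]:
                    raise ValueError("biosignal series shorter than window")
                cols.append(ans[:, sl].T)
            data = np.hstack(cols)
            if data.shape[0] != pair.n_window:
                raise ValueError("window exceeds session bounds")
            observations.append(Observation(data=data, label=label,
                                            pair_id=pair.pair_id))
    return observations


def write_observations(observations: list[Observation], path,
                       mode: str, spec: SegmentSpec | None = None) -> None:
    """Serialize observations as one CSV matrix each plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"mode": mode,
                "n_window": (spec or SegmentSpec()).n_window,
                "n_shift": (spec or SegmentSpec()).n_shift,
                "observations": []}
    for i, obs in enumerate(observations):
        name = f"obs{i:04d}.csv"
        np.savetxt(path / name, obs.data, delimiter=",", fmt="%.17g")
        manifest["observations"].append(
            {"file": name, "label": obs.label, "pair_id": obs.pair_id})
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_observations(path) -> tuple[list[Observation], dict]:
    """Load a directory written by :func:`write_observations`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    observations = []
    for rec in manifest["observations"]:
        data = np.loadtxt(path / rec["file"], delimiter=",", ndmin=2)
        observations.append(Observation(data=data, label=rec["label"],
                                        pair_id=rec["pair_id"]))
    return observations, manifest
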