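"""On-disk format: CSV signal tables + a JSON sidecar, and the run config.

A recording bundle is a directory with, per session ``i``::

    session{i}_fnirs.csv        time_s + 16 intensity columns (50 Hz)
    session{i}_biosignals.csv   time_s + ECG/RESP/BP/SC columns (600 Hz)

plus ``recording.json`` holding the event timeline, probe geometry,
simulation config (if any) and injected artifact ground truth.  The
round-trip is lossless to better than 1e-12 relative (full float repr).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import (
    BIOSIGNAL_NAMES,
    EventTimeline,
    MotionArtifact,
    OpticalGeometry,
    RawRecording,
    SessionRecording,
    SessionTimeline,
    SimulationConfig,
    Trial,
    fnirs_channel_names,
)


# --------------------------------------------------------------------------
# timeline / metadata (de)serialization
# --------------------------------------------------------------------------

def timeline_to_dict(timeline: EventTimeline) -> dict:
    return {"sessions": [
        {"baseline_start_s": s.baseline_start_s,
         "baseline_end_s": s.baseline_end_s,
         "trials": [dataclasses.asdict(t) for t in s.trials]}
        for s in timeline.sessions]}


def timeline_from_dict(d: dict) -> EventTimeline:
    sessions = []
    for s in d["sessions"]:
        trials = tuple(Trial(**t) for t in s["trials"])
        sessions.append(SessionTimeline(s["baseline_start_s"],
                                        s["baseline_end_s"], trials))
    return EventTimeline(tuple(sessions))


def _tuplify(obj):
    if isinstance(obj, list):
        return tuple(_tuplify(o) for o in obj)
    return obj


def _dataclass_from_dict(cls, d: dict):
    kwargs = {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    for key, value in d.items():
        kwargs[key] = _tuplify(value)
    return cls(**kwargs)


# --------------------------------------------------------------------------
# recording bundle
# --------------------------------------------------------------------------

def write_recording(recording: RawRecording, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, sess in enumerate(recording.sessions):
        t = np.arange(sess.fnirs.shape[1]) / recording.fs_fnirs
        df = pd.DataFrame(sess.fnirs.T, columns=fnirs_channel_names())
        df.insert(0, "time_s", t)
        df.to_csv(path / f"session{i}_fnirs.csv", index=False,
                  float_format="%.17g")
        if sess.biosignals is not None:
            tb = np.arange(sess.biosignals.shape[1]) / recording.fs_bio
            db = pd.DataFrame(sess.biosignals.T, columns=list(BIOSIGNAL_NAMES))
            db.insert(0, "time_s", tb)
            db.to_csv(path / f"session{i}_biosignals.csv", index=False,
                      float_format="%.17g")
    meta = {
        "n_sessions": len(recording.sessions),
        "fs_fnirs": recording.fs_fnirs,
        "fs_bio": recording.fs_bio,
        "timeline": timeline_to_dict(recording.timeline),
        "geometry": dataclasses.asdict(recording.geometry),
        "config": (dataclasses.asdict(recording.config)
                   if recording.config else None),
        "artifacts": [dataclasses.asdict(a) for a in recording.artifacts],
    }
    (path / "recording.json").write_text(json.dumps(meta, indent=1))


def _read_csv(fp: Path, expected_cols: list[str]) -> np.ndarray:
    try:
        df = pd.read_csv(fp)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {fp}: {exc}") from exc
    missing = [c for c in expected_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{fp}: missing columns {missing}")
    if df[expected_cols].isna().any().any():
        row = int(df[expected_cols].isna().any(axis=1).idxmax())
        raise ValueError(f"{fp}: missing/unparseable value at data row {row}")
    return df[expected_cols].to_numpy().T


def read_recording(path) -> RawRecording:
    path = Path(path)
    meta = json.loads((path / "recording.json").read_text())
    timeline = timeline_from_dict(meta["timeline"])
    geometry = _dataclass_from_dict(OpticalGeometry, meta["geometry"])
    config = (_dataclass_from_dict(SimulationConfig, meta["config"])
              if meta.get("config") else None)
    sessions = []
    for i in range(meta["n_sessions"]):
        fnirs = _read_csv(path / f"session{i}_fnirs.csv", fnirs_channel_names())
        bio_fp = path / f"session{i}_biosignals.csv"
        bio = (_read_csv(bio_fp, list(BIOSIGNAL_NAMES))
               if bio_fp.exists() else None)
        sessions.append(SessionRecording(fnirs=fnirs, biosignals=bio))
    rec = RawRecording(sessions=sessions, timeline=timeline, geometry=geometry,
                       config=config, fs_fnirs=meta["fs_fnirs"],
                       fs_bio=meta["fs_bio"],
                       artifacts=[MotionArtifact(**a)
                                  for a in meta["artifacts"]])
    rec.validate()
    return rec


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RunConfig:
    """One JSON document governing a full decoding run."""

    seed: int = 0
    modes: tuple[str, ...] = ("fnirs_only", "combined")
    n_window: int = 75
    n_shift: int = 25
    grid_states: tuple[int, ...] = (1, 2, 3, 4, 5)
    grid_mixtures: tuple[int, ...] = (1, 2)
    n_repeats: int = 7
    n_folds: int = 4
    n_restarts: int = 10
    ma_threshold: float = 3.0
    em_max_iter: int = 100
    em_tol: float = 1e-6
    em_cov_floor: float = 1e-6

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return _dataclass_from_dict(cls, json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))
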