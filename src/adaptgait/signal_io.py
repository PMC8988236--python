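"""Session-log data model, on-disk dialect, and amputation-side normalization.

A *session* is one subject-day of recording from a powered knee/ankle
prosthesis: 17 mechanical sensor channels sampled at 500 Hz, plus a trigger
stream emitted by the device's gait state machine at 30 ms frame granularity.
Each trigger is a timestamped gait event (heel contact or toe off) annotated
with a ground-truth locomotion mode and step type; heel-contact triggers of
interest (TOIs) drive all downstream windowing.

On disk a session is three sibling text files sharing a base path::

    <base>.samples.csv   sample_index, then the 17 named channel columns
    <base>.triggers.csv  sample_index, event_kind, is_toi, mode_label, step_type
    <base>.meta.json     subject_id, session_index, sample_rate, frame_ms, side

Numeric output is written at 9 significant digits; a write/read cycle is the
identity at that precision and exactly idempotent thereafter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SAMPLE_RATE_HZ",
    "FRAME_MS",
    "FRAME_SAMPLES",
    "CHANNEL_NAMES",
    "N_CHANNELS",
    "MODES",
    "EVENT_KINDS",
    "STEP_TYPES",
    "SessionLogError",
    "RecordingMeta",
    "TriggerEvent",
    "SessionRecording",
    "SignMap",
    "load_sign_map",
    "read_session_log",
    "write_session_log",
    "normalize_side",
]

SAMPLE_RATE_HZ = 500
FRAME_MS = 30
#: samples per state-machine frame: 500 Hz * 30 ms
FRAME_SAMPLES = SAMPLE_RATE_HZ * FRAME_MS // 1000

#: Fixed channel schema: knee/ankle joint state and commanded torque from the
#: prosthesis, the 1-DOF axial load cell, the shank-mounted 6-DOF IMU, and the
#: segment angles/velocities derived on-device. 17 channels total; downstream
#: math treats them as opaque.
CHANNEL_NAMES = (
    "knee_angle",
    "knee_velocity",
    "knee_torque",
    "ankle_angle",
    "ankle_velocity",
    "ankle_torque",
    "axial_load",
    "accel_x",
    "accel_y",
    "accel_z",
    "gyro_x",
    "gyro_y",
    "gyro_z",
    "thigh_angle",
    "thigh_velocity",
    "shank_angle",
    "shank_velocity",
)
N_CHANNELS = len(CHANNEL_NAMES)

#: The five locomotion modes: standing, level-ground walking, stair ascent,
#: stair descent, ramp descent.  Ramp ascent shares impedance parameters with
#: level walking and is remapped to LW at read time; the dialect never stores
#: an RA label.
MODES = ("ST", "LW", "SA", "SD", "RD")
EVENT_KINDS = ("heel_contact", "toe_off")
STEP_TYPES = ("SS", "T")

_RAMP_ASCENT_ALIASES = {"RA"}
_FLOAT_FMT = "%.9g"


class SessionLogError(ValueError):
    """Malformed session log or invariant violation."""


@dataclass(frozen=True)
class RecordingMeta:
    """Identity and timing metadata for one subject-session."""

    subject_id: str
    session_index: int
    side: str
    sample_rate: int = SAMPLE_RATE_HZ
    frame_ms: int = FRAME_MS

    def __post_init__(self) -> None:
        if self.session_index < 1:
            raise SessionLogError(f"session_index must be >= 1, got {self.session_index}")
        if self.side not in ("left", "right"):
            raise SessionLogError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.sample_rate <= 0 or self.frame_ms <= 0:
            raise SessionLogError("sample_rate and frame_ms must be positive")
        frame = self.sample_rate * self.frame_ms / 1000
        if frame != int(frame):
            raise SessionLogError(
                f"frame length {frame} samples is not an integer "
                f"({self.sample_rate} Hz x {self.frame_ms} ms)"
            )

    @property
    def frame_samples(self) -> int:
        return self.sample_rate * self.frame_ms // 1000


@dataclass(frozen=True)
class TriggerEvent:
    """A gait-state-machine event with its ground-truth annotation.

    ``mode_label`` / ``step_type`` describe the stride that *ends* at this
    event (see the featureset module for why heel-contact windows on either
    side of the event then share one target).
    """

    sample_index: int
    event_kind: str
    is_toi: bool
    mode_label: str
    step_type: str

    def __post_init__(self) -> None:
        if self.event_kind not in EVENT_KINDS:
            raise SessionLogError(f"unknown event_kind {self.event_kind!r}")
        if self.mode_label not in MODES:
            raise SessionLogError(f"unknown mode label {self.mode_label!r}")
        if self.step_type not in STEP_TYPES:
            raise SessionLogError(f"unknown step_type {self.step_type!r}")
        if self.sample_index < 0:
            raise SessionLogError(f"negative trigger sample_index {self.sample_index}")


@dataclass
class SessionRecording:
    """One session: 17 equal-length channels plus the ordered trigger stream.

    ``channels`` is a float array of shape ``(17, n_samples)`` whose rows
    follow :data:`CHANNEL_NAMES`.
    """

    meta: RecordingMeta
    channels: np.ndarray
    triggers: list[TriggerEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != N_CHANNELS:
            raise SessionLogError(
                f"expected {N_CHANNELS} channels, got array of shape {self.channels.shape}"
            )
        self.triggers = list(self.triggers)
        n = self.channels.shape[1]
        prev = -1
        for i, trig in enumerate(self.triggers):
            if not isinstance(trig, TriggerEvent):
                raise SessionLogError(f"trigger {i} is not a TriggerEvent")
            if trig.sample_index <= prev:
                raise SessionLogError(
                    f"trigger {i} at sample {trig.sample_index} is not strictly "
                    f"after previous trigger at {prev}"
                )
            if trig.sample_index >= n:
                raise SessionLogError(
                    f"trigger {i} at sample {trig.sample_index} outside recording "
                    f"of length {n}"
                )
            prev = trig.sample_index

    @property
    def n_samples(self) -> int:
        return int(self.channels.shape[1])

    def channel(self, name: str) -> np.ndarray:
        return self.channels[CHANNEL_NAMES.index(name)]

    def tois(self) -> list[TriggerEvent]:
        return [t for t in self.triggers if t.is_toi]


@dataclass(frozen=True)
class SignMap:
    """Per-channel +/-1 multipliers normalizing for side of amputation.

    The prosthesis frame mirrors between left- and right-side fittings, so
    laterally-sensed channels change sign between sides.  Applying the map
    twice restores the original recording (involution).  Which channels flip
    is configuration, not code: see ``data/sign_map.yaml``.
    """

    multipliers: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = [c for c in CHANNEL_NAMES if c not in self.multipliers]
        if missing:
            raise SessionLogError(f"sign map missing channels: {missing}")
        bad = {c: v for c, v in self.multipliers.items() if v not in (1, -1)}
        if bad:
            raise SessionLogError(f"sign map values must be +1/-1, got {bad}")

    def as_vector(self) -> np.ndarray:
        return np.array([self.multipliers[c] for c in CHANNEL_NAMES], dtype=float)


def load_sign_map(path: str | Path | None = None) -> SignMap:
    """Load a sign map from YAML; defaults to the packaged configuration."""
    if path is None:
        text = resources.files("adaptgait").joinpath("data/sign_map.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping) or "channels" not in raw:
        raise SessionLogError("sign map YAML must contain a 'channels' mapping")
    return SignMap(multipliers=dict(raw["channels"]))


# ---------------------------------------------------------------------------
# dialect I/O
# ---------------------------------------------------------------------------

def _paths(base: str | Path) -> tuple[Path, Path, Path]:
    base = Path(base)
    if base.name.endswith(".meta.json"):
        base = base.with_name(base.name[: -len(".meta.json")])
    return (
        base.with_name(base.name + ".samples.csv"),
        base.with_name(base.name + ".triggers.csv"),
        base.with_name(base.name + ".meta.json"),
    )


def write_session_log(recording: SessionRecording, base: str | Path) -> Path:
    """Serialize a recording to the three-file dialect; returns the meta path.

    Non-finite sample values are rejected: a sensor log with NaN/inf entries
    has no meaningful dialect representation.
    """
    if not np.all(np.isfinite(recording.channels)):
        raise SessionLogError("recording contains non-finite sample values; refusing to write")
    samples_path, triggers_path, meta_path = _paths(base)
    meta_path.parent.mkdir(parents=True, exist_ok=True)

    frame = pd.DataFrame(recording.channels.T, columns=list(CHANNEL_NAMES))
    frame.insert(0, "sample_index", np.arange(recording.n_samples))
    frame.to_csv(samples_path, index=False, float_format=_FLOAT_FMT)

    trig = pd.DataFrame(
        {
            "sample_index": [t.sample_index for t in recording.triggers],
            "event_kind": [t.event_kind for t in recording.triggers],
            "is_toi": [int(t.is_toi) for t in recording.triggers],
            "mode_label": [t.mode_label for t in recording.triggers],
            "step_type": [t.step_type for t in recording.triggers],
        }
    )
    trig.to_csv(triggers_path, index=False)

    meta = {
        "subject_id": recording.meta.subject_id,
        "session_index": recording.meta.session_index,
        "sample_rate": recording.meta.sample_rate,
        "frame_ms": recording.meta.frame_ms,
        "side": recording.meta.side,
    }
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    return meta_path


def read_session_log(base: str | Path) -> SessionRecording:
    """Parse the three-file dialect back into a validated SessionRecording.

    Ramp-ascent mode labels ("RA") in the trigger file are remapped to LW:
    the prosthesis drives ramp ascent with level-walking impedance parameters,
    so the two are one class everywhere downstream.
    """
    samples_path, triggers_path, meta_path = _paths(base)
    for p in (samples_path, triggers_path, meta_path):
        if not p.exists():
            raise FileNotFoundError(f"session log component missing: {p}")

    try:
        meta_raw = json.loads(meta_path.read_text())
        meta = RecordingMeta(
            subject_id=str(meta_raw["subject_id"]),
            session_index=int(meta_raw["session_index"]),
            sample_rate=int(meta_raw["sample_rate"]),
            frame_ms=int(meta_raw["frame_ms"]),
            side=str(meta_raw["side"]),
        )
    except (KeyError, TypeError) as exc:
        raise SessionLogError(f"{meta_path}: malformed meta sidecar ({exc})") from exc

    frame = pd.read_csv(samples_path)
    cols = list(frame.columns)
    if not cols or cols[0] != "sample_index":
        raise SessionLogError(f"{samples_path}: first column must be 'sample_index', got {cols[:1]}")
    channel_cols = cols[1:]
    if len(channel_cols) != N_CHANNELS:
        raise SessionLogError(
            f"{samples_path}: expected {N_CHANNELS} channel columns, found {len(channel_cols)}"
        )
    if tuple(channel_cols) != CHANNEL_NAMES:
        raise SessionLogError(
            f"{samples_path}: channel columns do not match the published schema; "
            f"first mismatch at column "
            f"{next(i for i, (a, b) in enumerate(zip(channel_cols, CHANNEL_NAMES)) if a != b) + 2}"
        )
    channels = frame[list(CHANNEL_NAMES)].to_numpy(dtype=float).T

    trig_frame = pd.read_csv(triggers_path)
    expected = ["sample_index", "event_kind", "is_toi", "mode_label", "step_type"]
    if list(trig_frame.columns) != expected:
        raise SessionLogError(f"{triggers_path}: header must be {expected}, got {list(trig_frame.columns)}")
    triggers = []
    for line_no, row in enumerate(trig_frame.itertuples(index=False), start=2):
        mode = str(row.mode_label)
        if mode in _RAMP_ASCENT_ALIASES:
            mode = "LW"
        try:
            triggers.append(
                TriggerEvent(
                    sample_index=int(row.sample_index),
                    event_kind=str(row.event_kind),
                    is_toi=bool(int(row.is_toi)),
                    mode_label=mode,
                    step_type=str(row.step_type),
                )
            )
        except SessionLogError as exc:
            raise SessionLogError(f"{triggers_path}: line {line_no}: {exc}") from exc

    try:
        return SessionRecording(meta=meta, channels=channels, triggers=triggers)
    except SessionLogError as exc:
        raise SessionLogError(f"{base}: {exc}") from exc


def normalize_side(recording: SessionRecording, sign_map: SignMap) -> SessionRecording:
    """Normalize a recording for side of amputation.

    Left-side recordings have the mapped channels sign-reversed so that all
    subjects share one canonical channel orientation; right-side recordings
    pass through unchanged.  The operation is an involution on left-side data.
    """
    if recording.meta.side == "right":
        return replace(recording, channels=recording.channels.copy(), triggers=list(recording.triggers))
    flipped = recording.channels * sign_map.as_vector()[:, None]
    return replace(recording, channels=flipped, triggers=list(recording.triggers))
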