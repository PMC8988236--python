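"""Pseudo-online replay: per-event forward prediction, per-stride backward
estimation, and self-training adaptation of the forward classifier.

The engine replays a session's trigger stream in time order.  At every
trigger of interest it forms the 300 ms forward window, classifies it with
the current forward weights, and (in adaptation mode) buffers the features.
When a heel-contact-to-heel-contact stride completes and passes the
300-3000 ms gate, the full stride window is classified with the backward
weights; that prediction becomes the pseudo-label against which the buffered
forward features are trained by three epochs of gradient descent, and the
updated forward weights take effect from the next trigger of interest —
never retroactively.  Control mode performs the forward predictions only and
never touches the weights.

Forward and backward classifiers are separate weight sets by default and
only the forward set is ever adapted: the backward classifier is the label
source, and adapting it on its own outputs would let it drift.  The
``shared_weights`` switch instead routes backward estimation through the
(adapting) forward weights, for comparison with the single-classifier
reading of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .featureset import LabeledExample, WindowingConfig, compute_features
from .neuralnet import (
    GdConfig,
    NetworkWeights,
    WeightsFormatError,
    forward_pass,
    train_gd,
)
from .signal_io import MODES, SessionRecording

__all__ = [
    "AdaptationState",
    "PredictionRecord",
    "PredictionTrace",
    "backward_estimate",
    "run_pseudo_online",
    "truncate_recording",
]


@dataclass
class AdaptationState:
    """Classifier state carried through (and across) pseudo-online sessions."""

    forward_weights: NetworkWeights
    backward_weights: NetworkWeights
    mode: str = "control"  # {control, adaptation}
    shared_weights: bool = False
    pending: list[LabeledExample] = field(default_factory=list)
    n_updates: int = 0
    weights_version: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("control", "adaptation"):
            raise ValueError(f"mode must be 'control' or 'adaptation', got {self.mode!r}")

    def copy(self) -> "AdaptationState":
        return AdaptationState(
            forward_weights=self.forward_weights.copy(),
            backward_weights=self.backward_weights.copy(),
            mode=self.mode,
            shared_weights=self.shared_weights,
            pending=list(self.pending),
            n_updates=self.n_updates,
            weights_version=self.weights_version,
        )


@dataclass(frozen=True)
class PredictionRecord:
    """One forward prediction at a trigger of interest."""

    sample_index: int
    predicted: str
    truth: str
    step_type: str
    pseudo_label: str | None
    weights_version: int


@dataclass
class PredictionTrace:
    """Chronological per-TOI predictions from one pseudo-online run."""

    records: list[PredictionRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_index": [r.sample_index for r in self.records],
                "predicted": [r.predicted for r in self.records],
                "truth": [r.truth for r in self.records],
                "step_type": [r.step_type for r in self.records],
                "pseudo_label": [r.pseudo_label or "" for r in self.records],
                "weights_version": [r.weights_version for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PredictionTrace":
        records = [
            PredictionRecord(
                sample_index=int(row.sample_index),
                predicted=str(row.predicted),
                truth=str(row.truth),
                step_type=str(row.step_type),
                pseudo_label=str(row.pseudo_label) or None,
                weights_version=int(row.weights_version),
            )
            for row in frame.fillna({"pseudo_label": ""}).itertuples(index=False)
        ]
        return cls(records)


def backward_estimate(
    recording: SessionRecording,
    start: int,
    end: int,
    weights: NetworkWeights,
    config: WindowingConfig | None = None,
) -> str | None:
    """Classify the completed stride ``[start, end)``; None if gated out.

    The 300-3000 ms gate is applied here: strides outside it return ``None``
    (a rejection signal — no pseudo-label, hence no adaptation).
    """
    config = config or WindowingConfig()
    span_ms = (end - start) * 1000.0 / recording.meta.sample_rate
    if span_ms < config.backward_min_ms or span_ms > config.backward_max_ms:
        return None
    feats = compute_features(recording.channels[:, start:end])
    _, idx = forward_pass(weights, feats)
    return MODES[idx]


def run_pseudo_online(
    recording: SessionRecording,
    state: AdaptationState,
    windowing: WindowingConfig | None = None,
    gd_cfg: GdConfig | None = None,
) -> tuple[PredictionTrace, AdaptationState]:
    """Replay one session through the real-time pipeline.

    Returns the prediction trace and the final state; the input state is not
    mutated.  Event ordering at a heel contact that both throws a TOI and
    completes a stride: the forward prediction is made first (with the
    pre-update weights), then the stride closes and, in adaptation mode, the
    buffered forward features of that stride are trained against its
    backward-estimation pseudo-label.
    """
    windowing = windowing or WindowingConfig()
    gd_cfg = gd_cfg or GdConfig()
    from .featureset import N_FEATURES

    for w, name in ((state.forward_weights, "forward"), (state.backward_weights, "backward")):
        if w.shape.n_inputs != N_FEATURES or w.shape.n_outputs != len(MODES):
            raise WeightsFormatError(
                f"{name} weights have shape {w.shape}, incompatible with "
                f"{N_FEATURES}-feature, {len(MODES)}-mode classification"
            )

    state = state.copy()
    n_fwd = windowing.forward_samples(recording.meta.sample_rate)
    trace = PredictionTrace()
    pending_record_idx: list[int] = []
    prev_heel_contact: int | None = None
    src = (recording.meta.subject_id, recording.meta.session_index)

    for trig in recording.triggers:
        idx = trig.sample_index
        if trig.is_toi and idx - n_fwd >= 0:
            feats = compute_features(recording.channels[:, idx - n_fwd:idx])
            _, pred = forward_pass(state.forward_weights, feats)
            trace.records.append(
                PredictionRecord(
                    sample_index=idx,
                    predicted=MODES[pred],
                    truth=trig.mode_label,
                    step_type=trig.step_type,
                    pseudo_label=None,
                    weights_version=state.weights_version,
                )
            )
            if state.mode == "adaptation":
                state.pending.append(
                    LabeledExample(
                        features=feats,
                        mode_label=trig.mode_label,  # provisional; target is the pseudo-label
                        step_type=trig.step_type,
                        window_kind="forward",
                        source=(*src, idx),
                    )
                )
                pending_record_idx.append(len(trace.records) - 1)

        if trig.event_kind == "heel_contact":
            if prev_heel_contact is not None and state.mode == "adaptation":
                label_weights = (
                    state.forward_weights if state.shared_weights else state.backward_weights
                )
                pseudo = backward_estimate(
                    recording, prev_heel_contact, idx, label_weights, windowing
                )
                if pseudo is not None:
                    # one GD call per accepted stride, even on an empty buffer
                    # (train_gd is then the identity)
                    if state.pending:
                        X = np.stack([ex.features for ex in state.pending])
                        y = np.full(len(state.pending), MODES.index(pseudo), dtype=int)
                        state.forward_weights = train_gd(state.forward_weights, (X, y), gd_cfg)
                        state.weights_version += 1
                    else:
                        state.forward_weights = train_gd(state.forward_weights, [], gd_cfg)
                    state.n_updates += 1
                    for ridx in pending_record_idx:
                        trace.records[ridx] = replace(trace.records[ridx], pseudo_label=pseudo)
                # the stride is closed either way: stale features must not
                # leak into the next stride's update
                state.pending.clear()
                pending_record_idx.clear()
            prev_heel_contact = idx

    return trace, state


def truncate_recording(recording: SessionRecording, end_sample: int) -> SessionRecording:
    """Recording restricted to samples and triggers strictly before ``end_sample``.

    Replaying a truncated recording must reproduce the trace prefix exactly —
    the causality check that predictions never use future samples or future
    weight updates.
    """
    if end_sample < 1:
        raise ValueError("end_sample must be >= 1")
    end_sample = min(end_sample, recording.n_samples)
    return SessionRecording(
        meta=recording.meta,
        channels=recording.channels[:, :end_sample].copy(),
        triggers=[t for t in recording.triggers if t.sample_index < end_sample],
    )
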