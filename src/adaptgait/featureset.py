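"""Window extraction and the 102-element feature vector.

Two window kinds feed the classifiers:

* **forward prediction** — a fixed 300 ms (150-sample) window ending at a
  trigger of interest, ``[toi - 150, toi)``.  At a heel contact this window
  contains the late swing of the stride that just ended, and is the input of
  the real-time intent decision.
* **backward estimation** — the full heel-contact-to-heel-contact span of a
  completed stride, accepted only when it lasts 300–3000 ms.  It sees both
  stance and swing and therefore supports more accurate retrospective
  classification, which is what qualifies it as a pseudo-label source for
  online adaptation.

Both kinds are reduced to the same 1x102 vector: six per-channel statistics
(mean, standard deviation, min, max, initial value, final value) times 17
channels, channel-major.  The standard deviation uses the sample (n-1)
convention; any consistent choice works since training and test share it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .signal_io import MODES, N_CHANNELS, SessionRecording

__all__ = [
    "N_FEATURES_PER_CHANNEL",
    "N_FEATURES",
    "FEATURE_NAMES_PER_CHANNEL",
    "WindowingConfig",
    "LabeledExample",
    "ExtractionResult",
    "compute_features",
    "extract_forward_examples",
    "extract_backward_examples",
    "split_train_test",
    "examples_to_xy",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES_PER_CHANNEL = ("mean", "std", "min", "max", "initial", "final")
N_FEATURES_PER_CHANNEL = len(FEATURE_NAMES_PER_CHANNEL)
N_FEATURES = N_FEATURES_PER_CHANNEL * N_CHANNELS  # 102


@dataclass(frozen=True)
class WindowingConfig:
    """Window geometry; defaults are the method's fixed values."""

    forward_window_ms: float = 300.0
    backward_min_ms: float = 300.0
    backward_max_ms: float = 3000.0

    def __post_init__(self) -> None:
        if self.backward_min_ms > self.backward_max_ms:
            raise ValueError("backward_min_ms must be <= backward_max_ms")
        if self.forward_window_ms <= 0:
            raise ValueError("forward_window_ms must be positive")

    def forward_samples(self, sample_rate: int) -> int:
        n = self.forward_window_ms * sample_rate / 1000.0
        if n != int(n):
            raise ValueError(
                f"forward window of {self.forward_window_ms} ms is not a whole "
                f"number of samples at {sample_rate} Hz"
            )
        return int(n)


@dataclass(frozen=True)
class LabeledExample:
    """A feature vector with its target label and provenance."""

    features: np.ndarray
    mode_label: str
    step_type: str
    window_kind: str
    source: tuple[str, int, int]  # (subject_id, session_index, trigger sample_index)

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        object.__setattr__(self, "features", feats)
        if feats.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}, got {feats.shape}")
        if not np.all(np.isfinite(feats)):
            raise ValueError("feature vector contains non-finite values")
        if self.mode_label not in MODES:
            raise ValueError(f"unknown mode label {self.mode_label!r}")
        if self.window_kind not in ("forward", "backward"):
            raise ValueError(f"window_kind must be forward/backward, got {self.window_kind!r}")


@dataclass
class ExtractionResult:
    """Extracted examples plus bookkeeping about skipped/rejected windows."""

    examples: list[LabeledExample]
    skipped: dict[str, int] = field(default_factory=dict)

    def __iter__(self) -> Iterator[LabeledExample]:
        return iter(self.examples)

    def __len__(self) -> int:
        return len(self.examples)

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())


def compute_features(window: np.ndarray) -> np.ndarray:
    """Six statistics per channel of a ``(17, n)`` window, channel-major.

    Output order is ``[ch0 mean, ch0 std, ch0 min, ch0 max, ch0 initial,
    ch0 final, ch1 mean, ...]`` — length 102.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] != N_CHANNELS:
        raise ValueError(f"window must have shape (17, n), got {window.shape}")
    if window.shape[1] < 2:
        raise ValueError(
            f"window too short: {window.shape[1]} sample(s); the sample standard "
            f"deviation needs at least 2"
        )
    stats = np.stack(
        [
            window.mean(axis=1),
            window.std(axis=1, ddof=1),
            window.min(axis=1),
            window.max(axis=1),
            window[:, 0],
            window[:, -1],
        ],
        axis=1,
    )
    return stats.ravel()


def extract_forward_examples(
    recording: SessionRecording,
    config: WindowingConfig | None = None,
) -> ExtractionResult:
    """One forward example per TOI whose 300 ms window fits in the recording.

    The half-open window ``[toi - 150, toi)`` is skipped (and counted) when it
    would start before sample 0 — padding would fabricate sensor history.
    """
    config = config or WindowingConfig()
    n_fwd = config.forward_samples(recording.meta.sample_rate)
    examples: list[LabeledExample] = []
    skipped = 0
    src = (recording.meta.subject_id, recording.meta.session_index)
    for trig in recording.triggers:
        if not trig.is_toi:
            continue
        start = trig.sample_index - n_fwd
        if start < 0:
            skipped += 1
            continue
        feats = compute_features(recording.channels[:, start:trig.sample_index])
        examples.append(
            LabeledExample(
                features=feats,
                mode_label=trig.mode_label,
                step_type=trig.step_type,
                window_kind="forward",
                source=(*src, trig.sample_index),
            )
        )
    if skipped:
        logger.info("forward extraction: skipped %d TOI(s) with insufficient history", skipped)
    return ExtractionResult(examples, {"insufficient_history": skipped} if skipped else {})


def extract_backward_examples(
    recording: SessionRecording,
    config: WindowingConfig | None = None,
) -> ExtractionResult:
    """One backward example per consecutive heel-contact pair inside the gate.

    A stride window spans ``[hc_i, hc_{i+1})``; spans shorter than 300 ms or
    longer than 3000 ms are rejected and tallied.  The label comes from the
    stride's terminal TOI, which annotates the stride ending at it.  Pairs
    whose terminal heel contact is not a TOI are not stride windows at all
    and are counted separately.
    """
    config = config or WindowingConfig()
    rate = recording.meta.sample_rate
    heel_contacts = [t for t in recording.triggers if t.event_kind == "heel_contact"]
    examples: list[LabeledExample] = []
    skipped = {"too_short": 0, "too_long": 0, "terminal_not_toi": 0}
    src = (recording.meta.subject_id, recording.meta.session_index)
    for first, last in zip(heel_contacts[:-1], heel_contacts[1:]):
        if not last.is_toi:
            skipped["terminal_not_toi"] += 1
            continue
        span_ms = (last.sample_index - first.sample_index) * 1000.0 / rate
        if span_ms < config.backward_min_ms:
            skipped["too_short"] += 1
            continue
        if span_ms > config.backward_max_ms:
            skipped["too_long"] += 1
            continue
        feats = compute_features(recording.channels[:, first.sample_index:last.sample_index])
        examples.append(
            LabeledExample(
                features=feats,
                mode_label=last.mode_label,
                step_type=last.step_type,
                window_kind="backward",
                source=(*src, last.sample_index),
            )
        )
    skipped = {k: v for k, v in skipped.items() if v}
    if skipped:
        logger.info("backward extraction: rejected windows %s", skipped)
    return ExtractionResult(examples, skipped)


def split_train_test(
    examples: Sequence[LabeledExample],
    train_fraction: float = 0.85,
    seed: int = 0,
) -> tuple[list[LabeledExample], list[LabeledExample]]:
    """Stratified 85/15 split by mode label; an exact, seeded partition.

    The overall training size is ``floor(train_fraction * n + 0.5)``;
    per-mode quotas start at ``floor(train_fraction * n_mode)`` and the
    remainder is distributed by largest fractional part (ties broken in
    canonical mode order).  A mode with fewer than 2 examples cannot be
    split and is assigned wholly to training, with a warning.
    """
    if len(examples) < 2:
        raise ValueError("need at least 2 examples to split")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)

    by_mode: dict[str, list[int]] = {m: [] for m in MODES}
    for i, ex in enumerate(examples):
        by_mode[ex.mode_label].append(i)

    forced_train: list[int] = []
    splittable = {}
    for m in MODES:
        idx = by_mode[m]
        if not idx:
            continue
        if len(idx) < 2:
            warnings.warn(
                f"mode {m} has {len(idx)} example(s); assigning wholly to training",
                stacklevel=2,
            )
            forced_train.extend(idx)
        else:
            splittable[m] = idx

    n_total = len(examples)
    target_total = int(np.floor(train_fraction * n_total + 0.5))
    target_total = min(max(target_total - len(forced_train), 0),
                       sum(len(v) for v in splittable.values()))

    quotas = {m: int(np.floor(train_fraction * len(idx))) for m, idx in splittable.items()}
    remainders = sorted(
        splittable,
        key=lambda m: (-(train_fraction * len(splittable[m]) - quotas[m]), MODES.index(m)),
    )
    deficit = target_total - sum(quotas.values())
    for m in remainders:
        if deficit <= 0:
            break
        if quotas[m] < len(splittable[m]):
            quotas[m] += 1
            deficit -= 1

    train_idx: list[int] = list(forced_train)
    test_idx: list[int] = []
    for m in MODES:
        if m not in splittable:
            continue
        idx = np.array(splittable[m])
        order = rng.permutation(len(idx))
        take = quotas[m]
        train_idx.extend(idx[order[:take]].tolist())
        test_idx.extend(idx[order[take:]].tolist())

    train_idx.sort()
    test_idx.sort()
    return [examples[i] for i in train_idx], [examples[i] for i in test_idx]


def examples_to_xy(
    examples: Sequence[LabeledExample],
    class_order: Sequence[str] = MODES,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack examples into a design matrix and integer label vector."""
    if len(examples) == 0:
        return np.empty((0, N_FEATURES)), np.empty((0,), dtype=int)
    X = np.stack([ex.features for ex in examples])
    y = np.array([class_order.index(ex.mode_label) for ex in examples], dtype=int)
    return X, y
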