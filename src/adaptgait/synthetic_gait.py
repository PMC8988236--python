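"""Synthetic multi-subject, multi-session gait recordings.

No public recording of the powered-prosthesis protocol exists, so this module
generates sessions with the statistical structure the recognition method
assumes: per-mode channel signatures, stride segmentation into stance/swing
with heel-contact / toe-off triggers on 30 ms frame boundaries, steady-state
vs. transitional steps from a first-order Markov mode sequence, inter-subject
offset/scale variation, and a constant per-session drift that produces the
between-day distribution shift online adaptation is meant to correct.

Every simulator parameter here is a synthetic invention: the goal is
controllability and class separability, not biomechanical realism.  The
default mode mix is the activity composition of the four-subject study the
package models (ST 38%, LW 46%, SA 5%, SD 7%, RD 5%).

Mode signatures are fixed smooth curves over normalized stride phase
``t in [0, 1)``::

    template(m, c, t) = B[c] + s[m] * p[c]
                        + a[m] * A[c] * (sin(2*pi*t + phi[c]) + 0.4 sin(4*pi*t + psi[c]))

with per-channel coefficients (baseline ``B``, positive posture pattern
``p``, oscillation amplitude ``A`` and phases) drawn once from a frozen
generator, so the curves are package constants.  The gait modes share the
oscillatory waveform and are distinguished by their scalar *level* ``s[m]``
along the posture pattern — walking sits at 0, stair ascent above it, stair
and ramp descent below, with ramp descent the closest neighbor of walking
and hence the hardest class, mirroring the error structure reported for real
data.  Standing uses a strongly negative level and near-zero amplitude
(``a[ST] = 0.05``): a quasi-static segment, trivially recognizable by its
missing oscillation, but bracketed by the same trigger kinds so the
windowing code path is uniform across modes.

Because the between-class geometry is one-dimensional, an additive session
drift (the same constant on every channel, hence largely along ``p``) moves
every stride toward a neighboring mode's level — a distribution shift the
classifier cannot be invariant to, and the one online adaptation corrects.
Per-stride level jitter along the same pattern sets the within-class scatter
and therefore the class margins the drift competes with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .signal_io import (
    FRAME_MS,
    FRAME_SAMPLES,
    MODES,
    N_CHANNELS,
    SAMPLE_RATE_HZ,
    RecordingMeta,
    SessionRecording,
    SignMap,
    TriggerEvent,
    load_sign_map,
)

__all__ = [
    "DEFAULT_MODE_MIX",
    "ModeTemplate",
    "SubjectProfile",
    "SessionSpec",
    "default_templates",
    "make_cohort",
    "simulate_subject",
    "simulate_study",
    "default_study_specs",
    "simulate_default_study",
]

#: Activity composition of the modeled study protocol.  The published
#: percentages (ST 38, LW 46, SA 5, SD 7, RD 5) are rounded and sum to 101;
#: they are renormalized here to a proper probability vector.
_RAW_MODE_MIX = {"ST": 0.38, "LW": 0.46, "SA": 0.05, "SD": 0.07, "RD": 0.05}
DEFAULT_MODE_MIX: Mapping[str, float] = {
    m: v / sum(_RAW_MODE_MIX.values()) for m, v in _RAW_MODE_MIX.items()
}

#: Frozen seed for the package-constant mode templates.
_TEMPLATE_SEED = 7_160_339


#: Scalar level of each mode along the posture pattern (walking at zero;
#: ramp descent deliberately the nearest neighbor of walking).
MODE_LEVELS: Mapping[str, float] = {"ST": -0.9, "LW": 0.0, "SA": 0.6, "SD": -0.6, "RD": 0.3}
#: Oscillation amplitude scale per mode (standing is quasi-static).  The
#: gait modes differ appreciably in amplitude — but only through the stance
#: portion of the cycle (see ``_stance_weight``): stance loading is where
#: stairs and ramps diverge mechanically, while late swing looks much the
#: same across gait modes.  A full-stride backward window therefore carries
#: a strong, drift-invariant shape signature, whereas the 300 ms forward
#: window (late swing only) must lean on the drift-sensitive posture level.
#: This asymmetry is what makes backward estimation the more accurate,
#: drift-robust classifier and hence a usable pseudo-label source.
MODE_AMP_SCALE: Mapping[str, float] = {"ST": 0.05, "LW": 1.0, "SA": 1.6, "SD": 0.5, "RD": 1.35}


def _stance_weight(t: np.ndarray) -> np.ndarray:
    """Smooth envelope concentrating mode-specific amplitude in stance.

    ``sin^4(pi t)`` peaks mid-stride and is near zero over the last ~20% of
    the cycle, so a window confined to late swing sees almost none of the
    between-mode amplitude contrast.
    """
    return np.sin(np.pi * t) ** 4


class ModeTemplate:
    """Per-mode, per-channel smooth waveforms over normalized stride phase."""

    def __init__(self, baseline: np.ndarray, level_pattern: np.ndarray,
                 osc_amp: np.ndarray, phase1: np.ndarray, phase2: np.ndarray,
                 mode_levels: Mapping[str, float] | None = None,
                 mode_amp_scale: Mapping[str, float] | None = None) -> None:
        for name, arr in (("baseline", baseline), ("level_pattern", level_pattern),
                          ("osc_amp", osc_amp), ("phase1", phase1), ("phase2", phase2)):
            if arr.shape != (N_CHANNELS,):
                raise ValueError(f"{name} must have shape ({N_CHANNELS},), got {arr.shape}")
        if np.any(level_pattern <= 0):
            raise ValueError("level_pattern must be strictly positive")
        self.baseline = baseline
        self.level_pattern = level_pattern
        self.osc_amp = osc_amp
        self.phase1 = phase1
        self.phase2 = phase2
        self.mode_levels = dict(mode_levels or MODE_LEVELS)
        self.mode_amp_scale = dict(mode_amp_scale or MODE_AMP_SCALE)
        levels = [self.mode_levels[m] for m in MODES]
        if len(set(levels)) != len(levels):
            raise ValueError("mode levels must be pairwise distinct")

    def render(self, mode: str, phase: np.ndarray) -> np.ndarray:
        """Noise-free channel matrix ``(17, len(phase))`` for one mode."""
        t = np.asarray(phase, dtype=float)[None, :]
        osc = np.sin(2 * np.pi * t + self.phase1[:, None]) + 0.4 * np.sin(
            4 * np.pi * t + self.phase2[:, None]
        )
        a = self.mode_amp_scale[mode]
        if mode == "ST":
            # quasi-static: suppressed oscillation over the whole cycle
            amp_t = np.full_like(t, a)
        else:
            # mode-specific amplitude expressed through stance only; swing
            # amplitude is shared by all gait modes
            amp_t = 1.0 + (a - 1.0) * _stance_weight(t)
        return (
            (self.baseline + self.mode_levels[mode] * self.level_pattern)[:, None]
            + amp_t * self.osc_amp[:, None] * osc
        )

    def stride_average(self, mode: str, n: int = 512) -> np.ndarray:
        """Per-channel mean of the template over one full stride."""
        return self.render(mode, np.arange(n) / n).mean(axis=1)


@lru_cache(maxsize=1)
def default_templates() -> ModeTemplate:
    """The package-constant templates (deterministic; frozen seed)."""
    rng = np.random.default_rng(_TEMPLATE_SEED)
    baseline = rng.uniform(-1.0, 1.0, size=N_CHANNELS)
    level_pattern = rng.uniform(0.5, 1.5, size=N_CHANNELS)
    osc_amp = rng.uniform(0.7, 1.3, size=N_CHANNELS)
    phase1 = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)
    phase2 = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)
    return ModeTemplate(baseline, level_pattern, osc_amp, phase1, phase2)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject sensor idiosyncrasy: additive offsets and gain factors."""

    subject_id: str
    channel_offsets: np.ndarray
    channel_scales: np.ndarray
    side: str
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_offsets", np.asarray(self.channel_offsets, dtype=float))
        object.__setattr__(self, "channel_scales", np.asarray(self.channel_scales, dtype=float))
        if self.channel_offsets.shape != (N_CHANNELS,) or self.channel_scales.shape != (N_CHANNELS,):
            raise ValueError("channel_offsets/channel_scales must have length 17")
        if np.any(self.channel_scales <= 0):
            raise ValueError("channel_scales must be positive")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass(frozen=True)
class SessionSpec:
    """Parameters of one simulated session.

    ``session_drift`` is a constant added to every channel for the whole
    session — the simplest model of between-day sensor/doff-don drift under
    which online adaptation provably helps.  ``stride_jitter_sd`` is the
    standard deviation (in mode-level units) of a scalar drawn per stride
    and applied along the posture pattern: the stride-to-stride execution
    variability of real gait.  Unlike white sample noise it does not average
    away within a window, so it sets the within-class feature scatter — and
    with it the class margins that session drift competes with.
    """

    n_strides: int = 200
    mode_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MODE_MIX))
    transition_rate: float = 0.3
    stride_duration_range: tuple[float, float] = (810.0, 1410.0)
    swing_fraction: float = 0.4
    noise_sd: float = 0.3
    stride_jitter_sd: float = 0.18
    session_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if set(self.mode_mix) != set(MODES):
            raise ValueError(f"mode_mix must cover exactly {MODES}")
        probs = np.array([self.mode_mix[m] for m in MODES], dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-9):
            raise ValueError("mode_mix must be a probability vector summing to 1")
        lo, hi = self.stride_duration_range
        if not (300.0 <= lo <= hi <= 3000.0):
            raise ValueError("stride_duration_range must lie within [300, 3000] ms")
        if not (0.0 < self.swing_fraction < 1.0):
            raise ValueError("swing_fraction must be in (0, 1)")
        if not (0.0 <= self.transition_rate <= 1.0):
            raise ValueError("transition_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.stride_jitter_sd < 0:
            raise ValueError("stride_jitter_sd must be non-negative")

    def mode_probs(self) -> np.ndarray:
        return np.array([self.mode_mix[m] for m in MODES], dtype=float)


def make_cohort(
    n_subjects: int,
    seed: int,
    offset_sd: float = 0.15,
    scale_sd: float = 0.05,
    subject_level_sd: float = 0.1,
) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles.

    Each subject gets independent per-channel offsets N(0, offset_sd) and
    lognormal(0, scale_sd) gains, plus a coherent posture shift: a subject
    level N(0, subject_level_sd) applied along the template posture pattern,
    the component of inter-subject variation that actually confuses a
    user-independent classifier.  The first subject is fitted on the left
    side and the rest on the right, mirroring the one-left/three-right
    composition of the modeled cohort.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, offset_sd, size=(n_subjects, N_CHANNELS))
    offsets += (
        rng.normal(0.0, subject_level_sd, size=(n_subjects, 1))
        * default_templates().level_pattern[None, :]
    )
    scales = np.exp(rng.normal(0.0, scale_sd, size=(n_subjects, N_CHANNELS)))
    seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    return [
        SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            channel_offsets=offsets[i],
            channel_scales=scales[i],
            side="left" if i == 0 else "right",
            seed=int(seeds[i]),
        )
        for i in range(n_subjects)
    ]


def _mode_sequence(spec: SessionSpec, rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """First-order Markov mode chain and the resulting step types.

    With probability ``transition_rate`` the next stride's mode is redrawn
    from ``mode_mix`` (it may redraw the same mode, which stays steady-state);
    otherwise it repeats.  A stride is transitional (T) exactly when its mode
    differs from the previous stride's mode.

    The emulated protocol deliberately exercised every activity in every
    session, so coverage is guaranteed: any positive-probability mode absent
    from the drawn chain has a short two-stride bout spliced in at a random
    interior position.  Splices are rare for realistic session lengths and
    vanish asymptotically, leaving the chain's stationary proportions intact.
    """
    probs = spec.mode_probs()
    modes = [MODES[rng.choice(len(MODES), p=probs)]]
    for _ in range(1, spec.n_strides):
        if rng.random() < spec.transition_rate:
            modes.append(MODES[rng.choice(len(MODES), p=probs)])
        else:
            modes.append(modes[-1])

    # a frozen chain (transition_rate 0) is a deliberate single-activity
    # session and is exempt from the coverage guarantee
    required = [m for m, p in zip(MODES, probs) if p > 0] if spec.transition_rate > 0 else []
    missing = [m for m in required if m not in modes]
    if missing and spec.n_strides >= 2 * len(required):
        for m in missing:
            pos = int(rng.integers(1, spec.n_strides - 1))
            modes[pos] = m
            modes[min(pos + 1, spec.n_strides - 1)] = m

    step_types = ["SS"]
    for i in range(1, spec.n_strides):
        step_types.append("T" if modes[i] != modes[i - 1] else "SS")
    return modes, step_types


def simulate_subject(
    profile: SubjectProfile,
    spec: SessionSpec,
    session_index: int,
    seed: int,
    templates: ModeTemplate | None = None,
    sign_map: SignMap | None = None,
) -> SessionRecording:
    """Simulate one session for one subject.

    Stride durations are drawn uniformly over ``stride_duration_range`` and
    snapped to whole 30 ms frames; every stride contributes a heel-contact
    (TOI) and a toe-off trigger, the heel contact carrying the mode/step-type
    of the stride it terminates.  Channels are
    ``(template(mode, phase) + jitter_i * level_pattern) * scale + offset
    + session_drift + N(0, noise_sd)`` with ``jitter_i ~ N(0, stride_jitter_sd)``
    drawn once per stride.
    For a left-side subject the emitted channels are mirrored with the sign
    map, i.e. the raw log is in device frame and must be normalized with
    :func:`adaptgait.signal_io.normalize_side` before analysis.
    """
    templates = templates or default_templates()
    rng = np.random.default_rng(np.random.SeedSequence([seed, profile.seed, session_index]))

    modes, step_types = _mode_sequence(spec, rng)

    lo_frames = int(np.ceil(spec.stride_duration_range[0] / FRAME_MS))
    hi_frames = int(np.floor(spec.stride_duration_range[1] / FRAME_MS))
    frames = rng.integers(lo_frames, hi_frames + 1, size=spec.n_strides)
    durations = frames * FRAME_SAMPLES  # samples, whole frames

    lead_in = 10 * FRAME_SAMPLES  # 300 ms of history before the first TOI
    hc = np.empty(spec.n_strides + 1, dtype=int)
    hc[0] = lead_in
    np.cumsum(durations, out=hc[1:])
    hc[1:] += lead_in
    total = int(hc[-1]) + FRAME_SAMPLES  # short tail after the final heel contact

    data = np.empty((N_CHANNELS, total))
    # lead-in rendered as the tail of a virtual stride of the first mode
    virtual_dur = int(durations.mean())
    lead_phase = (virtual_dur - lead_in + np.arange(lead_in)) / virtual_dur
    # per-stride execution variability: a scalar level drawn per stride,
    # expressed along the same posture pattern that separates the modes
    levels = rng.normal(0.0, spec.stride_jitter_sd, size=spec.n_strides + 2)
    jitter = levels[:, None] * templates.level_pattern[None, :]
    data[:, :lead_in] = templates.render(modes[0], lead_phase) + jitter[0][:, None]
    for i in range(spec.n_strides):
        phase = np.arange(durations[i]) / durations[i]
        data[:, hc[i]:hc[i + 1]] = templates.render(modes[i], phase) + jitter[i + 1][:, None]
    data[:, hc[-1]:] = templates.render(modes[-1], np.zeros(total - hc[-1])) + jitter[-1][:, None]

    data = data * profile.channel_scales[:, None] + profile.channel_offsets[:, None]
    data += spec.session_drift
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)

    triggers: list[TriggerEvent] = [
        TriggerEvent(int(hc[0]), "heel_contact", True, modes[0], "SS")
    ]
    stance_frac = 1.0 - spec.swing_fraction
    for i in range(spec.n_strides):
        stance_frames = int(np.clip(round(stance_frac * frames[i]), 1, frames[i] - 1))
        toe_off = int(hc[i]) + stance_frames * FRAME_SAMPLES
        triggers.append(TriggerEvent(toe_off, "toe_off", False, modes[i], step_types[i]))
        triggers.append(TriggerEvent(int(hc[i + 1]), "heel_contact", True, modes[i], step_types[i]))

    if profile.side == "left":
        sign_map = sign_map or load_sign_map()
        data = data * sign_map.as_vector()[:, None]

    meta = RecordingMeta(
        subject_id=profile.subject_id,
        session_index=session_index,
        side=profile.side,
        sample_rate=SAMPLE_RATE_HZ,
        frame_ms=FRAME_MS,
    )
    return SessionRecording(meta=meta, channels=data, triggers=triggers)


def default_study_specs(
    n_sessions: int = 4,
    drift_per_session: float = 0.1,
    base: SessionSpec | None = None,
) -> list[SessionSpec]:
    """Session specs with linearly incrementing drift (0 on session 1)."""
    base = base or SessionSpec()
    return [
        SessionSpec(
            n_strides=base.n_strides,
            mode_mix=dict(base.mode_mix),
            transition_rate=base.transition_rate,
            stride_duration_range=base.stride_duration_range,
            swing_fraction=base.swing_fraction,
            noise_sd=base.noise_sd,
            session_drift=drift_per_session * k,
        )
        for k in range(n_sessions)
    ]


def simulate_study(
    cohort: Sequence[SubjectProfile],
    session_specs: Sequence[SessionSpec],
    seed: int,
) -> list[SessionRecording]:
    """Simulate one recording per (subject, session).

    ``session_specs[k]`` parameterizes session ``k+1`` for every subject; its
    ``session_drift`` creates the between-day shift the adaptation loop is
    meant to track.  Recordings are ordered subject-major.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must contain at least one subject")
    if len(session_specs) == 0:
        raise ValueError("at least one session spec is required")
    sign_map = load_sign_map()
    templates = default_templates()
    out = []
    for profile in cohort:
        for k, spec in enumerate(session_specs, start=1):
            out.append(
                simulate_subject(profile, spec, k, seed, templates=templates, sign_map=sign_map)
            )
    return out


def simulate_default_study(
    seed: int,
    n_subjects: int = 4,
    n_sessions: int = 4,
    n_strides: int = 200,
    drift_per_session: float = 0.1,
) -> list[SessionRecording]:
    """The default study: 4 subjects x 4 sessions with incrementing drift."""
    cohort = make_cohort(n_subjects, seed)
    specs = default_study_specs(
        n_sessions=n_sessions,
        drift_per_session=drift_per_session,
        base=SessionSpec(n_strides=n_strides),
    )
    return simulate_study(cohort, specs, seed)
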