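"""Session blocks, DC/IC experiment orchestration, and error metrics.

The evaluation protocol mirrors the modeled study: sessions 1-3 train, the
drifted session 4 tests.  Cumulative *blocks* group training sessions
(Block 1 = session 1, Block 2 = sessions 1-2, Block 3 = sessions 1-3).
User-dependent classification (DC) trains and tests within one subject;
user-independent classification (IC) pools the other subjects' blocks and
tests on the held-out subject's session 4, leave-one-subject-out.

Errors are per predicted step (per TOI): the steady-state and transitional
misclassification percentages and their step-count-weighted average
``avg = (n_SS * ss + n_T * t) / (n_SS + n_T)``, plus a 5x5 confusion matrix.
Cross-subject summaries report mean and SEM (sample n-1 standard deviation
over sqrt(n)); mixed-model inference is deliberately out of scope — the
result table keeps per-subject values so external statistics tools can be
applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adaptation import AdaptationState, PredictionTrace, run_pseudo_online
from .featureset import (
    LabeledExample,
    extract_backward_examples,
    extract_forward_examples,
)
from .neuralnet import InitConfig, NetworkShape, ScgConfig, train_scg
from .signal_io import MODES, SessionRecording, load_sign_map, normalize_side

__all__ = [
    "BlockSpec",
    "ErrorReport",
    "SummaryStat",
    "build_blocks",
    "make_ic_groups",
    "score_trace",
    "summarize",
    "parse_duration_hours",
    "run_experiment",
    "summarize_experiment",
]


@dataclass(frozen=True)
class BlockSpec:
    """Cumulative training block: block k uses sessions 1..k."""

    block_index: int

    def __post_init__(self) -> None:
        if self.block_index not in (1, 2, 3):
            raise ValueError("block_index must be 1, 2 or 3")

    @property
    def sessions(self) -> tuple[int, ...]:
        return tuple(range(1, self.block_index + 1))


@dataclass(frozen=True)
class SummaryStat:
    """Mean and standard error of the mean over n observations."""

    mean: float
    sem: float
    n: int


def summarize(values: Sequence[float]) -> SummaryStat:
    """Mean and SEM (sample n-1 standard deviation / sqrt(n))."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty list")
    if values.size == 1 or values.max() == values.min():
        sem = 0.0  # exactly zero for identical observations
    else:
        sem = float(values.std(ddof=1) / np.sqrt(values.size))
    return SummaryStat(mean=float(values.mean()), sem=sem, n=int(values.size))


_DURATION_RE = re.compile(r"^(\d+)h(\d{1,2})$")


def parse_duration_hours(text: str) -> float:
    """Parse an "HhMM" duration (e.g. ``"7h35"``) into decimal hours."""
    m = _DURATION_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse duration {text!r}; expected e.g. '2h30'")
    hours, minutes = int(m.group(1)), int(m.group(2))
    if minutes >= 60:
        raise ValueError(f"minutes must be < 60 in {text!r}")
    return hours + minutes / 60.0


@dataclass
class ErrorReport:
    """Step-type-resolved error rates and the mode confusion matrix.

    ``confusion_counts[i, j]`` counts steps of true mode ``MODES[i]``
    predicted as ``MODES[j]``; ``confusion_percent`` row-normalizes to
    percentages (rows with no steps are zero).
    """

    ss_error: float
    t_error: float
    avg_error: float
    n_ss: int
    n_t: int
    confusion_counts: np.ndarray

    def __post_init__(self) -> None:
        self.confusion_counts = np.asarray(self.confusion_counts, dtype=int)
        if self.confusion_counts.shape != (len(MODES), len(MODES)):
            raise ValueError("confusion matrix must be 5x5")

    @property
    def n_steps(self) -> int:
        return self.n_ss + self.n_t

    @property
    def confusion_percent(self) -> np.ndarray:
        totals = self.confusion_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals > 0, 100.0 * self.confusion_counts / totals, 0.0)
        return pct


def score_trace(trace: PredictionTrace) -> ErrorReport:
    """Score a pseudo-online trace against its ground truth."""
    if len(trace) == 0:
        raise ValueError("cannot score an empty trace")
    n_ss = n_t = err_ss = err_t = 0
    confusion = np.zeros((len(MODES), len(MODES)), dtype=int)
    for rec in trace:
        wrong = rec.predicted != rec.truth
        if rec.step_type == "SS":
            n_ss += 1
            err_ss += wrong
        else:
            n_t += 1
            err_t += wrong
        confusion[MODES.index(rec.truth), MODES.index(rec.predicted)] += 1
    ss_error = 100.0 * err_ss / n_ss if n_ss else 0.0
    t_error = 100.0 * err_t / n_t if n_t else 0.0
    avg_error = (n_ss * ss_error + n_t * t_error) / (n_ss + n_t)
    return ErrorReport(
        ss_error=ss_error,
        t_error=t_error,
        avg_error=avg_error,
        n_ss=n_ss,
        n_t=n_t,
        confusion_counts=confusion,
    )


def build_blocks(
    session_examples: Sequence[Sequence[LabeledExample]],
) -> list[list[LabeledExample]]:
    """Cumulative training datasets from 1-3 ordered training sessions.

    ``session_examples[k]`` holds the examples of training session ``k+1``;
    block ``k`` is the union of sessions ``1..k``.  Sessions must arrive in
    strictly increasing session order (verified from example provenance).
    """
    if len(session_examples) == 0:
        raise ValueError("at least one training session is required")
    if len(session_examples) > 3:
        raise ValueError("at most three training sessions form blocks")
    seen: list[int] = []
    for sess in session_examples:
        indices = {ex.source[1] for ex in sess}
        if len(indices) > 1:
            raise ValueError(f"one session's examples span session indices {sorted(indices)}")
        if indices:
            idx = indices.pop()
            if seen and idx <= seen[-1]:
                raise ValueError(
                    f"sessions must be ordered: session {idx} after session {seen[-1]}"
                )
            seen.append(idx)
    blocks = []
    acc: list[LabeledExample] = []
    for sess in session_examples:
        acc = acc + list(sess)
        blocks.append(list(acc))
    return blocks


def make_ic_groups(
    examples_by_subject: Mapping[str, Sequence[Sequence[LabeledExample]]],
) -> dict[str, list[list[LabeledExample]]]:
    """Leave-one-subject-out training pools.

    ``examples_by_subject[s][k]`` holds subject ``s``'s training session
    ``k+1`` examples.  For each held-out subject the returned blocks pool the
    *other* subjects' sessions ``1..k``; the held-out subject's own data never
    enters its training pool (testing uses their session 4).
    """
    subjects = list(examples_by_subject)
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    n_sessions = {len(v) for v in examples_by_subject.values()}
    if len(n_sessions) != 1:
        raise ValueError("all subjects must contribute the same number of training sessions")
    k_sessions = n_sessions.pop()
    groups: dict[str, list[list[LabeledExample]]] = {}
    for held_out in subjects:
        blocks = []
        for k in range(1, k_sessions + 1):
            pool: list[LabeledExample] = []
            for other in subjects:
                if other == held_out:
                    continue
                for sess in examples_by_subject[other][:k]:
                    pool.extend(sess)
            blocks.append(pool)
        groups[held_out] = blocks
    return groups


def _confusion_columns() -> list[str]:
    return [f"conf_{t}_{p}" for t in MODES for p in MODES]


def run_experiment(
    recordings: Sequence[SessionRecording],
    seed: int,
    classifications: Sequence[str] = ("DC", "IC"),
    arms: Sequence[str] = ("control", "adaptation"),
    blocks: Sequence[int] = (1, 2, 3),
    scg_cfg: ScgConfig | None = None,
) -> pd.DataFrame:
    """Run the full DC/IC x block x control/adaptation grid.

    ``recordings`` is a study: for every subject, sessions 1..4 (1-3 train,
    4 test).  Recordings are side-normalized, windowed into forward and
    backward examples, grouped into blocks (per subject for DC, leave-one-out
    pooled for IC), used to SCG-train a forward and a backward classifier per
    cell, and replayed pseudo-online on the held-out session 4 with and
    without adaptation.  Deterministic in ``seed``.

    Returns one row per (classification, subject, block, arm) with ss/t/avg
    errors, step counts, update count, and the flattened confusion matrix in
    row percentages.
    """
    scg_cfg = scg_cfg or ScgConfig()
    sign_map = load_sign_map()

    by_subject: dict[str, dict[int, SessionRecording]] = {}
    for rec in recordings:
        norm = normalize_side(rec, sign_map)
        by_subject.setdefault(norm.meta.subject_id, {})[norm.meta.session_index] = norm
    n_train = max(blocks)
    for subj, sessions in by_subject.items():
        missing = [k for k in (*range(1, n_train + 1), 4) if k not in sessions]
        if missing:
            raise ValueError(f"subject {subj} is missing session(s) {missing}")
    if "IC" in classifications and len(by_subject) < 2:
        raise ValueError("IC classification needs at least 2 subjects")

    fwd: dict[str, list[list[LabeledExample]]] = {}
    bwd: dict[str, list[list[LabeledExample]]] = {}
    for subj, sessions in by_subject.items():
        fwd[subj] = [list(extract_forward_examples(sessions[k])) for k in range(1, n_train + 1)]
        bwd[subj] = [list(extract_backward_examples(sessions[k])) for k in range(1, n_train + 1)]

    fwd_blocks_dc = {s: build_blocks(v) for s, v in fwd.items()}
    bwd_blocks_dc = {s: build_blocks(v) for s, v in bwd.items()}
    if "IC" in classifications:
        fwd_blocks_ic = make_ic_groups(fwd)
        bwd_blocks_ic = make_ic_groups(bwd)

    rows = []
    subjects = sorted(by_subject)
    for classification in classifications:
        for si, subj in enumerate(subjects):
            for block in blocks:
                if classification == "DC":
                    fwd_train = fwd_blocks_dc[subj][block - 1]
                    bwd_train = bwd_blocks_dc[subj][block - 1]
                else:
                    fwd_train = fwd_blocks_ic[subj][block - 1]
                    bwd_train = bwd_blocks_ic[subj][block - 1]
                cell_seed = np.random.SeedSequence(
                    [seed, 0 if classification == "DC" else 1, si, block]
                ).generate_state(2)
                fwd_weights, _ = train_scg(
                    fwd_train, NetworkShape(), scg_cfg, InitConfig(seed=int(cell_seed[0]))
                )
                bwd_weights, _ = train_scg(
                    bwd_train, NetworkShape(), scg_cfg, InitConfig(seed=int(cell_seed[1]))
                )
                test_rec = by_subject[subj][4]
                for arm in arms:
                    state = AdaptationState(
                        forward_weights=fwd_weights.copy(),
                        backward_weights=bwd_weights.copy(),
                        mode=arm,
                    )
                    trace, final = run_pseudo_online(test_rec, state)
                    report = score_trace(trace)
                    row = {
                        "classification": classification,
                        "subject": subj,
                        "block": block,
                        "arm": arm,
                        "ss_error": report.ss_error,
                        "t_error": report.t_error,
                        "avg_error": report.avg_error,
                        "n_ss": report.n_ss,
                        "n_t": report.n_t,
                        "n_updates": final.n_updates,
                    }
                    row.update(
                        dict(zip(_confusion_columns(), report.confusion_percent.ravel()))
                    )
                    rows.append(row)
    return pd.DataFrame(rows)


def summarize_experiment(results: pd.DataFrame) -> pd.DataFrame:
    """Cross-subject mean/SEM of the weighted-average error per cell."""
    out = []
    for (classification, block, arm), grp in results.groupby(
        ["classification", "block", "arm"], sort=True
    ):
        stat = summarize(grp["avg_error"].tolist())
        out.append(
            {
                "classification": classification,
                "block": block,
                "arm": arm,
                "mean_avg_error": stat.mean,
                "sem_avg_error": stat.sem,
                "n_subjects": stat.n,
            }
        )
    return pd.DataFrame(out)
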