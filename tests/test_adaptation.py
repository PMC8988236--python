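"""Pseudo-online replay: control idempotence, causality, and self-training."""

import numpy as np
import pytest

import adaptgait as ag
from adaptgait.adaptation import (
    AdaptationState,
    backward_estimate,
    run_pseudo_online,
    truncate_recording,
)
from adaptgait.featureset import (
    compute_features,
    extract_backward_examples,
    extract_forward_examples,
)
from adaptgait.neuralnet import (
    InitConfig,
    NetworkShape,
    WeightsFormatError,
    forward_pass,
    init_weights,
    train_scg,
)
from adaptgait.signal_io import MODES, SessionRecording, normalize_side


@pytest.fixture(scope="module")
def trained_state(cohort, sign_map):
    rec = normalize_side(ag.simulate_subject(cohort[1], ag.SessionSpec(n_strides=60), 1, seed=31), sign_map)
    fw, _ = train_scg(list(extract_forward_examples(rec)), NetworkShape(), init_cfg=InitConfig(seed=1))
    bw, _ = train_scg(list(extract_backward_examples(rec)), NetworkShape(), init_cfg=InitConfig(seed=2))
    return fw, bw


@pytest.fixture(scope="module")
def test_recording(cohort, sign_map):
    return normalize_side(
        ag.simulate_subject(cohort[1], ag.SessionSpec(n_strides=40, session_drift=0.2), 2, seed=32),
        sign_map,
    )


def test_control_mode_never_changes_weights(trained_state, test_recording):
    fw, bw = trained_state
    state = AdaptationState(forward_weights=fw.copy(), backward_weights=bw.copy(), mode="control")
    trace, final = run_pseudo_online(test_recording, state)
    assert np.array_equal(final.forward_weights.flatten(), fw.flatten())
    assert final.n_updates == 0
    assert all(r.pseudo_label is None for r in trace)
    assert all(r.weights_version == 0 for r in trace)
    # trace equals a pure batch forward pass over the same windows
    for rec in trace:
        window = test_recording.channels[:, rec.sample_index - 150:rec.sample_index]
        _, pred = forward_pass(fw, compute_features(window))
        assert MODES[pred] == rec.predicted


def test_control_mode_idempotent(trained_state, test_recording):
    fw, bw = trained_state
    runs = []
    for _ in range(2):
        state = AdaptationState(forward_weights=fw.copy(), backward_weights=bw.copy(), mode="control")
        trace, _ = run_pseudo_online(test_recording, state)
        runs.append(trace.records)
    assert runs[0] == runs[1]


def test_empty_recording_empty_trace(trained_state):
    fw, bw = trained_state
    meta = ag.RecordingMeta(subject_id="E", session_index=1, side="right")
    rec = SessionRecording(meta=meta, channels=np.zeros((17, 10)), triggers=[])
    state = AdaptationState(forward_weights=fw.copy(), backward_weights=bw.copy(), mode="adaptation")
    trace, final = run_pseudo_online(rec, state)
    assert len(trace) == 0
    assert final.n_updates == 0
    assert np.array_equal(final.forward_weights.flatten(), fw.flatten())


def test_incompatible_weights_rejected(test_recording):
    small = init_weights(NetworkShape(3, 2, 2), InitConfig(seed=0))
    state = AdaptationState(forward_weights=small, backward_weights=small.copy(), mode="control")
    with pytest.raises(WeightsFormatError):
        run_pseudo_online(test_recording, state)


def test_update_conservation(trained_state, test_recording):
    """In adaptation mode, GD updates happen once per gated stride; the
    pending buffer never leaks across strides."""
    fw, bw = trained_state
    state = AdaptationState(forward_weights=fw.copy(), backward_weights=bw.copy(), mode="adaptation")
    trace, final = run_pseudo_online(test_recording, state)
    heel = [t for t in test_recording.triggers if t.event_kind == "heel_contact"]
    spans_ms = np.diff([t.sample_index for t in heel]) * 2.0  # 500 Hz -> ms
    accepted = int(((spans_ms >= 300) & (spans_ms <= 3000)).sum())
    assert final.n_updates == accepted
    assert final.pending == []


def test_causality_truncated_replay(trained_state, test_recording):
    """Replaying a truncated recording reproduces the trace prefix exactly:
    no prediction depends on future samples or future weight updates."""
    fw, bw = trained_state
    state = AdaptationState(forward_weights=fw.copy(), backward_weights=bw.copy(), mode="adaptation")
    full, _ = run_pseudo_online(test_recording, state)
    cut = test_recording.triggers[len(test_recording.triggers) // 2].sample_index + 1
    state2 = AdaptationState(forward_weights=fw.copy(), backward_weights=bw.copy(), mode="adaptation")
    part, _ = run_pseudo_online(truncate_recording(test_recording, cut), state2)
    assert part.records == full.records[: len(part.records)]
    assert len(part) > 0


def test_backward_estimate_gate():
    rng = np.random.default_rng(0)
    meta = ag.RecordingMeta(subject_id="G", session_index=1, side="right")
    rec = SessionRecording(meta=meta, channels=rng.normal(size=(17, 2000)), triggers=[])
    w = init_weights(NetworkShape(), InitConfig(seed=0))
    assert backward_estimate(rec, 0, 100, w) is None  # 200 ms: too short
    assert backward_estimate(rec, 0, 1800, w) is None  # 3600 ms: too long
    assert backward_estimate(rec, 0, 500, w) in MODES  # 1000 ms: accepted


def test_short_stride_triggers_no_update(trained_state):
    """A stride below the 300 ms gate must not cause a GD update."""
    fw, bw = trained_state
    rng = np.random.default_rng(1)
    meta = ag.RecordingMeta(subject_id="G2", session_index=1, side="right")
    triggers = [
        ag.TriggerEvent(150, "heel_contact", True, "LW", "SS"),
        ag.TriggerEvent(240, "heel_contact", True, "LW", "SS"),  # 180 ms stride
    ]
    rec = SessionRecording(meta=meta, channels=rng.normal(size=(17, 300)), triggers=triggers)
    state = AdaptationState(forward_weights=fw.copy(), backward_weights=bw.copy(), mode="adaptation")
    _, final = run_pseudo_online(rec, state)
    assert final.n_updates == 0
    assert np.array_equal(final.forward_weights.flatten(), fw.flatten())


def test_zero_noise_pseudo_labels_match_truth(cohort, sign_map):
    """In the separable noiseless case the backward classifier relabels every
    accepted stride correctly."""
    spec = ag.SessionSpec(n_strides=60, noise_sd=0.0, stride_jitter_sd=0.0,
                          stride_duration_range=(900.0, 900.0))
    train_rec = normalize_side(ag.simulate_subject(cohort[1], spec, 1, seed=41), sign_map)
    bw, _ = train_scg(list(extract_backward_examples(train_rec)), NetworkShape(),
                      init_cfg=InitConfig(seed=3))
    fw, _ = train_scg(list(extract_forward_examples(train_rec)), NetworkShape(),
                      init_cfg=InitConfig(seed=4))
    test_rec = normalize_side(ag.simulate_subject(cohort[1], spec, 2, seed=42), sign_map)
    state = AdaptationState(forward_weights=fw, backward_weights=bw, mode="adaptation")
    trace, _ = run_pseudo_online(test_rec, state)
    labelled = [r for r in trace if r.pseudo_label is not None]
    assert labelled
    assert all(r.pseudo_label == r.truth for r in labelled)


def test_adaptation_recovers_from_drift_with_oracle_labels(cohort, sign_map):
    """With a session shift large enough to break the forward classifier
    (> 20% error frozen), per-stride GD retraining on correct stride labels
    drives the error down within the session: the last third of strides errs
    less than the first third."""
    from adaptgait.neuralnet import GdConfig, train_gd

    train_rec = normalize_side(ag.simulate_subject(cohort[1], ag.SessionSpec(), 1, seed=51), sign_map)
    fw, _ = train_scg(list(extract_forward_examples(train_rec)), NetworkShape(), init_cfg=InitConfig(seed=5))
    bw, _ = train_scg(list(extract_backward_examples(train_rec)), NetworkShape(), init_cfg=InitConfig(seed=6))
    test_rec = normalize_side(
        ag.simulate_subject(cohort[1], ag.SessionSpec(n_strides=300, session_drift=0.45), 4, seed=52),
        sign_map,
    )
    control = AdaptationState(forward_weights=fw.copy(), backward_weights=bw.copy(), mode="control")
    ctrace, _ = run_pseudo_online(test_rec, control)
    cerr = np.mean([r.predicted != r.truth for r in ctrace])
    assert cerr > 0.20  # the drift genuinely breaks the frozen classifier

    # oracle adaptation: the same per-stride loop, trained on the true label
    weights = fw.copy()
    heel = [t for t in test_rec.triggers if t.event_kind == "heel_contact"]
    wrong = []
    for a, b in zip(heel[:-1], heel[1:]):
        feats = compute_features(test_rec.channels[:, b.sample_index - 150:b.sample_index])
        _, pred = forward_pass(weights, feats)
        wrong.append(MODES[pred] != b.mode_label)
        span_ms = (b.sample_index - a.sample_index) * 2.0
        if 300 <= span_ms <= 3000:
            weights = train_gd(
                weights, (feats[None, :], np.array([MODES.index(b.mode_label)])), GdConfig()
            )
    third = len(wrong) // 3
    first = np.mean(wrong[:third])
    last = np.mean(wrong[-third:])
    assert last < first

    # pseudo-label adaptation on the same session does no worse than control
    adapt = AdaptationState(forward_weights=fw.copy(), backward_weights=bw.copy(), mode="adaptation")
    atrace, _ = run_pseudo_online(test_rec, adapt)
    aerr = np.mean([r.predicted != r.truth for r in atrace.records])
    assert aerr <= cerr


def test_oracle_labels_no_worse_than_pseudo(cohort, sign_map):
    """Adapting on ground-truth labels does at least as well (on average)
    as adapting on backward-estimation pseudo-labels."""
    train_rec = normalize_side(ag.simulate_subject(cohort[2], ag.SessionSpec(), 1, seed=61), sign_map)
    fw, _ = train_scg(list(extract_forward_examples(train_rec)), NetworkShape(), init_cfg=InitConfig(seed=7))
    bw, _ = train_scg(list(extract_backward_examples(train_rec)), NetworkShape(), init_cfg=InitConfig(seed=8))

    from adaptgait.neuralnet import GdConfig, train_gd

    deltas = []
    for seed in (62, 63):
        test_rec = normalize_side(
            ag.simulate_subject(cohort[2], ag.SessionSpec(n_strides=200, session_drift=0.3), 4, seed=seed),
            sign_map,
        )
        state = AdaptationState(forward_weights=fw.copy(), backward_weights=bw.copy(), mode="adaptation")
        trace, _ = run_pseudo_online(test_rec, state)
        pseudo_err = np.mean([r.predicted != r.truth for r in trace])

        # oracle: same loop but trained against the true stride label
        weights = fw.copy()
        heel = [t for t in test_rec.triggers if t.event_kind == "heel_contact"]
        wrong = []
        for a, b in zip(heel[:-1], heel[1:]):
            feats = compute_features(test_rec.channels[:, b.sample_index - 150:b.sample_index])
            _, pred = forward_pass(weights, feats)
            wrong.append(MODES[pred] != b.mode_label)
            span_ms = (b.sample_index - a.sample_index) * 2.0
            if 300 <= span_ms <= 3000:
                weights = train_gd(
                    weights,
                    (feats[None, :], np.array([MODES.index(b.mode_label)])),
                    GdConfig(),
                )
        deltas.append(np.mean(wrong) - pseudo_err)
    assert np.mean(deltas) <= 0.02


def test_shared_weights_mode_runs(trained_state, test_recording):
    fw, bw = trained_state
    state = AdaptationState(forward_weights=fw.copy(), backward_weights=bw.copy(),
                            mode="adaptation", shared_weights=True)
    trace, final = run_pseudo_online(test_recording, state)
    assert final.n_updates > 0
    assert len(trace) > 0
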