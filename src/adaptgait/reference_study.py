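"""Published summary figures from the four-subject powered-prosthesis study
whose protocol this package models.

These are *reported results*, used as inputs to consistency arithmetic (the
training-time summary and the error reduction obtainable by trading a second
data-collection session for one adapted session); nothing in this package
attempts to regenerate them, since the underlying subject recordings were
never deposited.

``TRAINING_SESSION_TIMES`` holds the per-subject durations of the three
training sessions in the study's "HhMM" notation; totals and their mean/SEM
are recomputed by :func:`adaptgait.evaluation.parse_duration_hours` and
:func:`adaptgait.evaluation.summarize`.

``REPORTED_ERRORS`` holds the block-wise steady-state (SS), transitional (T)
and step-count-weighted average error percentages for user-dependent (DC)
and user-independent (IC) classification, with and without adaptation,
keyed by ``(classification, arm, block)``.
"""

from __future__ import annotations

#: Per-subject training-session durations, sessions 1-3, "HhMM" strings.
TRAINING_SESSION_TIMES: dict[str, tuple[str, str, str]] = {
    "01": ("2h30", "2h45", "2h20"),
    "02": ("2h00", "2h00", "2h00"),
    "03": ("2h45", "4h00", "3h20"),
    "04": ("2h15", "2h15", "1h55"),
}

#: (classification, arm, block) -> {"ss": %, "t": %, "avg": %}
REPORTED_ERRORS: dict[tuple[str, str, int], dict[str, float]] = {
    ("DC", "control", 1): {"ss": 3.71, "t": 6.39, "avg": 4.09},
    ("DC", "control", 2): {"ss": 1.44, "t": 5.34, "avg": 1.99},
    ("DC", "control", 3): {"ss": 0.30, "t": 5.07, "avg": 0.97},
    ("IC", "control", 1): {"ss": 3.12, "t": 10.67, "avg": 4.19},
    ("IC", "control", 2): {"ss": 1.83, "t": 10.88, "avg": 3.11},
    ("IC", "control", 3): {"ss": 1.59, "t": 11.09, "avg": 2.93},
    ("DC", "adaptation", 1): {"ss": 0.58, "t": 5.97, "avg": 1.34},
    ("DC", "adaptation", 2): {"ss": 0.50, "t": 4.49, "avg": 1.07},
    ("DC", "adaptation", 3): {"ss": 0.40, "t": 3.91, "avg": 0.90},
    ("IC", "adaptation", 1): {"ss": 0.67, "t": 8.88, "avg": 1.83},
    ("IC", "adaptation", 2): {"ss": 0.61, "t": 8.40, "avg": 1.71},
    ("IC", "adaptation", 3): {"ss": 0.51, "t": 8.24, "avg": 1.61},
}
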