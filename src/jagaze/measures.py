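"""Per-participant joint-attention measures.

All measures are computed on the JA phase of usable trials only.  Undefined
quantities (empty denominators) are returned as ``nan`` and propagate into the
statistics as missing values — an undefined score is absence of evidence, not a
zero.

Normalized scores are of the form ``(a - b) / (a + b)``:

* normalized gaze/object-following accuracy — first looks at target vs
  non-target, denominator the number of trials with a first look at either
  object;
* RJA normalized transition score — face→target vs face→non-target transition
  totals;
* IJA1 normalized transition score — target→face vs non-target→face totals.

Fixation-duration percentages (FD%) divide the summed fixation time on an AOI
by the participant's total on-trial fixation time in the JA phase, including
fixations on no AOI (the "all-inclusive" denominator).
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np

from .events import extract_transitions, first_look
from .trials import Trial

AOI_PAIRS = [
    (a, b)
    for a, b in itertools.permutations(("face", "target", "non_target"), 2)
]

#: ordered pairs reported per task (between-object pairs pooled for IJA1)
TASK_PAIRS = {
    "RJA": [("face", "target"), ("face", "non_target")],
    "IJA1": [
        ("target", "face"),
        ("non_target", "face"),
        ("face", "target"),
        ("face", "non_target"),
    ],
    "IJA2": [("target", "face"), ("face", "target")],
}


def _check_counts(*counts: float) -> None:
    for c in counts:
        if c < 0:
            raise ValueError("counts must be non-negative")


def _norm_score(a: float, b: float) -> float:
    _check_counts(a, b)
    denom = a + b
    if denom == 0:
        return float("nan")
    return (a - b) / denom


def normalized_accuracy(n_first_target: float, n_first_nontarget: float) -> float:
    """(first looks at target − at non-target) / trials with either first look."""
    return _norm_score(n_first_target, n_first_nontarget)


def norm_transition_score_rja(t_face_to_target: float,
                              t_face_to_nontarget: float) -> float:
    """(face→target − face→non-target) / (face→either object), across trials."""
    return _norm_score(t_face_to_target, t_face_to_nontarget)


def norm_transition_score_ija1(t_target_to_face: float,
                               t_nontarget_to_face: float) -> float:
    """(target→face − non-target→face) / (either object→face), across trials."""
    return _norm_score(t_target_to_face, t_nontarget_to_face)


def transition_counts(trials: Sequence[Trial], task: str) -> dict:
    """Transition totals over usable trials of one task, plus per-trial means.

    Returns a dict with keys ``totals`` (all ordered AOI pairs), ``per_trial_mean``,
    ``between_objects_total``/``between_objects_per_trial`` (target↔non-target
    pooled) and ``n_usable``.  With zero usable trials all means are ``nan``.
    """
    usable = [t for t in trials if t.task == task and t.usable]
    totals = {pair: 0 for pair in AOI_PAIRS}
    for t in usable:
        for tr in extract_transitions(t.ja_fixations):
            totals[(tr.from_aoi, tr.to_aoi)] += 1
    n = len(usable)
    between = totals[("target", "non_target")] + totals[("non_target", "target")]
    if n == 0:
        per_trial = {pair: float("nan") for pair in AOI_PAIRS}
        between_pt = float("nan")
    else:
        per_trial = {pair: totals[pair] / n for pair in AOI_PAIRS}
        between_pt = between / n
    return {
        "totals": totals,
        "per_trial_mean": per_trial,
        "between_objects_total": between,
        "between_objects_per_trial": between_pt,
        "n_usable": n,
    }


def first_look_counts(trials: Sequence[Trial], task: str) -> tuple[int, int]:
    """(trials with first JA look at target, at non-target) among usable trials."""
    n_t = n_nt = 0
    for t in trials:
        if t.task != task or not t.usable:
            continue
        fl = first_look(t.ja_fixations)
        if fl == "target":
            n_t += 1
        elif fl == "non_target":
            n_nt += 1
    return n_t, n_nt


def _fd_sums(trials: Sequence[Trial]) -> dict[str, float]:
    sums = {"face": 0.0, "target": 0.0, "non_target": 0.0, "none": 0.0}
    for t in trials:
        for f in t.ja_fixations:
            sums[f.aoi] += f.duration_ms
    return sums


def fixation_duration_pct(trials: Sequence[Trial], aoi: str,
                          task: str | None = None) -> float:
    """Percent of JA-phase fixation time spent on ``aoi`` over usable trials.

    The denominator is the total on-screen fixation time, off-AOI fixations
    included.  ``nan`` when there is no fixation time at all.
    """
    subset = [t for t in trials
              if t.usable and (task is None or t.task == task)]
    sums = _fd_sums(subset)
    total = sum(sums.values())
    if total == 0:
        return float("nan")
    return 100.0 * sums[aoi] / total


def conditional_fd(trials: Sequence[Trial], aoi: str = "face",
                   task: str | None = None,
                   condition_first_look: str = "target") -> float:
    """FD% restricted to usable trials whose first JA look hit
    ``condition_first_look``; ``nan`` when no trial qualifies."""
    subset = [
        t for t in trials
        if t.usable and (task is None or t.task == task)
        and first_look(t.ja_fixations) == condition_first_look
    ]
    if not subset:
        return float("nan")
    return fixation_duration_pct(subset, aoi)


def participant_measures(trials: Sequence[Trial], task: str) -> dict[str, float]:
    """All analysis variables for one participant and one task."""
    counts = transition_counts(trials, task)
    per_trial = counts["per_trial_mean"]
    totals = counts["totals"]
    n_t, n_nt = first_look_counts(trials, task)

    out: dict[str, float] = {
        "n_usable": counts["n_usable"],
        "n_first_target": n_t,
        "n_first_nontarget": n_nt,
        "norm_accuracy": normalized_accuracy(n_t, n_nt),
        "fd_face": fixation_duration_pct(trials, "face", task),
        "fd_target": fixation_duration_pct(trials, "target", task),
        "fd_nontarget": fixation_duration_pct(trials, "non_target", task),
        "fd_face_first_target": conditional_fd(trials, "face", task, "target"),
        "fd_target_first_target": conditional_fd(trials, "target", task, "target"),
        "fd_nontarget_first_target": conditional_fd(
            trials, "non_target", task, "target"
        ),
    }
    for pair in TASK_PAIRS[task]:
        out[f"trans_{pair[0]}_to_{pair[1]}"] = per_trial[pair]
    if task == "IJA1":
        out["between_objects"] = counts["between_objects_per_trial"]
        out["norm_transition_score"] = norm_transition_score_ija1(
            totals[("target", "face")], totals[("non_target", "face")]
        )
    elif task == "RJA":
        out["norm_transition_score"] = norm_transition_score_rja(
            totals[("face", "target")], totals[("face", "non_target")]
        )
    return out


#: variables entering the group comparison per task, mirroring the reported
#: transition/score/fixation analyses
COMPARISON_VARIABLES = {
    "RJA": [
        "trans_face_to_target",
        "trans_face_to_non_target",
        "norm_transition_score",
        "norm_accuracy",
        "fd_face",
        "fd_target",
        "fd_nontarget",
    ],
    "IJA1": [
        "trans_target_to_face",
        "trans_non_target_to_face",
        "norm_transition_score",
        "trans_face_to_target",
        "trans_face_to_non_target",
        "between_objects",
        "norm_accuracy",
        "fd_face",
        "fd_target",
        "fd_nontarget",
        "fd_face_first_target",
    ],
    "IJA2": [
        "trans_target_to_face",
        "trans_face_to_target",
        "fd_face",
        "fd_target",
        "fd_face_first_target",
    ],
}
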