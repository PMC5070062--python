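"""Trial structure: task specifications, segmentation into phases, exclusions.

Each trial has three contiguous phases: ``looking_down`` (2 s), ``interaction``
(2 s) and ``ja`` (4 s in the gaze-following task RJA, 7 s in the two
initiating-JA tasks).  Trials are presented in blocks of four per task, block
order RJA, IJA1, IJA2 (12 trials per participant).

A trial is excluded when (1) it contains no face fixation during the
interaction phase (a face look there is the prerequisite for a joint-attention
episode), or (2) it contains no on-screen fixation at all during the JA phase.
Criterion 1 takes precedence when both apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import AnalysisError, ConfigError, DataError
from .events import (
    AOI,
    AOISet,
    Fixation,
    assign_aois,
    detect_fixations,
)
from .io import DEFAULT_GEOMETRY, GazeRecording, ScreenGeometry

TASKS = ("RJA", "IJA1", "IJA2")
PHASES = ("looking_down", "interaction", "ja")

#: canonical JA-phase duration per task (ms)
CANONICAL_JA_MS = {"RJA": 4000.0, "IJA1": 7000.0, "IJA2": 7000.0}

EXCLUSION_NONE = "none"
EXCLUSION_NO_FACE = "no_face_interactive"
EXCLUSION_AWAY = "away_whole_ja"


@dataclass(frozen=True)
class TaskSpec:
    """Timeline and AOI layout of one task block."""

    task: str
    segment_durations_ms: Mapping[str, float]
    trial_aois: tuple[AOISet, ...]  # one AOISet per trial, target side resolved

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ConfigError(f"unknown task {self.task!r}")
        for ph in PHASES:
            if ph not in self.segment_durations_ms:
                raise ConfigError(f"task {self.task}: missing segment {ph!r}")
            if self.segment_durations_ms[ph] <= 0:
                raise ConfigError(
                    f"task {self.task}: segment {ph!r} duration must be positive"
                )
        if len(self.trial_aois) < 1:
            raise ConfigError(f"task {self.task}: needs at least one trial")

    @property
    def n_trials(self) -> int:
        return len(self.trial_aois)

    @property
    def trial_duration_ms(self) -> float:
        return float(sum(self.segment_durations_ms[p] for p in PHASES))

    @property
    def ja_duration_ms(self) -> float:
        return float(self.segment_durations_ms["ja"])

    def phase_windows(self, onset_ms: float) -> dict[str, tuple[float, float]]:
        t = onset_ms
        out = {}
        for ph in PHASES:
            d = self.segment_durations_ms[ph]
            out[ph] = (t, t + d)
            t += d
        return out


@dataclass(frozen=True)
class StudyDesign:
    """The full stimulus protocol: ordered task blocks plus screen geometry."""

    tasks: tuple[TaskSpec, ...]
    geometry: ScreenGeometry = DEFAULT_GEOMETRY

    def __post_init__(self) -> None:
        names = [t.task for t in self.tasks]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate task blocks: {names}")

    @property
    def block_order(self) -> tuple[str, ...]:
        return tuple(t.task for t in self.tasks)

    def task(self, name: str) -> TaskSpec:
        for t in self.tasks:
            if t.task == name:
                return t
        raise KeyError(name)

    @property
    def n_trials(self) -> int:
        return sum(t.n_trials for t in self.tasks)

    def trial_plan(self) -> list[tuple[TaskSpec, int]]:
        """(task spec, within-task index) for every trial in presentation order."""
        return [(t, i) for t in self.tasks for i in range(t.n_trials)]


def default_trial_onsets(design: StudyDesign, gap_ms: float = 1000.0,
                         t0_ms: float = 0.0) -> list[float]:
    """Deterministic trial onsets with a fixed attention-getter gap before each
    trial; this is the timeline the synthetic generator uses."""
    onsets = []
    t = t0_ms
    for spec, _ in design.trial_plan():
        t += gap_ms
        onsets.append(t)
        t += spec.trial_duration_ms
    return onsets


# ---------------------------------------------------------------------------
# config parsing


def study_design_from_dict(payload: dict, source: str = "<config>") -> StudyDesign:
    problems: list[str] = []
    screen = payload.get("screen")
    if screen is None:
        problems.append("screen: missing")
        geometry = DEFAULT_GEOMETRY
    else:
        try:
            geometry = ScreenGeometry(**screen)
        except (TypeError, ConfigError) as exc:
            problems.append(f"screen: {exc}")
            geometry = DEFAULT_GEOMETRY
    tasks_cfg = payload.get("tasks")
    order = payload.get("block_order", list(TASKS))
    specs: list[TaskSpec] = []
    if not isinstance(tasks_cfg, dict):
        problems.append("tasks: missing or not a mapping")
    else:
        for name in order:
            cfg = tasks_cfg.get(name)
            if cfg is None:
                problems.append(f"tasks.{name}: missing")
                continue
            try:
                specs.append(_task_spec_from_dict(name, cfg))
            except ConfigError as exc:
                problems.append(f"tasks.{name}: {exc}")
    if problems:
        raise ConfigError(f"{source}: invalid study config: " + "; ".join(problems))
    return StudyDesign(tasks=tuple(specs), geometry=geometry)


def _task_spec_from_dict(name: str, cfg: dict) -> TaskSpec:
    segs = cfg.get("segments_ms")
    if not isinstance(segs, dict):
        raise ConfigError("segments_ms missing")
    for ph in PHASES:
        if segs.get(ph, 0) <= 0:
            raise ConfigError(f"segments_ms.{ph} must be positive")
    if name in CANONICAL_JA_MS and float(segs["ja"]) != CANONICAL_JA_MS[name]:
        raise ConfigError(
            f"segments_ms.ja must be {CANONICAL_JA_MS[name]:.0f} ms for {name}"
        )
    aois = cfg.get("aois")
    if not isinstance(aois, dict):
        raise ConfigError("aois missing")
    for key in ("face", "left_object", "right_object"):
        if key not in aois:
            raise ConfigError(f"aois.{key} missing")
    trials = cfg.get("trials")
    if not isinstance(trials, list) or not trials:
        raise ConfigError("trials must be a non-empty list")
    trial_sets = []
    for k, tr in enumerate(trials):
        side = tr.get("target_side")
        if side not in ("left", "right"):
            raise ConfigError(f"trials[{k}].target_side must be 'left' or 'right'")
        target_rect = aois["left_object" if side == "left" else "right_object"]
        nontarget_rect = aois["right_object" if side == "left" else "left_object"]
        trial_sets.append(
            AOISet(
                [
                    AOI("face", tuple(aois["face"])),
                    AOI("target", tuple(target_rect)),
                    AOI("non_target", tuple(nontarget_rect)),
                ]
            )
        )
    return TaskSpec(
        task=name,
        segment_durations_ms={p: float(segs[p]) for p in PHASES},
        trial_aois=tuple(trial_sets),
    )


# ---------------------------------------------------------------------------
# trials


@dataclass(frozen=True)
class Trial:
    task: str
    index: int  # within-task trial index
    onset_ms: float
    phase_windows: Mapping[str, tuple[float, float]]
    fixations_by_phase: Mapping[str, tuple[Fixation, ...]]
    usable: bool = True
    exclusion_reason: str = EXCLUSION_NONE

    @property
    def ja_fixations(self) -> tuple[Fixation, ...]:
        return self.fixations_by_phase["ja"]


def _majority_phase(fix: Fixation, windows: Mapping[str, tuple[float, float]]) -> str | None:
    """Phase holding the majority of the fixation's duration; ties go to the
    earlier phase.  Returns None when the fixation does not overlap the trial."""
    best = None
    best_overlap = 0.0
    for ph in PHASES:
        lo, hi = windows[ph]
        overlap = min(fix.offset_ms, hi) - max(fix.onset_ms, lo)
        if overlap > best_overlap:  # strict: ties keep the earlier phase
            best = ph
            best_overlap = overlap
    return best


def segment_trials(
    rec: GazeRecording,
    design: StudyDesign,
    trial_onsets: Sequence[float],
    fixations: Sequence[Fixation] | None = None,
    **detect_kwargs,
) -> list[Trial]:
    """Cut a recording into trials, assign fixations to phases and label AOIs.

    ``trial_onsets`` must follow the design's trial plan (one onset per trial,
    in presentation order, non-overlapping).  Fixations are detected once over
    the whole recording unless supplied.
    """
    plan = design.trial_plan()
    if len(trial_onsets) != len(plan):
        raise DataError(
            f"expected {len(plan)} trial onsets, got {len(trial_onsets)}"
        )
    prev_end = -np.inf
    for (spec, _), onset in zip(plan, trial_onsets):
        if onset < prev_end:
            raise DataError(f"overlapping trials at onset {onset} ms")
        prev_end = onset + spec.trial_duration_ms
    if fixations is None:
        fixations = detect_fixations(rec, **detect_kwargs)

    trials: list[Trial] = []
    for (spec, idx), onset in zip(plan, trial_onsets):
        windows = spec.phase_windows(onset)
        lo, hi = onset, onset + spec.trial_duration_ms
        in_trial = [f for f in fixations
                    if min(f.offset_ms, hi) - max(f.onset_ms, lo) > 0
                    or (f.onset_ms == f.offset_ms and lo <= f.onset_ms < hi)]
        labelled = assign_aois(in_trial, spec.trial_aois[idx])
        by_phase: dict[str, list[Fixation]] = {p: [] for p in PHASES}
        for f in labelled:
            ph = _majority_phase(f, windows)
            if ph is not None:
                by_phase[ph].append(f)
        trials.append(
            Trial(
                task=spec.task,
                index=idx,
                onset_ms=float(onset),
                phase_windows=windows,
                fixations_by_phase={p: tuple(v) for p, v in by_phase.items()},
            )
        )
    return trials


def apply_exclusions(trial: Trial) -> Trial:
    """Flag a trial as unusable per the two exclusion criteria (1 before 2)."""
    face_in_interaction = any(
        f.aoi == "face" for f in trial.fixations_by_phase["interaction"]
    )
    if not face_in_interaction:
        return replace(trial, usable=False, exclusion_reason=EXCLUSION_NO_FACE)
    if len(trial.fixations_by_phase["ja"]) == 0:
        return replace(trial, usable=False, exclusion_reason=EXCLUSION_AWAY)
    return replace(trial, usable=True, exclusion_reason=EXCLUSION_NONE)


def apply_exclusions_all(trials: Sequence[Trial]) -> list[Trial]:
    return [apply_exclusions(t) for t in trials]


def usable_trial_summary(
    trials_by_participant: Mapping[str, Sequence[Trial]],
    group_by_participant: Mapping[str, str] | None = None,
):
    """Per-participant usable-trial counts (overall and per task) as a DataFrame.

    When groups are supplied a second frame with group means/SDs is returned.
    """
    import pandas as pd

    rows = []
    for pid, trials in trials_by_participant.items():
        row = {"participant_id": pid}
        for task in TASKS:
            row[f"usable_{task}"] = sum(
                1 for t in trials if t.task == task and t.usable
            )
        row["usable_total"] = sum(1 for t in trials if t.usable)
        if group_by_participant is not None:
            row["group"] = group_by_participant[pid]
        rows.append(row)
    per_participant = pd.DataFrame(rows)
    if group_by_participant is None or per_participant.empty:
        return per_participant, pd.DataFrame()
    stats = (
        per_participant.groupby("group")["usable_total"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return per_participant, stats
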