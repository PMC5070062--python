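"""End-to-end study orchestration: simulate or load recordings, run the event
and measure layers, compute the group statistics and write the report bundle.

The report bundle is plain CSV plus a JSON manifest so that every number is
diff-able and reproducible by calling the underlying module functions on the
same inputs.  Columns are documented in ``docs/data_dictionary.md``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .errors import AnalysisError, ConfigError
from .events import detect_fixations
from .io import (
    GazeRecording,
    load_default_design,
    load_task_config,
    read_gaze_csv,
    read_metadata_csv,
)
from .measures import COMPARISON_VARIABLES, participant_measures
from .simulate import calibrated_presets, generate_participant
from .stats import bh_fdr, compare_groups, usable_trials_anova
from .trials import (
    StudyDesign,
    TASKS,
    Trial,
    apply_exclusions_all,
    default_trial_onsets,
    segment_trials,
    usable_trial_summary,
)


@dataclass
class StudyConfig:
    """Inputs and options for one study run.

    Either ``data_dir``/``metadata_path`` point at canonical gaze CSVs (one
    ``<participant_id>.csv`` per participant) plus a metadata table, or the
    study is simulated from the packaged calibrated presets with ``n_asd`` /
    ``n_td`` participants.
    """

    out_dir: str | Path | None = None
    seed: int = 0
    n_asd: int = 17
    n_td: int = 15
    data_dir: str | Path | None = None
    metadata_path: str | Path | None = None
    task_config_path: str | Path | None = None
    trial_gap_ms: float = 1000.0
    alpha: float = 0.05
    fdr_q: float = 0.05
    fdr_family: str = "per_task"  # or "global"
    dispersion_max_deg: float = 1.0
    min_fixation_ms: float = 60.0
    max_gap_ms: float = 75.0

    def __post_init__(self) -> None:
        if self.fdr_family not in ("per_task", "global"):
            raise ConfigError("fdr_family must be 'per_task' or 'global'")
        if self.data_dir is not None and self.metadata_path is None:
            raise ConfigError("metadata_path required when data_dir is given")


@dataclass
class StudyResult:
    measures: pd.DataFrame  # one row per participant x task
    comparisons: pd.DataFrame  # Table-2-style group statistics
    usable: pd.DataFrame  # per-participant usable-trial counts
    usable_stats: pd.DataFrame
    usable_anova: dict
    fd_summary: pd.DataFrame  # FD% group means per task/AOI
    correlations: pd.DataFrame
    manifest: dict
    trials_by_participant: dict[str, list[Trial]] = field(repr=False, default_factory=dict)


def _load_recordings(config: StudyConfig, design: StudyDesign) -> list[GazeRecording]:
    meta = read_metadata_csv(config.metadata_path)
    data_dir = Path(config.data_dir)
    recs = []
    for row in meta.itertuples(index=False):
        path = data_dir / f"{row.participant_id}.csv"
        if not path.exists():
            raise ConfigError(f"gaze log missing for {row.participant_id}: {path}")
        recs.append(
            read_gaze_csv(
                path, design.geometry, participant_id=str(row.participant_id),
                group=row.group, covariate=float(row.covariate),
            )
        )
    return recs


def _simulate_recordings(config: StudyConfig, design: StudyDesign):
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_asd + config.n_td)
    presets = calibrated_presets()
    recs, truths = [], []
    labels = [("ASD", i) for i in range(config.n_asd)] + [
        ("TD", i) for i in range(config.n_td)
    ]
    for (group, i), ss in zip(labels, children):
        by_task = {task: presets[(group, task)] for task in design.block_order}
        pid = f"{group}{i:03d}"
        rec, truth = generate_participant(
            by_task, design, np.random.default_rng(ss), participant_id=pid,
            group=group, gap_ms=config.trial_gap_ms,
        )
        recs.append(rec)
        truths.append(truth)
    return recs, truths


def analyze_recordings(
    recordings: Sequence[GazeRecording],
    design: StudyDesign,
    trial_onsets: Mapping[str, Sequence[float]] | Sequence[float] | None = None,
    config: StudyConfig | None = None,
) -> StudyResult:
    """Run the full analysis on ready-made recordings.

    ``trial_onsets`` may be a single onset list shared by all participants
    (default: the deterministic attention-getter timeline) or a mapping
    participant_id -> onsets.
    """
    config = config or StudyConfig()
    if trial_onsets is None:
        trial_onsets = default_trial_onsets(design, gap_ms=config.trial_gap_ms)

    detect_kwargs = dict(
        dispersion_max_deg=config.dispersion_max_deg,
        min_duration_ms=config.min_fixation_ms,
        max_gap_ms=config.max_gap_ms,
    )

    rows = []
    trials_by_pid: dict[str, list[Trial]] = {}
    group_by_pid: dict[str, str] = {}
    exclusion_counts = {"no_face_interactive": 0, "away_whole_ja": 0}
    for rec in recordings:
        onsets = (
            trial_onsets[rec.participant_id]
            if isinstance(trial_onsets, Mapping)
            else trial_onsets
        )
        fixations = detect_fixations(rec, **detect_kwargs)
        trials = apply_exclusions_all(
            segment_trials(rec, design, onsets, fixations=fixations)
        )
        trials_by_pid[rec.participant_id] = trials
        group_by_pid[rec.participant_id] = rec.group
        for t in trials:
            if t.exclusion_reason in exclusion_counts:
                exclusion_counts[t.exclusion_reason] += 1
        for task in design.block_order:
            row = {
                "participant_id": rec.participant_id,
                "group": rec.group,
                "covariate": rec.covariate,
                "task": task,
            }
            row.update(participant_measures(trials, task))
            rows.append(row)
    measures = pd.DataFrame(rows)

    comparisons = _group_comparisons(measures, config)
    usable, usable_stats = usable_trial_summary(trials_by_pid, group_by_pid)
    usable_anova = _usable_anova_or_note(usable)
    fd_summary = _fd_summary(measures)
    correlations = _cross_task_correlations(measures)

    manifest = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "n_participants": len(recordings),
        "groups": {g: int(np.sum([gr == g for gr in group_by_pid.values()]))
                   for g in ("ASD", "TD")},
        "excluded_trials_by_reason": exclusion_counts,
        "options": {
            "alpha": config.alpha,
            "fdr_q": config.fdr_q,
            "fdr_family": config.fdr_family,
            "dispersion_max_deg": config.dispersion_max_deg,
            "min_fixation_ms": config.min_fixation_ms,
            "max_gap_ms": config.max_gap_ms,
            "trial_gap_ms": config.trial_gap_ms,
        },
    }
    return StudyResult(
        measures=measures,
        comparisons=comparisons,
        usable=usable,
        usable_stats=usable_stats,
        usable_anova=usable_anova,
        fd_summary=fd_summary,
        correlations=correlations,
        manifest=manifest,
        trials_by_participant=trials_by_pid,
    )


def _usable_anova_or_note(usable: pd.DataFrame) -> dict:
    long = usable.melt(
        id_vars=[c for c in ("participant_id", "group") if c in usable.columns],
        value_vars=[f"usable_{t}" for t in TASKS],
        var_name="task",
        value_name="count",
    )
    long["task"] = long["task"].str.removeprefix("usable_")
    try:
        return usable_trials_anova(long)
    except AnalysisError as exc:
        return {"error": str(exc)}


def _group_comparisons(measures: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    rows = []
    for task in TASKS:
        sub = measures[measures["task"] == task]
        if sub.empty:
            continue
        for var in COMPARISON_VARIABLES[task]:
            if var not in sub.columns:
                continue
            try:
                cmp_res = compare_groups(sub, var)
            except AnalysisError:
                continue
            row = {"task": task, "variable": var}
            for g, (m, sd, n) in cmp_res.group_stats.items():
                row[f"mean_{g}"] = m
                row[f"sd_{g}"] = sd
                row[f"n_{g}"] = n
            row.update(
                F=cmp_res.F, p=cmp_res.p, eta2_partial=cmp_res.eta2_partial,
                ranked=cmp_res.ranked, levene_p=cmp_res.levene_p,
            )
            rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr_significant"] = False
    if config.fdr_family == "global":
        out["fdr_significant"] = bh_fdr(out["p"].to_numpy(), q=config.fdr_q)
    else:
        for task in out["task"].unique():
            mask = out["task"] == task
            out.loc[mask, "fdr_significant"] = bh_fdr(
                out.loc[mask, "p"].to_numpy(), q=config.fdr_q
            )
    return out


def _fd_summary(measures: pd.DataFrame) -> pd.DataFrame:
    rows = []
    fd_cols = ["fd_face", "fd_target", "fd_nontarget", "fd_face_first_target"]
    for task in TASKS:
        sub = measures[measures["task"] == task]
        for g in ("ASD", "TD"):
            gsub = sub[sub["group"] == g]
            if gsub.empty:
                continue
            row = {"task": task, "group": g}
            for col in fd_cols:
                vals = gsub[col].to_numpy(float)
                vals = vals[np.isfinite(vals)]
                row[f"{col}_mean"] = float(np.mean(vals)) if len(vals) else float("nan")
                row[f"{col}_sd"] = (
                    float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
                )
            rows.append(row)
    return pd.DataFrame(rows)


#: measure pairs compared across the two initiating tasks
CROSS_TASK_PAIRS = [
    ("trans_target_to_face", "IJA1", "IJA2"),
    ("trans_face_to_target", "IJA1", "IJA2"),
]


def _cross_task_correlations(measures: pd.DataFrame) -> pd.DataFrame:
    from .stats import auto_correlation

    rows = []
    for var, task_a, task_b in CROSS_TASK_PAIRS:
        a = measures[measures["task"] == task_a].set_index("participant_id")
        b = measures[measures["task"] == task_b].set_index("participant_id")
        for g in ("ASD", "TD"):
            ga = a[a["group"] == g]
            gb = b[b["group"] == g]
            common = ga.index.intersection(gb.index)
            if len(common) < 4:
                continue
            try:
                res = auto_correlation(
                    ga.loc[common, var], gb.loc[common, var],
                    names=(f"{var}@{task_a}", f"{var}@{task_b}"),
                )
            except ValueError:
                continue
            rows.append(
                {
                    "group": g, "variable": var, "task_a": task_a,
                    "task_b": task_b, "method": res.method, "r": res.r,
                    "p": res.p, "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> StudyResult:
    """Run a full study (simulated or from files) and, when ``out_dir`` is set,
    write the report bundle: per-participant measures, group comparisons,
    FD% summary, correlations, usable-trial counts and a run manifest."""
    design = (
        load_task_config(config.task_config_path)
        if config.task_config_path
        else load_default_design()
    )
    if config.data_dir is not None:
        recordings = _load_recordings(config, design)
        truths = None
    else:
        recordings, truths = _simulate_recordings(config, design)
    result = analyze_recordings(recordings, design, config=config)
    result.manifest["mode"] = "files" if config.data_dir is not None else "simulated"
    if config.out_dir is not None:
        _write_bundle(result, Path(config.out_dir))
    return result


def _write_bundle(result: StudyResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    result.measures.to_csv(out_dir / "participant_measures.csv", index=False,
                           float_format=fmt)
    result.comparisons.to_csv(out_dir / "group_comparisons.csv", index=False,
                              float_format=fmt)
    result.fd_summary.to_csv(out_dir / "fd_summary.csv", index=False,
                             float_format=fmt)
    result.correlations.to_csv(out_dir / "correlations.csv", index=False,
                               float_format=fmt)
    result.usable.to_csv(out_dir / "usable_trials.csv", index=False,
                         float_format=fmt)
    manifest = dict(result.manifest)
    manifest["usable_trials_anova"] = result.usable_anova
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
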