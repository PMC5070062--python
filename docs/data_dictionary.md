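# Data dictionary

## Canonical gaze CSV (`<participant_id>.csv`)

| column | type | meaning |
|---|---|---|
| `t_ms` | float | time since recording start, ms; strictly increasing |
| `x_px`, `y_px` | float | combined-eye gaze point, screen pixels (origin top-left); sentinel 0 when invalid |
| `valid_l`, `valid_r` | 0/1 | per-eye validity; a sample enters analysis when either eye is valid and the point is on screen |

## Participant metadata CSV

`participant_id` (string), `group` (`ASD`/`TD`), `covariate` (nonverbal
developmental score, finite float).

## Task configuration JSON

`screen` (pixel and physical geometry incl. viewing distance), `block_order`,
and per task: `segments_ms` (`looking_down`, `interaction`, `ja`), `aois`
(`face`, `left_object`, `right_object` rectangles `[x0, y0, x1, y1]`,
half-open), `trials` (list of `{"target_side": "left"|"right"}`).

## Report bundle (written by `run_study`)

### participant_measures.csv — one row per participant × task

| column | meaning |
|---|---|
| `participant_id`, `group`, `covariate`, `task` | identifiers |
| `n_usable` | usable trials for this task (of 4) |
| `n_first_target`, `n_first_nontarget` | trials whose first JA object look hit target / non-target |
| `norm_accuracy` | (n_first_target − n_first_nontarget)/(sum); NaN when no object look |
| `trans_<a>_to_<b>` | per-trial mean transition count for the ordered AOI pair |
| `between_objects` | per-trial mean target↔non-target transitions pooled (IJA1) |
| `norm_transition_score` | normalized transition score (RJA, IJA1) |
| `fd_face`, `fd_target`, `fd_nontarget` | FD% of JA fixation time per AOI |
| `fd_*_first_target` | same, restricted to trials with first look at target |

### group_comparisons.csv — one row per tested variable

`task`, `variable`, `mean_/sd_/n_` per group (raw scale), `F`, `p`,
`eta2_partial`, `ranked` (True when the rank ANCOVA was used), `levene_p`,
`fdr_significant` (BH at q = 0.05 within the configured family).

### fd_summary.csv

Group mean ± SD of the FD% measures per task (the bar-plot summary;
`jagaze.viz.plot_fd_summary` draws it).

### correlations.csv

Cross-task correlations of matching transition measures per group:
`group`, `variable`, `task_a`, `task_b`, `method` (pearson/spearman), `r`,
`p`, `n`.

### usable_trials.csv

`participant_id`, `usable_RJA`, `usable_IJA1`, `usable_IJA2`, `usable_total`,
`group`.

### manifest.json

Seed, package version, participant counts per group, excluded-trial counts by
reason, all analysis options, the usable-trials repeated-measures ANOVA, and
the run mode (simulated vs files).
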