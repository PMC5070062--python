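"""Per-participant joint-attention measures for each task.

Normalized accuracy and transition scores lie in [-1, 1]; positive values mean
a preference for the target object (or for target-linked transitions).  FD% is
the share of JA-phase fixation time spent on an AOI.
"""

from jagaze import (
    apply_exclusions_all,
    default_trial_onsets,
    generate_participant,
    load_default_design,
    participant_measures,
    presets_for_group,
    segment_trials,
)

design = load_default_design()
rec, _ = generate_participant(presets_for_group("TD"), design, seed=3,
                              participant_id="TD000", group="TD")
trials = apply_exclusions_all(
    segment_trials(rec, design, default_trial_onsets(design))
)
print(f"usable trials: {sum(t.usable for t in trials)}/12")
for task in design.block_order:
    m = participant_measures(trials, task)
    print(f"\n{task}: usable {m['n_usable']}, "
          f"first looks T/NT {m['n_first_target']}/{m['n_first_nontarget']}, "
          f"accuracy {m['norm_accuracy']:+.2f}")
    print(f"  FD% face {m['fd_face']:.1f}  target {m['fd_target']:.1f}  "
          f"non-target {m['fd_nontarget']:.1f}")
    if "norm_transition_score" in m:
        print(f"  normalized transition score {m['norm_transition_score']:+.2f}")
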