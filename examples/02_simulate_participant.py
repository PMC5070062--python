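"""Simulate one participant's full session.

Twelve trials in three blocks (gaze-following RJA, then the two initiating-JA
tasks), 120 Hz binocular samples, with attention-getter gaps between trials.
The generator also returns the ground truth (dwell sequences, transition
counts, exclusion events) so recovery can be checked downstream.
"""

from jagaze import generate_participant, load_default_design, presets_for_group

design = load_default_design()
presets = presets_for_group("ASD")

rec, truth = generate_participant(presets, design, seed=42,
                                  participant_id="ASD000", group="ASD")

n_valid = int((rec.samples[["valid_l", "valid_r"]].any(axis=1)).sum())
print(f"participant {rec.participant_id}: {len(rec.samples)} samples "
      f"({n_valid} valid), covariate {rec.covariate:.1f}")
print(f"trials: {[t.task for t in truth.trials]}")

usable = sum(t.usable_expected for t in truth.trials)
print(f"trials expected usable after exclusion criteria: {usable}/12")

t = truth.trials[8]  # first initiating JA-2 trial
print(f"trial {t.task}#{t.index}: {len(t.ja_dwells)} JA dwells, "
      f"transitions {dict(t.transition_counts)}")
# Each ordered pair counts moves between AOI fixations; 'elsewhere' dwells are
# transparent, mirroring how the analysis treats off-AOI fixations.
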