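"""From raw samples to fixations, AOI labels and transitions for one trial.

Fixation detection is dispersion-based (bounding-box width + height within
1 degree of visual angle) with the 60 ms minimum-duration threshold; fixations
are labelled by the AOI containing their centroid and consecutive
differently-labelled fixations form transitions.
"""

from jagaze import (
    detect_fixations,
    extract_transitions,
    first_look,
    generate_trial,
    load_default_design,
    presets_for_group,
)
from jagaze.events import assign_aois

design = load_default_design()
spec = design.task("IJA1")
preset = presets_for_group("ASD")["IJA1"]

frame, truth = generate_trial(preset, spec, seed=7)
fixations = detect_fixations(frame, design.geometry)
labelled = assign_aois(fixations, spec.trial_aois[0])

print(f"{len(frame)} samples -> {len(fixations)} fixations")
for f in labelled[:5]:
    print(f"  {f.onset_ms:7.1f}-{f.offset_ms:7.1f} ms  "
          f"({f.cx_px:6.1f},{f.cy_px:6.1f})  {f.aoi}")

ja = [f for f in labelled if f.onset_ms >= 4000.0]  # JA phase starts at 4 s
transitions = extract_transitions(ja)
print(f"JA phase: {len(ja)} fixations, {len(transitions)} transitions")
print("first object look:", first_look(ja))

counts = {}
for tr in transitions:
    counts[(tr.from_aoi, tr.to_aoi)] = counts.get((tr.from_aoi, tr.to_aoi), 0) + 1
print("measured:", counts)
print("truth:   ", dict(truth.transition_counts))
# With the default low jitter the measured counts equal the generator's truth.
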