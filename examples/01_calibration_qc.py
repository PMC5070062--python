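"""Calibration quality control.

Five-point calibration leaves a deviation (dx, dy) in degrees of visual angle
at each point.  Quality is summarised as the RMS over the pooled x/y
components; the session passes when every component is below 2 degrees.
"""

from jagaze import compute_calibration_rms

deviations = [(0.4, -0.6), (1.1, 0.3), (-0.2, 0.5), (0.8, -0.9), (0.1, 0.2)]
res = compute_calibration_rms(deviations)
print(f"calibration RMS: {res.rms_deg:.3f} deg, pass: {res.passed}")

bad = deviations + [(2.4, 0.0)]  # one component beyond the 2 deg criterion
res = compute_calibration_rms(bad)
print(f"with a 2.4 deg outlier: RMS {res.rms_deg:.3f} deg, pass: {res.passed}")

# The RMS pools all x and y components, so a single bad point raises it only
# modestly — the pass criterion, being per-component, is what catches it.
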