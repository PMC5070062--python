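# Methods

This note documents the models, conventions and numerical choices behind
`jagaze`, in the order data flows through the package.

## Coordinates, geometry, calibration QC

All positions are screen pixels, origin top-left, x rightward, y downward,
half-open bounds `[0, width) × [0, height)`. The default geometry is a
22-inch 16:10 monitor (1680×1050 px, 47.4×29.6 cm) viewed at 50 cm. A pixel
extent `s` converts to visual angle as `2·atan(s_cm / 2d)`.

Calibration quality is the RMS over the pooled x and y deviation components
of the calibration points; the pass criterion is per-component (`|dx|, |dy| <
2°` at every point). Pooling components is a choice — the protocol this
mirrors reports a single RMS without stating whether components were pooled
or averaged per point.

Binocular combination (SMI-style raw exports): average the two points of
regard when both eyes are valid, use the valid eye when one is, invalid
otherwise. Samples flagged invalid, or valid but off-screen, never enter
event detection.

## Fixation detection

Dispersion-based (I-DT) semantics with a greedy left-to-right scan: from each
start sample the window is extended while (a) the gap to the next valid
sample is ≤ 75 ms and (b) the bounding-box dispersion (x-extent + y-extent,
degrees) stays ≤ 1.0°. If the resulting maximal window spans ≥ 60 ms
(last-minus-first sample time) it becomes a fixation (centroid = mean of its
samples) and the scan resumes after it; otherwise the start advances one
sample. The rule is deterministic and is verified against an exhaustive
brute-force implementation in the tests.

Choices worth knowing:

- the 60 ms threshold is the protocol's; the 1.0° ceiling matches the stated
  tracker accuracy ("better than 1 degree") since the protocol applied only a
  duration threshold to vendor-preprocessed data;
- the threshold is applied before AOI assignment;
- 75 ms ≈ 9 samples at 120 Hz: blinks shorter than that are bridged, longer
  ones split fixations (harmless for transition counts, since split parts
  share an AOI).

## AOIs, transitions, first look

AOIs are half-open rectangles (face, target, non-target; the object roles are
resolved per trial from the target side). A fixation gets the AOI containing
its centroid, else `none`. Transitions connect consecutive AOI-labelled
fixations with different labels; `none` fixations are *transparent* (skipped,
not chain-breaking) because scan paths traverse empty screen between AOIs —
breaking on every off-AOI fixation would undercount all transition types.
First look is the first JA-phase fixation on either object; face fixations
before it are ignored (the face is the interaction anchor, not an object).

## Trials and exclusions

Phases are contiguous windows (2 s looking-down, 2 s interaction, 4 or 7 s
JA). A fixation straddling a boundary belongs to the phase holding the
majority of its duration; ties go to the earlier phase. Exclusions: (1) no
face fixation in the interaction phase — "looking at the face" is
operationalized as ≥ 1 face fixation, i.e. a ≥ 60 ms dwell; (2) no on-screen
fixation in the JA phase ("looking away" = invalid or off-screen gaze only).
Criterion 1 takes precedence. Excluded trials contribute to no measure.

## Measures

Normalized scores are `(a − b)/(a + b)` and hence lie in [−1, 1], are
antisymmetric under swapping target/non-target, and are *undefined* (NaN, not
zero) when `a + b = 0`; undefined values propagate into statistics as
missingness. FD% uses the all-inclusive denominator (total JA fixation time,
off-AOI fixations included) — "on-trial FD" is read as total fixation time.
Per-trial transition means divide a participant's totals by their usable
trial count for that task.

## Statistics

- ANCOVA: `dv ~ group + covariate`, no interaction; with one two-level factor
  and one covariate, the Type III group SS equals the extra SS of the group
  term given the covariate, computed by comparing the full and reduced least
  squares fits (cross-checked against `pingouin.ancova`). Partial η² =
  SS_group/(SS_group + SS_resid). Degenerate inputs (zero residual and zero
  group SS, e.g. all-tied ranks) return F = 0, p = 1 by convention.
- Rank ANCOVA (Conover–Iman): midranks of dv and covariate, pooled across
  groups, then the same model. Group means/SDs are reported on the raw scale.
- Normality gate: Shapiro–Wilk per group at α = 0.05; the parametric ANCOVA
  runs only when both groups pass. Constant samples count as non-normal.
- BH-FDR: step-up, boundary inclusive (`p_(k) ≤ k·q/m`), q = 0.05, applied
  within each task's family of comparisons by default (`fdr_family="global"`
  is available; the original family definition is not stated anywhere).
- Correlations: Pearson when both variables pass the gate, else Spearman.
- Usable-trial counts: mixed (within = task, between = group) repeated-
  measures ANOVA via `pingouin.mixed_anova`.

## Synthetic gaze generator

The generator emulates what the analysis assumes about real data, not the
oculomotor physiology. Within the JA phase, gaze is a semi-Markov process
over states {face, target, non-target, elsewhere}: state dwells are
log-normal (truncated at the phase end), the next state comes from an
embedded Markov chain with zero diagonal, and samples sit at the state's
anchor (AOI centre, or a fixed off-AOI point for `elsewhere`) plus isotropic
Gaussian jitter (default SD 3 px ≈ 0.1°, small enough that a dwell almost
never splits under the 1° dispersion ceiling). The looking-down phase is a
face dwell; the interaction phase is elsewhere–face–elsewhere (200/1600/200 ms)
so that fixations never merge across phase boundaries. Between trials an
attention-getter gap inserts a 500 ms centre look plus 500 ms of invalid
samples. Blinks are Poisson (0.1 /s, 120 ms) invalid windows.

Attrition is injected as two independent per-trial events mirroring the
exclusion criteria: with `p_skip` the interaction phase contains no face
dwell; with `p_away` the JA phase is entirely off-screen. The packaged split
is symmetric, `p_skip = p_away = 1 − √(1 − p)`, with p = 0.10 (ASD) and
0.075 (TD) so the expected usable-trial means are 10.8 and 11.1 of 12.
Covariates are drawn per group from N(85, 24.2²) (ASD) and N(107.1, 15.2²)
(TD). Dwell parameters: mean 400 ms (SD 200) in the 7 s initiating phases,
320 ms (SD 160) in the 4 s responding phase — right-skewed dwells in the
range typical of toddler AOI looks; these were fixed once, before any
calibration, and are not tuned.

### Calibration to the published group means

With a state-independent dwell distribution the dwell starts form a renewal
process, so the expected number of dwells in a phase of length `T` is
`D ≈ T/μ + (σ² + μ²)/(2μ²)`. Starting the chain from its stationary
distribution π, the expected *measured* count of the ordered AOI pair (a, b)
per trial is

    E[c_ab] ≈ κ · π_a · ( P[a,b]·(D−1) + P[a,e]·P[e,b]·(D−2) )

(the second term is the elsewhere-mediated route, which transition extraction
treats as a direct move; κ corrects for the final truncated dwell falling
below the fixation-detection threshold, κ = 1 − P(residual < 60 ms + Δt)/(D−1)).
`calibrated_presets()` inverts this map by least squares over
softmax-parameterised chain rows; a soft penalty selects the solution with a
plausible share of off-AOI time (8–20 % depending on task). Large-n
simulation places every implied mean within sampling error of its target
(|z| ≤ 1.3 at n = 300 participants).

Two consequences of stationarity matter when reading the targets. Expected
in-flow equals expected out-flow for every state, so (i) in the two-AOI
initiating JA-2 task the two directions face↔target must have equal expected
counts — the presets pin the FDR-significant published entries (ASD
target→face 3.62, TD face→target 1.31) and the reverse directions inherit
them; (ii) the published ASD initiating JA-1 row is internally inconsistent
(its counts 3.31/0.50 imply a normalized score of 0.74, not the printed
0.36), so the ASD preset keeps the published total object→face flow
(3.81/trial) split 2.588/1.218, which implies the printed score 0.36 and
preserves all group orderings; the remaining entries are projected onto the
nearest flow-balanced set. The responding-JA presets are identical for both
groups (the protocol found no group differences there) and use the
across-group means of the published counts.

`first_look_p_target` can force the first object look (for tests); the
calibrated presets leave it unset so the closed-form calibration stays exact.
Chain-driven first looks make the responding-JA accuracy hover near zero,
consistent with the near-zero published responding-JA transition scores.

### What a green test establishes — and what it does not

The generator reproduces the *statistical structure* the analysis consumes:
dwell/transition dynamics, measurement jitter, blinks, validity gaps,
attrition, group contrasts, covariate distributions. It does not emulate
saccade kinematics, smooth pursuit, head movement, drift, participant-level
heterogeneity of preferences (all children in a group share one preset), or
AOIs that move with the stimulus. Recovery tests therefore validate the
pipeline's correctness and the calibration's self-consistency — not the
empirical claims of any particular study, whose recordings are not public.

## Numerical conventions

- Undefined measures are NaN and are dropped per variable, never imputed.
- Ties: phase assignment → earlier phase; BH boundary → reject; first-look
  override consumes the first object entry only.
- The acceptance script derives every RNG stream from `--seed` via
  `SeedSequence([seed, offset])` with fixed per-target offsets, so runs are
  reproducible and targets independent.
- Determinism: identical seeds give bit-identical sample streams, measures
  and report CSVs (fixed float formatting in the writers).

## Known limitations

- The closed-form calibration is first-order in boundary effects (truncated
  final dwell, non-stationary start of the induced AOI chain); residual bias
  is below sampling error at the study's n but would surface at n ≫ 10³.
- The exclusion model is exact by construction (the generator implements the
  criteria it is tested against); it cannot detect mis-specified criteria.
- Rank-ANCOVA p-values rely on the F reference distribution on ranks, which
  is approximate for small n; its type-I error is simulation-checked at
  n = 16/group.
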