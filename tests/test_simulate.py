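import math

import numpy as np
import pandas as pd
import pytest

from jagaze.errors import CalibrationError, ConfigError
from jagaze.events import detect_fixations
from jagaze.io import GazeRecording
from jagaze.measures import transition_counts
from jagaze.simulate import (
    ATTRITION,
    CALIBRATION_TARGETS,
    GeneratorPreset,
    JA_MS,
    attrition_probabilities,
    expected_transition_counts,
    expected_usable_trials,
    generate_participant,
    generate_trial,
    solve_chain,
    stationary_distribution,
)
from jagaze.trials import apply_exclusions_all, default_trial_onsets, segment_trials

DT = 1000.0 / 120.0


def two_state_preset(**kw):
    args = dict(
        group="ASD", task="IJA2", states=("face", "target"),
        transition_matrix=((0.0, 1.0), (1.0, 0.0)),
        dwell_mean_ms=500.0, dwell_sd_ms=0.0, noise_sd_px=0.0,
        blink_rate_hz=0.0,
    )
    args.update(kw)
    return GeneratorPreset(**args)


class TestPresetValidation:
    def test_rows_must_be_stochastic(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            two_state_preset(transition_matrix=((0.0, 0.5), (1.0, 0.0)))

    def test_diagonal_must_be_zero(self):
        with pytest.raises(ConfigError, match="diagonal"):
            two_state_preset(transition_matrix=((0.5, 0.5), (1.0, 0.0)))

    def test_aoi_dwell_means_must_be_detectable(self):
        with pytest.raises(ConfigError, match="60 ms"):
            two_state_preset(dwell_mean_ms=50.0)

    def test_probabilities_in_unit_interval(self):
        with pytest.raises(ConfigError):
            two_state_preset(p_away_whole_ja=1.5)


class TestGenerateTrial:
    def test_forced_alternation_deterministic_dwells(self, design):
        """Zero-variance 500 ms dwells over a 7 s JA phase: 14 dwells (starts
        at 0, 500, ..., 6500 ms), hence 13 alternating transitions."""
        spec = design.task("IJA2")
        _, truth = generate_trial(two_state_preset(), spec, seed=0)
        assert len(truth.ja_dwells) == 14
        states = [s for s, _, _ in truth.ja_dwells]
        assert all(a != b for a, b in zip(states, states[1:]))
        assert sum(truth.transition_counts.values()) == 13
        ft = truth.transition_counts[("face", "target")]
        tf = truth.transition_counts[("target", "face")]
        assert {ft, tf} == {6, 7}

    def test_away_whole_ja_every_sample_invalid(self, design):
        spec = design.task("IJA2")
        frame, truth = generate_trial(
            two_state_preset(p_away_whole_ja=1.0), spec, seed=1
        )
        assert truth.away_fired
        ja_lo = 4000.0
        in_ja = frame["t_ms"] >= ja_lo
        assert not frame.loc[in_ja, "valid_l"].any()
        assert (frame.loc[in_ja, "x_px"] == 0).all()  # sentinel coordinates

    def test_zero_noise_single_state_sits_on_centroid(self, design):
        spec = design.task("IJA2")
        # elsewhere unreachable: face<->target with target prob 0 -> face/elsewhere
        preset = GeneratorPreset(
            group="ASD", task="IJA2", states=("face", "target"),
            transition_matrix=((0.0, 1.0), (1.0, 0.0)),
            dwell_mean_ms={"face": 8000.0, "target": 8000.0},
            dwell_sd_ms=0.0, noise_sd_px=0.0, blink_rate_hz=0.0,
        )
        frame, truth = generate_trial(preset, spec, seed=2)
        assert len(truth.ja_dwells) == 1  # one dwell covers the whole phase
        state = truth.ja_dwells[0][0]
        center = spec.trial_aois[0][state].center
        in_ja = frame["t_ms"] >= 4000.0
        assert (frame.loc[in_ja, "x_px"] == center[0]).all()
        assert (frame.loc[in_ja, "y_px"] == center[1]).all()

    def test_skip_face_removes_interaction_face_look(self, design):
        spec = design.task("RJA")
        preset = two_state_preset(task="RJA", p_skip_face_interactive=1.0)
        frame, truth = generate_trial(preset, spec, seed=3)
        assert truth.skip_face_fired
        inter = (frame["t_ms"] >= 2000.0) & (frame["t_ms"] < 4000.0)
        face = spec.trial_aois[0]["face"]
        xs = frame.loc[inter, "x_px"]
        ys = frame.loc[inter, "y_px"]
        assert not any(face.contains(x, y) for x, y in zip(xs, ys))


class TestGenerateParticipant:
    def test_same_seed_bit_identical(self, presets, design):
        by_task = {t: presets[("ASD", t)] for t in design.block_order}
        rec1, _ = generate_participant(by_task, design, 123, group="ASD")
        rec2, _ = generate_participant(by_task, design, 123, group="ASD")
        pd.testing.assert_frame_equal(rec1.samples, rec2.samples)
        assert rec1.covariate == rec2.covariate

    def test_different_seeds_differ(self, presets, design):
        by_task = {t: presets[("ASD", t)] for t in design.block_order}
        rec1, _ = generate_participant(by_task, design, 123, group="ASD")
        rec2, _ = generate_participant(by_task, design, 124, group="ASD")
        assert not rec1.samples["x_px"].equals(rec2.samples["x_px"])

    def test_block_structure(self, presets, design):
        by_task = {t: presets[("TD", t)] for t in design.block_order}
        rec, truth = generate_participant(by_task, design, 5, group="TD")
        assert [t.task for t in truth.trials] == (
            ["RJA"] * 4 + ["IJA1"] * 4 + ["IJA2"] * 4
        )
        assert len(truth.trial_onsets) == 12
        # 120 Hz grid
        dt = np.diff(rec.samples["t_ms"].to_numpy())
        assert np.allclose(dt, DT)

    def test_covariate_drawn_from_group_distribution(self, presets, design):
        by_task = {t: presets[("ASD", t)] for t in design.block_order}
        covs = [
            generate_participant(by_task, design, s, group="ASD")[0].covariate
            for s in range(30)
        ]
        assert 60 < np.mean(covs) < 110  # ASD covariate: mean 85, sd 24.2


class TestZeroNoiseRecovery:
    def test_pipeline_recovers_truth_exactly(self, design):
        """With no jitter, no blinks and dwells well above the detection
        threshold, the event pipeline reproduces the generator's dwell-level
        transition counts and exclusion flags exactly."""
        preset = GeneratorPreset(
            group="ASD", task="RJA", states=("face", "target", "elsewhere"),
            transition_matrix=(
                (0.0, 0.7, 0.3), (0.7, 0.0, 0.3), (0.5, 0.5, 0.0),
            ),
            dwell_mean_ms=500.0, dwell_sd_ms=0.0, noise_sd_px=0.0,
            blink_rate_hz=0.0, p_skip_face_interactive=0.2,
            p_away_whole_ja=0.2,
        )
        by_task = {t: preset for t in design.block_order}
        rec, truth = generate_participant(by_task, design, 77, group="ASD")
        trials = apply_exclusions_all(
            segment_trials(rec, design, default_trial_onsets(design))
        )
        assert len(trials) == 12
        for trial, t_truth in zip(trials, truth.trials):
            assert trial.usable == t_truth.usable_expected
            if not trial.usable:
                continue
            from jagaze.events import extract_transitions

            counts = {}
            for tr in extract_transitions(trial.ja_fixations):
                counts[(tr.from_aoi, tr.to_aoi)] = counts.get(
                    (tr.from_aoi, tr.to_aoi), 0) + 1
            assert counts == t_truth.transition_counts

    def test_exclusion_rate_recovery(self, design):
        """Empirical exclusion fraction converges to ps + pa - ps*pa."""
        ps, pa = 0.3, 0.2
        preset = two_state_preset(
            task="RJA", p_skip_face_interactive=ps, p_away_whole_ja=pa
        )
        by_task = {t: preset for t in design.block_order}
        excluded = total = 0
        for seed in range(40):  # 480 trials
            rec, _ = generate_participant(by_task, design, seed, group="ASD")
            trials = apply_exclusions_all(
                segment_trials(rec, design, default_trial_onsets(design))
            )
            excluded += sum(not t.usable for t in trials)
            total += len(trials)
        want = ps + pa - ps * pa  # 0.44
        rate = excluded / total
        assert abs(rate - want) < 3 * math.sqrt(want * (1 - want) / total)


class TestCalibration:
    def test_presets_hit_their_targets_in_closed_form(self, presets):
        for (group, task), preset in presets.items():
            implied = expected_transition_counts(preset, JA_MS[task])
            for pair, want in CALIBRATION_TARGETS[(group, task)].items():
                assert implied[pair] == pytest.approx(want, abs=0.01)

    def test_rja_presets_identical_across_groups(self, presets):
        a = expected_transition_counts(presets[("ASD", "RJA")], JA_MS["RJA"])
        t = expected_transition_counts(presets[("TD", "RJA")], JA_MS["RJA"])
        for pair in a:
            assert a[pair] == pytest.approx(t[pair], abs=1e-6)

    def test_implied_ija1_score_asd(self, presets):
        c = expected_transition_counts(presets[("ASD", "IJA1")], JA_MS["IJA1"])
        score = (c[("target", "face")] - c[("non_target", "face")]) / (
            c[("target", "face")] + c[("non_target", "face")]
        )
        assert score == pytest.approx(0.36, abs=0.005)

    def test_attrition_split_matches_totals(self):
        for group, p in ATTRITION.items():
            ps, pa = attrition_probabilities(group)
            assert 1 - (1 - ps) * (1 - pa) == pytest.approx(p)
        preset = two_state_preset(
            p_skip_face_interactive=attrition_probabilities("ASD")[0],
            p_away_whole_ja=attrition_probabilities("ASD")[1],
        )
        assert expected_usable_trials(preset) == pytest.approx(10.8)

    def test_infeasible_calibration_raises(self):
        # ~40 transitions per 4 s phase cannot happen at a 320 ms dwell pace
        targets = {
            ("face", "target"): 20.0, ("target", "face"): 20.0,
        }
        with pytest.raises(CalibrationError):
            solve_chain(("face", "target"), targets, ja_ms=4000.0,
                        dwell_mean_ms=320.0, dwell_sd_ms=160.0)

    def test_stationary_distribution(self):
        P = np.array([[0.0, 1.0], [0.5, 0.5]])
        pi = stationary_distribution(P)
        assert pi @ P == pytest.approx(pi)
        assert pi.sum() == pytest.approx(1.0)
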