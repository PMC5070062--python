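import numpy as np
import pytest

from jagaze.errors import ConfigError
from jagaze.events import (
    AOI,
    AOISet,
    Fixation,
    Transition,
    assign_aoi,
    assign_aois,
    detect_fixations,
    extract_transitions,
    first_look,
)
from jagaze.io import ScreenGeometry

from conftest import make_samples

DT = 1000.0 / 120.0

# square screen/geometry keeps px->deg identical on both axes in these tests
GEO = ScreenGeometry(1000, 1000, 40.0, 40.0, 50.0)


def brute_force_idt(t, x, y, geometry, disp_max=1.0, min_dur=60.0, max_gap=75.0):
    """Exhaustive reference: greedy leftmost-maximal dispersion windows.

    From each start index the maximal admissible end index is found by
    directly recomputing the bounding-box dispersion of every candidate
    window; windows long enough become fixations and the scan resumes after
    them, else the start advances one sample.
    """
    out = []
    n = len(t)
    i = 0
    while i < n:
        j_max = i
        for j in range(i, n):
            if j > i and (t[j] - t[j - 1]) > max_gap:
                break
            w = geometry.extent_deg_x(np.ptp(x[i:j + 1]))
            h = geometry.extent_deg_y(np.ptp(y[i:j + 1]))
            if w + h > disp_max:
                break
            j_max = j
        if t[j_max] - t[i] >= min_dur:
            out.append(
                (t[i], t[j_max], float(np.mean(x[i:j_max + 1])),
                 float(np.mean(y[i:j_max + 1])))
            )
            i = j_max + 1
        else:
            i += 1
    return out


def _as_tuples(fixs):
    return [(f.onset_ms, f.offset_ms, f.cx_px, f.cy_px) for f in fixs]


class TestDetectFixations:
    def test_below_duration_threshold(self):
        s = make_samples([0.0, DT], [10, 10], [10, 10])
        assert detect_fixations(s, GEO) == []

    def test_ten_stationary_samples_make_one_fixation(self):
        t = np.arange(10) * DT  # span 75 ms >= 60 ms
        s = make_samples(t, np.full(10, 500.0), np.full(10, 400.0))
        fixs = detect_fixations(s, GEO)
        assert len(fixs) == 1
        f = fixs[0]
        assert f.duration_ms == pytest.approx(9 * DT)
        assert (f.cx_px, f.cy_px) == (500.0, 400.0)
        assert f.aoi == "none"

    def test_two_distant_clusters_two_fixations(self):
        t = np.arange(26) * DT
        x = np.concatenate([np.full(13, 100.0), np.full(13, 600.0)])  # ~10 deg apart
        y = np.full(26, 500.0)
        fixs = detect_fixations(make_samples(t, x, y), GEO)
        assert len(fixs) == 2
        assert fixs[0].cx_px == pytest.approx(100.0)
        assert fixs[1].cx_px == pytest.approx(600.0)
        # non-overlapping and ordered
        assert fixs[0].offset_ms < fixs[1].onset_ms

    def test_invalid_gap_bridged_and_broken(self):
        # 8 invalid samples -> 75 ms between valid neighbours: bridged
        n = 30
        t = np.arange(n) * DT
        valid = np.ones(n, dtype=int)
        valid[10:18] = 0
        s = make_samples(t, np.full(n, 300.0), np.full(n, 300.0), valid)
        assert len(detect_fixations(s, GEO)) == 1
        # 9 invalid samples -> 83 ms gap: window terminated, two fixations
        valid = np.ones(n, dtype=int)
        valid[10:19] = 0
        s = make_samples(t, np.full(n, 300.0), np.full(n, 300.0), valid)
        assert len(detect_fixations(s, GEO)) == 2

    def test_offscreen_samples_never_enter_detection(self):
        n = 20
        t = np.arange(n) * DT
        x = np.full(n, 300.0)
        x[5] = -50.0  # off screen although flagged valid
        s = make_samples(t, x, np.full(n, 300.0))
        fixs = detect_fixations(s, GEO)
        assert len(fixs) == 1
        assert fixs[0].cx_px == pytest.approx(300.0)

    def test_empty_input(self):
        s = make_samples([], [], [])
        assert detect_fixations(s, GEO) == []

    def test_matches_brute_force_on_random_streams(self):
        """Exhaustive maximal-window oracle on 500 random streams (<=200 samples)."""
        rng = np.random.default_rng(20240917)
        for _ in range(500):
            n = int(rng.integers(1, 200))
            t = np.cumsum(rng.choice([DT, 3 * DT, 12 * DT], size=n,
                                     p=[0.9, 0.07, 0.03]))
            # random walk with occasional jumps: mixes fixations and saccades
            jumps = rng.choice([0.0, 1.0], size=n, p=[0.93, 0.07])
            x = np.clip(np.cumsum(rng.normal(0, 2, n) + jumps * rng.normal(0, 200, n)) + 500, 0, 999)
            y = np.clip(np.cumsum(rng.normal(0, 2, n)) + 500, 0, 999)
            got = _as_tuples(detect_fixations(make_samples(t, x, y), GEO))
            want = brute_force_idt(t, x, y, GEO)
            assert got == pytest.approx(want)

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        n = 150
        t = np.arange(n) * DT
        x = 300 + np.repeat(rng.normal(0, 2, n // 10), 10).cumsum() % 50
        y = 300 + rng.normal(0, 2, n)
        base = detect_fixations(make_samples(t, x, y), GEO)
        shifted = detect_fixations(make_samples(t, x + 57, y + 31), GEO)
        assert len(base) == len(shifted)
        for a, b in zip(base, shifted):
            assert b.cx_px == pytest.approx(a.cx_px + 57)
            assert b.cy_px == pytest.approx(a.cy_px + 31)
            assert b.onset_ms == a.onset_ms and b.offset_ms == a.offset_ms

    def test_min_duration_respected_everywhere(self):
        rng = np.random.default_rng(99)
        n = 200
        t = np.arange(n) * DT
        x = rng.uniform(0, 999, n)
        y = rng.uniform(0, 999, n)
        for f in detect_fixations(make_samples(t, x, y), GEO):
            assert f.duration_ms >= 60.0


AOIS = AOISet(
    [
        AOI("face", (100, 100, 300, 300)),
        AOI("target", (400, 100, 600, 300)),
        AOI("non_target", (700, 100, 900, 300)),
    ]
)


def _fix(cx, cy, onset=0.0, aoi="none"):
    return Fixation(onset_ms=onset, offset_ms=onset + 100, cx_px=cx, cy_px=cy,
                    aoi=aoi)


class TestAssignAoi:
    def test_center_containment(self):
        assert assign_aoi(_fix(200, 200), AOIS).aoi == "face"
        assert assign_aoi(_fix(500, 200), AOIS).aoi == "target"

    def test_half_open_right_edge(self):
        assert assign_aoi(_fix(300, 200), AOIS).aoi == "none"  # x1 excluded
        assert assign_aoi(_fix(100, 100), AOIS).aoi == "face"  # x0 included

    def test_outside_all(self):
        assert assign_aoi(_fix(50, 50), AOIS).aoi == "none"

    def test_overlapping_aois_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            AOISet([AOI("face", (0, 0, 10, 10)), AOI("target", (5, 5, 15, 15))])


def transitions_oracle(labels):
    """Hand-trace reference for the none-transparent transition rule."""
    real = [l for l in labels if l != "none"]
    out = []
    for a, b in zip(real, real[1:]):
        if a != b:
            out.append((a, b))
    return out


class TestTransitions:
    def _seq(self, labels):
        return [
            Fixation(i * 100.0, i * 100.0 + 80, 0, 0, aoi=l)
            for i, l in enumerate(labels)
        ]

    def test_hand_trace(self):
        labels = ["face", "target", "face", "none", "target"]
        trs = extract_transitions(self._seq(labels))
        assert [(t.from_aoi, t.to_aoi) for t in trs] == [
            ("face", "target"), ("target", "face"), ("face", "target"),
        ]
        # destination onset time is carried
        assert trs[0].t_ms == 100.0

    @pytest.mark.parametrize("labels", [[], ["none", "none"], ["face"] * 3])
    def test_no_transitions(self, labels):
        assert extract_transitions(self._seq(labels)) == []

    def test_matches_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        opts = ["face", "target", "non_target", "none"]
        for _ in range(500):
            labels = list(rng.choice(opts, size=rng.integers(0, 30)))
            got = [(t.from_aoi, t.to_aoi)
                   for t in extract_transitions(self._seq(labels))]
            assert got == transitions_oracle(labels)

    def test_count_identity_runs_minus_one(self):
        """Total transitions = (# maximal same-AOI runs among labelled) - 1."""
        rng = np.random.default_rng(3)
        opts = ["face", "target", "non_target", "none"]
        for _ in range(200):
            labels = list(rng.choice(opts, size=rng.integers(1, 40)))
            real = [l for l in labels if l != "none"]
            runs = sum(1 for i, l in enumerate(real) if i == 0 or real[i - 1] != l)
            total = len(extract_transitions(self._seq(labels)))
            assert total == max(runs - 1, 0)

    def test_transition_type_invariants(self):
        with pytest.raises(ValueError):
            Transition("face", "face", 0.0)
        with pytest.raises(ValueError):
            Transition("none", "face", 0.0)


class TestFirstLook:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            (["face", "target", "non_target"], "target"),
            (["face", "face"], "neither"),
            (["non_target", "target"], "non_target"),
            ([], "neither"),
            (["none", "face", "non_target"], "non_target"),
        ],
    )
    def test_rule(self, labels, expected):
        fixs = [
            Fixation(i * 100.0, i * 100.0 + 80, 0, 0, aoi=l)
            for i, l in enumerate(labels)
        ]
        assert first_look(fixs) == expected
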