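"""Stride segmentation and head-nod forelimb lameness analysis."""

import numpy as np
import pytest

from equigait import (
    GaitParams,
    HeadNodResult,
    InsufficientStridesError,
    KeypointSeries,
    LamenessSpec,
    NOISELESS,
    NoiseSpec,
    StrideSegmentation,
    analyze_circle,
    classify_forelimb,
    detect_stance_onsets,
    head_nod_index,
    segment_strides,
    simulate_cohort,
    simulate_trial,
)
from equigait.synthetic_gait import HEAD_NOD_GAIN


def _series_from_x(x):
    x = np.asarray(x, float)
    return KeypointSeries(x, np.zeros_like(x), np.ones_like(x))


def windowed_argmax_oracle(x, w):
    """Brute-force onset detector: i is an onset iff it is the strict-from-
    the-left maximum of the window [i-w, i+w]."""
    onsets = []
    for i in range(len(x)):
        lo, hi = max(0, i - w), min(len(x), i + w + 1)
        window = x[lo:hi]
        if x[i] == window.max() and i - lo == int(np.argmax(window)):
            onsets.append(i)
    return np.array(onsets)


class TestStanceOnsets:
    def test_pure_sinusoid_closed_form(self):
        # f = 1.25 Hz at 30 fps for 60 s: maxima every 24 frames, 75 of them
        t = np.arange(1800) / 30.0
        x = np.sin(2 * np.pi * 1.25 * t)
        onsets = detect_stance_onsets(_series_from_x(x), 30.0, 75.0)
        assert len(onsets) == 75
        assert set(np.diff(onsets)) == {24}

    def test_noisy_sinusoid_matches_windowed_argmax_oracle(self):
        rng = np.random.default_rng(12)
        t = np.arange(1800) / 30.0
        x = 40.0 * np.sin(2 * np.pi * 1.25 * t) + rng.normal(0, 2.0, 1800)
        onsets = detect_stance_onsets(_series_from_x(x), 30.0, 75.0)
        oracle = windowed_argmax_oracle(x, 12)
        assert np.array_equal(onsets, oracle)

    def test_missing_frames_are_bridged(self):
        t = np.arange(1800) / 30.0
        x = np.sin(2 * np.pi * 1.25 * t)
        lk = np.ones(1800)
        lk[100:110] = 0.1  # drop a block of frames
        s = KeypointSeries(x, np.zeros_like(x), lk)
        from equigait import filter_by_likelihood

        onsets = detect_stance_onsets(filter_by_likelihood(s), 30.0, 75.0)
        assert 73 <= len(onsets) <= 76

    def test_too_few_strides_raises(self):
        x = np.sin(2 * np.pi * np.arange(30) / 60.0)
        with pytest.raises(InsufficientStridesError):
            detect_stance_onsets(_series_from_x(x), 30.0, 74.0)

    def test_synthetic_default_trial_stride_count(self, noisy_sound_trial):
        seg = segment_strides(noisy_sound_trial)
        assert abs(seg.n_strides - 74) <= 2

    def test_left_right_onsets_interleave(self, sound_trial_cl):
        seg = segment_strides(sound_trial_cl)
        merged = np.sort(np.concatenate([seg.onsets_left, seg.onsets_right]))
        sides = np.concatenate(
            [np.zeros_like(seg.onsets_left), np.ones_like(seg.onsets_right)]
        )[np.argsort(np.concatenate([seg.onsets_left, seg.onsets_right]))]
        assert (np.diff(merged) > 0).all()
        assert (np.abs(np.diff(sides)) == 1).all()  # strict alternation


class TestHeadNod:
    def test_constant_poll_is_sound(self, sound_trial_cl):
        seg = segment_strides(sound_trial_cl)
        n = sound_trial_cl.n_frames
        poll = KeypointSeries(np.zeros(n), np.full(n, 90.0), np.ones(n))
        res = head_nod_index(poll, seg)
        assert res.nod_index == pytest.approx(0.0, abs=1e-12)
        assert res.verdict == "sound"
        assert res.predicted_side == "none"

    def test_left_lame_nod_matches_generator_closed_form(self):
        delta, gait = 0.15, GaitParams()
        trial = simulate_trial(
            gait, LamenessSpec("forelimb_lame", "left", delta), "CL", NOISELESS
        )
        res = analyze_circle(trial)
        # injected once-per-stride component, averaged over a half-period
        # stance window, contributes (2/pi) * amplitude per side
        expected = 2 * (2 / np.pi) * delta * HEAD_NOD_GAIN * gait.head_amp
        assert res.nod_index == pytest.approx(expected, rel=0.02)
        assert res.verdict == "forelimb_lame"
        assert res.predicted_side == "left"

    def test_right_lame_detected_from_right_circle(self):
        trial = simulate_trial(
            lameness=LamenessSpec("forelimb_lame", "right", 0.05),
            circle="CR",
            noise=NoiseSpec(seed=2),
        )
        res = analyze_circle(trial)
        assert res.verdict == "forelimb_lame"
        assert res.predicted_side == "right"

    def test_mirror_symmetry_negates_nod(self, noisy_sound_trial):
        seg = segment_strides(noisy_sound_trial)
        from equigait import filter_by_likelihood

        poll = filter_by_likelihood(noisy_sound_trial.get("poll"))
        fwd = head_nod_index(poll, seg)
        mirrored = StrideSegmentation(
            onsets_left=seg.onsets_right,
            onsets_right=seg.onsets_left,
            stride_period=seg.stride_period,
            n_strides=seg.n_strides,
        )
        rev = head_nod_index(poll, mirrored)
        assert rev.nod_index == pytest.approx(-fwd.nod_index, abs=1e-12)

    def test_too_few_strides_rejected(self):
        seg = StrideSegmentation(
            np.array([0.0, 24.0]), np.array([12.0]), 24.0, 2
        )
        poll = KeypointSeries(np.zeros(100), np.zeros(100), np.ones(100))
        with pytest.raises(InsufficientStridesError):
            head_nod_index(poll, seg)

    def test_sound_cohort_no_false_positives(self):
        horses = simulate_cohort([LamenessSpec()] * 20, seed=314)
        for h in horses:
            for circle in ("CL", "CR"):
                assert analyze_circle(h.trials[circle]).verdict == "sound"

    def test_detection_rate_monotone_in_delta(self):
        rates = []
        for delta in (0.0, 0.02, 0.05, 0.15):
            spec = (
                LamenessSpec("forelimb_lame", "left", delta)
                if delta
                else LamenessSpec()
            )
            horses = simulate_cohort([spec] * 6, seed=99)
            hits = sum(
                analyze_circle(h.trials["CL"]).verdict == "forelimb_lame"
                for h in horses
            )
            rates.append(hits / 6)
        assert rates == sorted(rates)
        assert rates[0] == 0.0 and rates[-1] == 1.0


class TestClassifyForelimb:
    def _result(self, nod, verdict, side):
        return HeadNodResult(0.0, -nod, nod, verdict, side)

    def test_both_sound(self):
        s = self._result(0.01, "sound", "none")
        assert classify_forelimb(s, s).status == "sound"

    def test_agreeing_circles(self):
        r = self._result(3.0, "forelimb_lame", "left")
        out = classify_forelimb(r, r)
        assert (out.status, out.side) == ("forelimb_lame", "left")

    def test_single_circle_detection_wins(self):
        lame = self._result(2.0, "forelimb_lame", "right")
        sound = self._result(0.1, "sound", "none")
        assert classify_forelimb(sound, lame).side == "right"

    def test_disagreement_resolved_by_larger_nod(self):
        left = self._result(1.0, "forelimb_lame", "left")
        right = self._result(-4.0, "forelimb_lame", "right")
        assert classify_forelimb(left, right).side == "right"
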