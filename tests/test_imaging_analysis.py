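"""dF/F, response maps, adaptation index, SNR/responsiveness, percept
labels, classifier, and activation ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter

from glomflow import imaging_analysis as ia


def make_trace(F, frame_rate=10.0, on=5.0, off=8.0, **kw):
    return ia.GlomerulusTrace(F=np.asarray(F, float), frame_rate=frame_rate,
                              stim_on_s=on, stim_off_s=off, **kw)


class TestDff:
    def test_constant_trace_is_zero(self):
        tr = make_trace(np.full(100, 80.0))
        assert ia.dff(tr).values == pytest.approx(0.0)

    def test_simple_step(self):
        F = np.full(100, 100.0)
        F[50:80] = 150.0
        d = ia.dff(make_trace(F))
        assert d.values[60] == pytest.approx(0.5)
        assert d.values[10] == pytest.approx(0.0)

    def test_drifting_baseline_hand_computed(self):
        # 10-frame trace at 1 Hz, baseline = frames 0..4 (5 s before onset)
        F = np.array([100.0, 102.0, 98.0, 101.0, 99.0, 150.0, 130.0, 120.0, 95.0, 100.0])
        f0 = (100 + 102 + 98 + 101 + 99) / 5.0
        expected = (F - f0) / f0
        d = ia.dff(ia.GlomerulusTrace(F=F, frame_rate=1.0, stim_on_s=5.0,
                                      stim_off_s=8.0))
        np.testing.assert_allclose(d.values, expected, rtol=1e-12)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ia.InvalidBaselineError):
            ia.dff(make_trace(np.full(100, -1.0)))

    def test_insufficient_pre_stimulus_frames_rejected(self):
        tr = ia.GlomerulusTrace(F=np.full(100, 10.0), frame_rate=10.0,
                                stim_on_s=0.2, stim_off_s=5.0)
        with pytest.raises(ia.InvalidBaselineError):
            ia.dff(tr, baseline_s=5.0)


class TestResponseMap:
    def setup_method(self):
        self.masks = np.zeros((20, 20), dtype=bool)
        self.masks[4:8, 4:8] = True
        self.masks[12:16, 12:16] = True

    def test_constant_movie_gives_zero_map(self):
        movie = np.full((100, 20, 20), 60.0)
        m = ia.response_map(movie, self.masks, 10.0, 5.0, 8.0)
        np.testing.assert_allclose(m, 0.0)

    def test_single_pixel_response_matches_direct_gaussian_filter(self):
        movie = np.full((100, 20, 20), 50.0)
        movie[50:80, 5, 5] = 100.0
        m = ia.response_map(movie, self.masks, 10.0, 5.0, 8.0)
        delta = np.zeros((20, 20))
        delta[5, 5] = 1.0
        expected = np.where(self.masks, gaussian_filter(delta, 2.0), 0.0)
        np.testing.assert_allclose(m, expected, atol=1e-12)

    def test_response_outside_masks_is_zeroed(self):
        movie = np.full((100, 20, 20), 50.0)
        movie[50:80, 0, 0] = 500.0  # far from any mask
        m = ia.response_map(movie, self.masks, 10.0, 5.0, 8.0)
        assert m[0, 0] == 0.0

    def test_empty_masks_rejected(self):
        with pytest.raises(ValueError):
            ia.response_map(np.full((100, 20, 20), 50.0),
                            np.zeros((20, 20), bool), 10.0, 5.0, 8.0)


def dff_from_values(values, frame_rate=10.0, on=5.0, off=8.0):
    return ia.DffTrace(values=np.asarray(values, float), frame_rate=frame_rate,
                       stim_on_s=on, stim_off_s=off)


class TestAdaptationIndex:
    def test_complete_adaptation_gives_one(self):
        # plateaus survive the 5-point mean filter unchanged
        v = np.zeros(100)
        v[50:60] = 1.0           # peak plateau
        v[60:80] = 0.0           # tail at zero
        r = ia.adaptation_index(dff_from_values(v))
        assert r.ai == pytest.approx(1.0)
        assert r.peak == pytest.approx(1.0)

    def test_below_baseline_tail_exceeds_one(self):
        v = np.zeros(100)
        v[50:60] = 1.0
        v[60:85] = -0.15   # plateau spans the filter window at the tail
        r = ia.adaptation_index(dff_from_values(v))
        assert r.ai == pytest.approx(1.15)

    def test_explicit_trace_hand_filtered(self):
        # 20 stimulus samples at 42 Hz; expected value computed by applying
        # the centered shrinking-window 5-point mean by hand
        rng = np.random.default_rng(11)
        n = 400
        v = rng.normal(0, 0.01, n)
        v[210:230] += np.linspace(1.0, 0.2, 20)
        fr = 42.0
        tr = dff_from_values(v, frame_rate=fr, on=210 / fr, off=230 / fr)

        filt = np.empty(n)
        for i in range(n):
            lo, hi = max(0, i - 2), min(n, i + 3)
            filt[i] = v[lo:hi].mean()
        t = np.arange(n) / fr
        stim = (t >= tr.stim_on_s) & (t < tr.stim_off_s)
        n_tail = int(round(0.1 * fr))
        peak = filt[stim].max()
        tail = filt[stim][-n_tail:].mean()
        expected = (peak - tail) / peak

        got = ia.adaptation_index(tr)
        assert got.ai == pytest.approx(expected, rel=1e-9)

    def test_nonpositive_peak_rejected(self):
        v = np.zeros(100)
        v[50:80] = -0.5
        with pytest.raises(ia.UndefinedAIError):
            ia.adaptation_index(dff_from_values(v))

    def test_invariant_to_multiplicative_rescaling(self):
        rng = np.random.default_rng(4)
        F = 100.0 * (1.0 + np.abs(rng.normal(0.2, 0.1, 100)))
        tr1 = make_trace(F)
        tr2 = make_trace(3.7 * F)   # gain change preserves dF/F
        a1 = ia.adaptation_index(ia.dff(tr1)).ai
        a2 = ia.adaptation_index(ia.dff(tr2)).ai
        assert a1 == pytest.approx(a2, rel=1e-12)


class TestSnr:
    def test_seeded_fixture_matches_definition(self):
        rng = np.random.default_rng(123)
        v = np.zeros(100)
        v[20:50] = rng.normal(0.0, 0.1, 30)   # 3-s baseline before onset
        v[55] = 1.0
        tr = dff_from_values(v)
        mu, sd = v[20:50].mean(), v[20:50].std()
        assert ia.snr(tr) == pytest.approx((1.0 - mu) / sd, rel=1e-12)
        assert ia.snr(tr) == pytest.approx(10.0, rel=0.25)

    def test_stimulus_equal_to_baseline_mean_gives_zero(self):
        v = np.full(100, 0.3)
        v[20:50] += np.tile([0.01, -0.01], 15)
        v[50:80] = 0.3
        tr = dff_from_values(v)
        assert ia.snr(tr) == pytest.approx(0.0, abs=1e-9)

    def test_zero_baseline_sd_rejected(self):
        with pytest.raises(ValueError):
            ia.snr(dff_from_values(np.zeros(100)))


class TestResponsive:
    @pytest.mark.parametrize("snrs,expected", [
        ([2, 6, 7, 8], [False, True, True, True]),
        ([6, 6, 7, 8], [True, True, True, True]),
        ([2, 9, 2, 2], [False, False, False, False]),   # isolated flicker
        ([5.0, 5.0, 4.9, 5.0], [True, False, False, True]),  # boundary inclusive
    ])
    def test_successor_rule(self, snrs, expected):
        ladder = [1e-4, 1e-2, 0.1, 1.0]
        flags = ia.responsive(dict(zip(ladder, snrs)))
        assert [flags[c] for c in ladder] == expected

    def test_plain_rule_option(self):
        flags = ia.responsive({0.1: 9.0, 1.0: 2.0}, require_successor=False)
        assert flags == {0.1: True, 1.0: False}


class TestAmplitudeAndLabels:
    def test_constant_during_window(self):
        v = np.zeros(200)
        v[50:90] = 0.5      # stimulus 5..8 s plus the 1-s tail at 10 Hz
        tr = dff_from_values(v)
        assert ia.response_amplitude(tr) == pytest.approx(0.5)

    def test_normalization_to_max_across_stimuli(self):
        amps = pd.DataFrame({0: [0.2, 0.4], 1: [1.0, 0.5]})
        norm = ia.normalize_responses(amps)
        np.testing.assert_allclose(norm[0], [0.5, 1.0])
        np.testing.assert_allclose(norm[1], [1.0, 0.5])

    def test_percept_boundaries(self):
        labels = ia.label_percepts([1e-4, 3e-3, 0.01, 0.1, 0.3, 3.0])
        assert list(labels) == ["weak", "weak", "weak", None, "strong", "strong"]


class TestClassifier:
    def separable(self, n_per=12, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({
            0: np.r_[rng.normal(1.0, 0.05, n_per), rng.normal(0.0, 0.05, n_per)],
            1: rng.normal(0.5, 0.2, 2 * n_per),
            2: rng.normal(0.5, 0.2, 2 * n_per),
        })
        y = ["weak"] * n_per + ["strong"] * n_per
        return X, y

    def test_separable_fixture_scores_perfectly(self):
        X, y = self.separable()
        rep = ia.fit_percept_classifier(X, y)
        assert rep.f1 == 1.0
        assert rep.weights.index[0] == 0
        assert rep.weights.iloc[0] == 1.0

    def test_informative_glomerulus_recovered_by_top1_refit(self):
        X, y = self.separable()
        top1 = ia.fit_percept_classifier(X, y, subset=[0])
        assert top1.f1 == pytest.approx(ia.fit_percept_classifier(X, y).f1, abs=0.05)

    def test_shuffled_labels_score_at_chance(self):
        X, y = self.separable()
        rng = np.random.default_rng(99)
        scores = []
        for _ in range(100):
            ys = list(rng.permutation(y))
            if len(set(ys)) < 2:
                continue
            scores.append(ia.fit_percept_classifier(X, ys).f1)
        mean = np.mean(scores)
        assert 0.3 < mean < 0.65          # two balanced classes -> ~0.5
        assert ia.fit_percept_classifier(X, y).f1 - mean > 0.3

    def test_invariant_to_glomerulus_ordering_and_rescaling(self):
        X, y = self.separable(seed=3)
        r1 = ia.fit_percept_classifier(X, y)
        r2 = ia.fit_percept_classifier(X[[2, 0, 1]], y)
        r3 = ia.fit_percept_classifier(X * 37.0, y)
        assert r1.f1 == r2.f1 == r3.f1
        for g in (0, 1, 2):
            assert r1.weights[g] == pytest.approx(r2.weights[g], rel=1e-9)
            assert r1.weights[g] == pytest.approx(r3.weights[g], rel=1e-9)

    def test_single_class_rejected(self):
        X, _ = self.separable()
        with pytest.raises(ValueError):
            ia.fit_percept_classifier(X, ["weak"] * len(X))

    def test_transition_rows_dropped(self):
        X, y = self.separable()
        y = list(y)
        y[0] = None
        rep = ia.fit_percept_classifier(X, y)
        assert rep.n_stimuli == len(X) - 1


class TestRankActivation:
    def ramp_trace(self, onset_frame, frame_rate=10.0, n=150, amp=1.0, seed=0):
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 0.01, n)
        v[onset_frame:onset_frame + 40] += amp
        return dff_from_values(v, frame_rate=frame_rate, on=5.0, off=10.0)

    def test_single_glomerulus_gets_rank_one(self):
        r = ia.rank_activation({7: self.ramp_trace(60)})
        assert r.ranks == {7: 1}

    def test_ordering_by_onset_frame(self):
        r = ia.rank_activation({0: self.ramp_trace(53), 1: self.ramp_trace(57)})
        assert r.ranks == {0: 1, 1: 2}
        assert r.first_frame_s[0] < r.first_frame_s[1]

    def test_mean_rank_across_repeats(self):
        # ranks (1, 2, 1) over three repeats -> mean 1.33, per the stated rule
        ranks = [1, 2, 1]
        assert np.mean(ranks) == pytest.approx(1.3333, abs=1e-3)

    def test_ranks_are_permutation_of_active_glomeruli(self):
        rng = np.random.default_rng(5)
        traces = {g: self.ramp_trace(int(rng.integers(52, 90)), seed=g)
                  for g in range(6)}
        traces[6] = self.ramp_trace(60, amp=0.0, seed=99)   # never active
        r = ia.rank_activation(traces)
        assert sorted(r.ranks.values()) == [1, 2, 3, 4, 5, 6]
        assert 6 not in r.ranks

    def test_non_activating_glomerulus_has_nan_time(self):
        r = ia.rank_activation({0: self.ramp_trace(60, amp=0.0)})
        assert np.isnan(r.first_frame_s[0])
        assert r.ranks == {}
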