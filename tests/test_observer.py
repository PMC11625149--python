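"""Synthetic observer detection model and detection-time statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from lumitint.lens import fast_self_tinting, normal_lens
from lumitint.observer import (
    DetectionRecord,
    ObserverParams,
    compare_conditions,
    learning_effect,
    median_iqr,
    paired_test,
    simulate_detection,
    summarize,
)
from lumitint.protocol import StimulusSpec, TrialConfig, run_trial, weber_contrast


def _trial(lens, direction="decrease", fade_duration=0.333, seed=0, condition="cond"):
    if direction == "decrease":
        ls, le, grey = 140.0, 0.14, 14
    else:
        ls, le, grey = 0.14, 140.0, 230
    return TrialConfig(
        direction=direction,
        ramp_rate=3.0,
        lens=lens,
        stimulus=StimulusSpec(target_grey=grey, fade_duration=fade_duration),
        lum_start=ls,
        lum_end=le,
        seed=seed,
        condition=condition,
    )


def _rec(rt, trial=0, direction="increase", condition="c", participant="p1",
         correct=True):
    return DetectionRecord(
        participant_id=participant,
        condition=condition,
        direction=direction,
        trial_index=trial,
        corner="upper_left",
        reported_corner="upper_left" if correct else "none",
        detection_time=rt,
        correct=correct,
    )


class TestSimulateDetection:
    def test_pure_motor_latency_when_no_penalty(self, lin_table):
        # Instant full-contrast stimulus, no adaptation penalty, no jitter:
        # the detection time is exactly the motor latency.
        tl = run_trial(_trial(normal_lens(), direction="increase", fade_duration=0.0), lin_table)
        p = ObserverParams(penalty_gain=0.0, latency_sd=0.0)
        rec = simulate_detection(tl, p)
        assert rec.correct
        assert rec.detection_time == p.motor_latency
        assert rec.reported_corner == tl.corner

    def test_larger_adaptation_gap_delays_detection(self, lin_table):
        tl = run_trial(_trial(normal_lens()), lin_table)
        fast_track = ObserverParams(latency_sd=0.0, adaptation_tau_dark=0.25)
        slow_track = ObserverParams(latency_sd=0.0, adaptation_tau_dark=0.5)
        a = simulate_detection(tl, fast_track).detection_time
        b = simulate_detection(tl, slow_track).detection_time
        assert a < b
        # with very slow tracking the inflated threshold never decays in time
        stuck = ObserverParams(latency_sd=0.0, adaptation_tau_dark=2.0)
        assert not simulate_detection(tl, stuck).correct

    def test_quick_tinting_lens_helps_during_darkening(self, lin_table):
        p = ObserverParams(latency_sd=0.0)
        t_fast = simulate_detection(run_trial(_trial(fast_self_tinting()), lin_table), p)
        t_norm = simulate_detection(run_trial(_trial(normal_lens()), lin_table), p)
        assert t_fast.detection_time < t_norm.detection_time

    def test_matches_independent_closed_form(self, lin_table):
        # Re-derive the threshold-crossing time from scratch for a constant
        # (fade_duration = 0) stimulus and compare with the simulator.
        tl = run_trial(_trial(normal_lens(), fade_duration=0.0), lin_table)
        p = ObserverParams(latency_sd=0.0)

        fr = tl.frames
        t = fr["t"].to_numpy()
        lb = np.log10(fr["wall_lum"].to_numpy() * fr["transmission"].to_numpy())
        onset = tl.events["stim_onset"]
        a = lb[0]
        for i in range(1, len(t)):
            dt = t[i] - t[i - 1]
            diff = lb[i] - a
            tau = p.adaptation_tau_light if diff > 0 else p.adaptation_tau_dark
            a += math.copysign(min(abs(diff), dt / tau), diff)
            if t[i] >= onset:
                break
        lb_on = float(np.interp(onset, t, lb))
        gap = a - lb_on
        lum_on = 10.0**lb_on

        theta0 = p.contrast_threshold * math.sqrt(1 + p.lum_half / lum_on)
        contrast = abs(weber_contrast(fr["stim_lum"].dropna().iloc[-1], 0.14))
        inflation = p.penalty_gain * gap**p.penalty_exponent
        tau_decay = p.adaptation_tau_dark * gap * (
            1 + p.scotopic_slowdown * max(0.0, math.log10(p.lum_scotopic / lum_on))
        )
        assert gap > 0 and contrast > theta0
        t_star = tau_decay * math.log(inflation / (contrast / theta0 - 1))
        expected = max(t_star, 0.0) + p.motor_latency

        rec = simulate_detection(tl, p)
        assert rec.detection_time == pytest.approx(expected, abs=1e-6)

    def test_monte_carlo_recovers_motor_latency(self, lin_table):
        tl = run_trial(_trial(normal_lens(), direction="increase", fade_duration=0.0), lin_table)
        p = ObserverParams(penalty_gain=0.0)
        rng = np.random.default_rng(123)
        times = np.array(
            [simulate_detection(tl, p, rng).detection_time for _ in range(1000)]
        )
        se = p.latency_sd / math.sqrt(len(times))
        assert abs(times.mean() - p.motor_latency) < 3 * se
        assert times.std(ddof=1) == pytest.approx(p.latency_sd, rel=0.1)

    def test_undetectable_stimulus_recorded_as_miss(self, lin_table):
        tl = run_trial(_trial(normal_lens()), lin_table)
        p = ObserverParams(contrast_threshold=5.0, latency_sd=0.0)
        rec = simulate_detection(tl, p)
        assert not rec.correct
        assert rec.reported_corner == "none"
        assert math.isnan(rec.detection_time)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ObserverParams(contrast_threshold=0.0)
        with pytest.raises(ValueError):
            ObserverParams(latency_sd=-0.1)


class TestSummaries:
    def test_median_iqr_examples(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0)
        assert median_iqr([1.7]) == (1.7, 0.0)
        med, iqr = median_iqr([1.0, 1.1, 1.2, 1.5, 2.0, 2.2])
        assert med == pytest.approx(1.35)
        assert iqr == pytest.approx(0.75)

    def test_median_iqr_ignores_nan_and_rejects_empty(self):
        assert median_iqr([1.0, float("nan"), 3.0])[0] == 2.0
        with pytest.raises(ValueError):
            median_iqr([])

    def test_summarize_groups_and_excludes_misses(self):
        recs = [
            _rec(1.0, condition="a"),
            _rec(2.0, condition="a"),
            _rec(3.0, condition="a"),
            _rec(5.0, condition="b"),
            _rec(float("nan"), condition="b", correct=False),
        ]
        out = summarize(recs).set_index("condition")
        assert out.loc["a", "median_rt_s"] == 2.0
        assert out.loc["a", "n"] == 3
        assert out.loc["b", "median_rt_s"] == 5.0
        assert out.loc["b", "n"] == 1


def _brute_force_wilcoxon(d, alternative):
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    ge = le = total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        t = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        ge += t >= t_obs - 1e-12
        le += t <= t_obs + 1e-12
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2 * min(ge, le) / total)


class TestPairedTest:
    def test_all_positive_small_shift_is_one_over_2n(self):
        x = np.arange(8) + 0.5
        y = np.arange(8, dtype=float)
        assert paired_test(x, y, alternative="greater") == pytest.approx(1 / 256)

    def test_identical_samples_give_p_one(self):
        assert paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed, alternative):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 11)
        x = rng.normal(0.1, 1.0, n)
        y = rng.normal(0.0, 1.0, n)
        expected = _brute_force_wilcoxon(x - y, alternative)
        assert paired_test(x, y, alternative=alternative) == pytest.approx(expected)

    def test_exact_untied_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.3, 1.0, 12)
        y = rng.normal(0.0, 1.0, 12)
        ours = paired_test(x, y)
        ref = stats.wilcoxon(x - y, method="exact").pvalue
        assert ours == pytest.approx(ref)

    def test_ttest_method_differs_but_agrees_in_direction(self):
        x = [1.0, 1.2, 1.1, 1.4, 1.3, 1.25]
        y = [1.5, 1.6, 1.55, 1.8, 1.7, 1.65]
        pw = paired_test(x, y, alternative="less")
        pt = paired_test(x, y, method="ttest", alternative="less")
        assert pw < 0.05 and pt < 0.05

    def test_unequal_lengths_and_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            paired_test([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            paired_test([1.0, 2.0], [1.0, 2.0], method="bogus")


class TestCompareConditions:
    @staticmethod
    def _records(participants=("p1", "p2", "p3"), conditions=("a", "b")):
        rng = np.random.default_rng(0)
        recs = []
        shift = {c: 0.4 * i for i, c in enumerate(conditions)}
        for p in participants:
            for c in conditions:
                for i in range(5):
                    recs.append(
                        _rec(1.0 + shift[c] + rng.normal(0, 0.05), trial=i,
                             condition=c, participant=p)
                    )
        return recs

    def test_pairwise_table_shape_and_direction(self):
        out = compare_conditions(self._records())
        assert len(out) == 1
        row = out.iloc[0]
        assert {row["condition_a"], row["condition_b"]} == {"a", "b"}
        assert 0.0 < row["p_value"] <= 1.0

    def test_holm_adjusted_never_below_raw(self):
        recs = self._records(conditions=("a", "b", "c"))
        raw = compare_conditions(recs)["p_value"].to_numpy()
        adj = compare_conditions(recs, correction="holm")["p_value"].to_numpy()
        assert np.all(adj >= raw - 1e-12)

    def test_unpaired_participants_rejected(self):
        recs = self._records()
        recs = [r for r in recs if not (r.participant_id == "p3" and r.condition == "b")]
        with pytest.raises(ValueError):
            compare_conditions(recs)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions(self._records(participants=("p1", "p2")))


class TestLearningEffect:
    def test_identical_blocks_show_no_effect(self):
        vals = [1.0, 1.2, 1.1, 1.3, 1.15] * 4
        recs = [_rec(v, trial=i) for i, v in enumerate(vals + vals)]
        eff = learning_effect(recs, block_size=20)
        assert eff.mean_difference == pytest.approx(0.0)
        assert eff.p_value == pytest.approx(0.5)

    def test_recovers_seeded_improvement(self):
        rng = np.random.default_rng(7)
        first = rng.normal(1.23, 0.08, 20)
        last = rng.normal(1.16, 0.06, 20)
        recs = [_rec(v, trial=i) for i, v in enumerate(np.concatenate([first, last]))]
        eff = learning_effect(recs, block_size=20)
        se = math.sqrt(0.08**2 / 20 + 0.06**2 / 20)
        assert abs(eff.mean_difference - 0.07) < 3 * se
        assert eff.p_value < 0.05

    def test_insufficient_trials_rejected(self):
        recs = [_rec(1.0, trial=i) for i in range(30)]
        with pytest.raises(ValueError):
            learning_effect(recs, block_size=20)

    def test_only_increase_trials_counted(self):
        recs = [_rec(1.0, trial=i) for i in range(40)]
        recs += [_rec(9.0, trial=i, direction="decrease") for i in range(40)]
        eff = learning_effect(recs, block_size=20)
        assert eff.mean_difference == pytest.approx(0.0)
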