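"""Cleaning rules, LISAS, paired tests, Holm, power, and the jnd regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import timbrecapture as tc
from timbrecapture.analysis import clean, exclude_participants


def records_from_rts(rts, participant=1, condition="b+2", correct=True):
    n = len(rts)
    return pd.DataFrame(
        {
            "participant": participant,
            "condition": condition,
            "trial": np.arange(1, n + 1),
            "response": ["long"] * n,
            "correct": correct,
            "rt_ms": np.asarray(rts, dtype=float),
            "jnd_brightness": 2.0,
            "jnd_roughness": 0.0,
            "singleton_pos": "after",
        }
    )


class TestClean:
    def test_two_sd_rule_matches_direct_computation(self):
        # one inflated cell; expected survivors computed by the rule itself
        rts = np.array([500, 510, 520, 530, 540, 550, 560, 570, 580, 5000.0])
        mu, sd = rts.mean(), rts.std(ddof=1)
        expected = rts[np.abs(rts - mu) <= 2 * sd]
        kept, report = clean(records_from_rts(rts))
        assert sorted(kept["rt_ms"]) == sorted(expected)
        assert report.removed_by_rule["sd_rule"] == len(rts) - len(expected)
        assert 5000.0 not in kept["rt_ms"].to_numpy()

    def test_identical_rts_survive_sd_rule(self):
        kept, report = clean(records_from_rts([700.0] * 10))
        assert len(kept) == 10
        assert report.removed_by_rule["sd_rule"] == 0

    def test_floor_rule_fires_regardless_of_sd(self):
        kept, report = clean(records_from_rts([90.0] * 10))
        assert len(kept) == 0
        assert report.removed_by_rule["floor_rule"] == 10

    def test_no_answer_trials_removed(self):
        df = records_from_rts([500, 510, 520, 530])
        df.loc[2, ["response", "rt_ms"]] = ["none", np.nan]
        kept, report = clean(df)
        assert report.removed_by_rule["no_answer"] == 1
        assert len(kept) == 3

    def test_tiny_cell_passes_through_with_warning(self):
        with pytest.warns(UserWarning, match="untrimmed"):
            kept, _ = clean(records_from_rts([500.0, 5000.0]))
        assert len(kept) == 2

    def test_kept_fractions(self):
        df = pd.concat(
            [
                records_from_rts([500, 510, 520, 530, 540], correct=True),
                records_from_rts(
                    [600, 610, 620, 630, 640], condition="none", correct=False
                ),
            ],
            ignore_index=True,
        )
        _, report = clean(df)
        assert report.kept_fraction_all == 1.0
        assert report.kept_fraction_correct == 0.5

    def test_trimming_is_per_participant_per_condition(self):
        # the same RT is typical in one cell and an outlier in another
        fast_cell = records_from_rts([300, 310, 320, 330, 340], participant=1)
        slow_cell = records_from_rts(
            [300.0] + list(np.arange(2000.0, 2100.0, 10.0)), participant=2
        )
        mu, sd = slow_cell["rt_ms"].mean(), slow_cell["rt_ms"].std(ddof=1)
        assert abs(300.0 - mu) > 2 * sd  # outlier by direct computation
        kept, _ = clean(pd.concat([fast_cell, slow_cell], ignore_index=True))
        assert (kept[kept["participant"] == 1]["rt_ms"] == 300).sum() == 1
        assert (kept[kept["participant"] == 2]["rt_ms"] == 300).sum() == 0


class TestExcludeParticipants:
    def _records(self, error_rates):
        frames = []
        for pid, er in enumerate(error_rates, start=1):
            n_err = round(100 * er)
            frames.append(
                pd.DataFrame(
                    {
                        "participant": pid,
                        "correct": [False] * n_err + [True] * (100 - n_err),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_half_wrong_is_excluded(self):
        kept, dropped = exclude_participants(self._records([0.5, 0.1]))
        assert dropped == [(1, 0.5)]
        assert set(kept["participant"]) == {2}

    def test_boundary_forty_percent_is_excluded(self):
        _, dropped = exclude_participants(self._records([0.40]))
        assert dropped == [(1, 0.40)]

    def test_perfect_cohort_untouched(self):
        kept, dropped = exclude_participants(self._records([0.0, 0.0]))
        assert dropped == [] and len(kept) == 200


class TestLisas:
    def test_no_errors_reduces_to_mean_rt(self):
        assert tc.lisas([900.0, 1000.0, 1100.0], [0, 0, 0]) == pytest.approx(1000.0)

    def test_hand_worked_cell(self):
        # 16 trials, 4 errors; correct RTs constructed with mean 1000, SD 100
        rt = np.array([900.0, 1000.0, 1100.0])
        rt = (rt - rt.mean()) / rt.std(ddof=1) * 100 + 1000
        errors = [1] * 4 + [0] * 12
        expected = 1000 + (100 / np.std(errors, ddof=1)) * 0.25
        assert tc.lisas(rt, errors) == pytest.approx(expected)
        assert expected == pytest.approx(1055.9017, abs=0.001)

    def test_scaling_rts_scales_the_score(self):
        rt = [800.0, 900.0, 1000.0]
        errors = [1, 0, 0, 0, 1, 0]
        assert tc.lisas([2 * r for r in rt], errors) == pytest.approx(
            2 * tc.lisas(rt, errors)
        )

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            tc.lisas([], [1, 0])


class TestPairedT:
    def test_hand_worked_example(self):
        res = tc.paired_t([110, 220, 330, 440], [100, 200, 300, 400])
        assert res.t == pytest.approx(3.872983, abs=1e-5)
        assert res.cohen_d == pytest.approx(1.936492, abs=1e-5)
        assert res.df == 3

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        a = rng.normal(1000, 100, 15)
        b = a - rng.normal(50, 30, 15)
        res = tc.paired_t(a, b)
        ref = pg.ttest(a, b, paired=True)
        assert res.t == pytest.approx(float(ref["T"].iloc[0]), rel=1e-9)
        assert res.p_raw == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-9)

    def test_symmetric_differences_are_null(self):
        res = tc.paired_t([100, 200, 300, 400], [200, 100, 400, 300])
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)

    def test_one_sided_halves_the_symmetric_p(self):
        a = [110.0, 125.0, 132.0, 118.0, 140.0]
        b = [100.0, 120.0, 130.0, 115.0, 128.0]
        two = tc.paired_t(a, b, tail="two-sided").p_raw
        one = tc.paired_t(a, b, tail="greater").p_raw
        assert one == pytest.approx(two / 2)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            tc.paired_t([1.0], [2.0])


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(tc.holm_correct([0.03]), [0.03])

    def test_hand_worked_step_down(self):
        np.testing.assert_allclose(
            tc.holm_correct([0.005, 0.01, 0.03, 0.04]),
            [0.02, 0.03, 0.06, 0.06],
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(tc.holm_correct([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8),
        st.randoms(use_true_random=False),
    )
    def test_adjusted_never_below_raw_and_permutation_invariant(self, ps, rnd):
        adj = tc.holm_correct(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        adj_perm = tc.holm_correct([ps[i] for i in perm])
        np.testing.assert_allclose([adj[i] for i in perm], adj_perm)


class TestPowerSampleSize:
    def test_planned_design_needs_twelve(self):
        assert tc.power_sample_size(0.8, 0.05, 0.8, "one-sided") == 12

    def test_huge_effect_needs_four(self):
        assert tc.power_sample_size(2.1, 0.05, 0.8, "one-sided") == 4

    def test_monotone_in_target_power(self):
        ns = [
            tc.power_sample_size(0.8, 0.05, p, "one-sided")
            for p in (0.5, 0.8, 0.9, 0.99)
        ]
        assert ns == sorted(ns)

    @pytest.mark.parametrize("d", [0.5, 0.8, 1.0, 2.1])
    def test_agrees_with_statsmodels_power(self, d):
        from statsmodels.stats.power import TTestPower

        n = tc.power_sample_size(d, 0.05, 0.8, "one-sided")
        solver = TTestPower()
        assert solver.power(d, n, 0.05, alternative="larger") >= 0.8
        assert solver.power(d, n - 1, 0.05, alternative="larger") < 0.8

    def test_invalid_effect_size_rejected(self):
        with pytest.raises(ValueError):
            tc.power_sample_size(0.0)


class TestJndRegression:
    def test_exact_line_recovered(self):
        res = tc.jnd_regression([(k, 14.0 * k) for k in (1, 2, 5, 10)])
        assert res.slope == pytest.approx(14.0)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope_se == pytest.approx(0.0, abs=1e-9)

    def test_constant_ordinate_flagged_degenerate(self):
        res = tc.jnd_regression([(1, 5.0), (2, 5.0), (5, 5.0)])
        assert res.degenerate and res.slope == 0.0 and res.pearson_r == 0.0

    def test_noisy_points_match_direct_ols(self):
        # frozen expectation from the normal equations: slope = Sxy/Sxx
        pts = [(1, 10.0), (2, 32.0), (5, 68.0), (10, 143.0)]
        res = tc.jnd_regression(pts)
        assert res.slope == pytest.approx(705.5 / 49, abs=1e-9)   # 14.3980
        assert res.pearson_r == pytest.approx(0.998184, abs=1e-5)

    def test_under_three_points_rejected(self):
        with pytest.raises(ValueError):
            tc.jnd_regression([(1, 10.0), (2, 20.0)])


class TestPositionAndSurpriseEffects:
    def _cohort(self, position_effect_ms):
        plan = tc.generate_plan(tc.load_experiment("exp1"), seed=6)
        p = tc.ObserverParams(
            sigma_rt_ms=120.0, lapse_rate=0.0, base_error_rate=0.05,
            error_capture_gain=0.0, position_effect_ms=position_effect_ms,
        )
        return tc.simulate_cohort(
            plan, 15, tc.PopulationSpec(mean=p, mu_rt_sd_ms=80.0), seed=21
        )

    def test_null_position_effect_not_detected(self):
        res = tc.position_effect(self._cohort(0.0))
        assert res.p_raw > 0.01

    def test_injected_after_cost_detected(self):
        res = tc.position_effect(self._cohort(50.0))
        assert res.t > 0 and res.p_raw < 0.01

    def test_history_free_observer_shows_no_surprise_effect(self):
        res = tc.surprise_effect(self._cohort(0.0))
        assert abs(res.cohen_d) < 0.8 and res.p_raw > 0.01

    def test_missing_position_labels_rejected(self):
        df = records_from_rts([500, 510, 520, 530])
        df["singleton_pos"] = np.nan
        with pytest.raises(ValueError):
            tc.position_effect(df)
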