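"""Fatigue-index regression, pooling, scoring and cohort statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ergofatigue import (
    ChannelLabel,
    FatigueIndex,
    InsufficientDataError,
    MdfSeries,
    ValidationError,
    dominant_leg,
    fit_fatigue_index,
    generate_cohort_slopes,
    mann_whitney,
    one_way_anova,
    pool_participant,
    proportional_score,
    shapiro_wilk,
)
from ergofatigue.fatigue import score_groups

_LABEL = ChannelLabel("GAS", "L")

# printed study inputs: 1000 m times (s) and dominant-leg torques (Nm)
TIMES = {"P1": 177.9, "P2": 194.3, "P3": 194.8, "P4": 195.5,
         "P5": 195.9, "P6": 197.4, "P7": 205.6, "P8": 207.7}
TORQUES = {"P1": 268.2, "P2": 303.7, "P3": 296.3, "P4": 290.9,
           "P5": 291.6, "P6": 242.3, "P7": 262.2, "P8": 190.3}


def _series(times, values):
    return MdfSeries(mid_times=np.asarray(times, float),
                     mdf=np.asarray(values, float), channel=_LABEL)


class TestFitFatigueIndex:
    def test_exact_line_recovered(self):
        t = np.arange(1.0, 31.0)
        idx = fit_fatigue_index(_series(t, 100.0 - 0.05 * t), "seconds")
        assert idx.slope == pytest.approx(-0.05, abs=1e-12)
        assert idx.intercept == pytest.approx(100.0, abs=1e-9)
        assert idx.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_has_zero_slope(self):
        idx = fit_fatigue_index(_series([1.0, 2.0, 3.0], [80.0, 80.0, 80.0]))
        assert idx.slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_fatigue_index(_series([1.0, 2.0], [80.0, 79.0]))

    def test_time_base_equivariance(self):
        """At a steady 2 s stroke, slope per cycle = 2 x slope per second."""
        t = 1.0 + 2.0 * np.arange(40)
        rng = np.random.default_rng(0)
        y = 100.0 - 0.05 * t + rng.normal(0, 2.0, 40)
        per_second = fit_fatigue_index(_series(t, y), "seconds").slope
        per_cycle = fit_fatigue_index(_series(t, y), "cycle_index").slope
        assert per_cycle == pytest.approx(2.0 * per_second, rel=1e-9)


class TestPooling:
    def _index(self, slope, pid="P1"):
        return FatigueIndex(slope=slope, intercept=100.0, r_squared=0.5,
                            n_cycles=30, time_base="seconds",
                            channel=_LABEL, participant_id=pid)

    def test_median_of_symmetric_slopes(self):
        s = pool_participant([self._index(v) for v in (-1.0, 0.0, 1.0)])
        assert s.median_slope == 0.0
        assert s.n_indices == 3

    def test_single_index(self):
        s = pool_participant([self._index(-0.04)])
        assert s.median_slope == -0.04
        assert s.iqr_slope == 0.0

    def test_iqr_uses_interpolated_quartiles(self):
        slopes = [-0.08, -0.06, -0.02, 0.0]
        s = pool_participant([self._index(v) for v in slopes])
        q1, q3 = np.quantile(slopes, [0.25, 0.75])
        assert s.iqr_slope == pytest.approx(q3 - q1)


class TestProportionalScore:
    def test_printed_time_scores(self):
        table = proportional_score(TIMES, better="lower")
        assert table.score_of("P1") == 100
        assert table.score_of("P2") == 45
        assert table.score_of("P7") == 7
        assert table.score_of("P8") == 0

    def test_printed_torque_scores(self):
        table = proportional_score(TORQUES, better="higher")
        assert table.score_of("P2") == 100
        assert table.score_of("P4") == 89
        assert table.score_of("P6") == 46
        assert table.score_of("P8") == 0
        assert table.score_of("P1") == 69

    def test_two_values(self):
        table = proportional_score({"A": 10.0, "B": 20.0}, better="lower")
        assert table.score_of("A") == 100
        assert table.score_of("B") == 0

    def test_degenerate_scale_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            proportional_score({"A": 5.0, "B": 5.0})

    @settings(max_examples=50, derandomize=True)
    @given(
        shift=st.floats(-1e3, 1e3),
        scale=st.floats(1e-3, 1e3),
    )
    def test_affine_invariance(self, shift, scale):
        values = {"A": 177.9, "B": 194.3, "C": 205.6, "D": 207.7}
        base = proportional_score(values, "lower")
        moved = proportional_score(
            {k: scale * v + shift for k, v in values.items()}, "lower"
        )
        assert base.scores == moved.scores


class TestDominantLeg:
    def test_clear_dominance(self):
        assert dominant_leg([100, 100, 100], [90, 90, 90]) == ("L", 100.0)

    def test_tie_is_indeterminate(self):
        side, _ = dominant_leg([95, 100, 105], [100, 100, 100])
        assert side == "indeterminate"

    def test_agrees_with_direct_mean_comparison(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            left = rng.uniform(150, 350, 3)
            right = rng.uniform(150, 350, 3)
            side, mean = dominant_leg(left, right)
            expected = "L" if left.mean() > right.mean() else "R"
            assert side == expected
            assert mean == pytest.approx(max(left.mean(), right.mean()))

    def test_nonpositive_torque_rejected(self):
        with pytest.raises(ValidationError):
            dominant_leg([100, -5, 100], [90, 90, 90])


class TestGroupTests:
    def test_anova_identical_groups_f_zero(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.f_value == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.99

    def test_anova_matches_hand_computed_table(self):
        # groups (1,2,3), (2,3,4), (6,7,8): grand mean 4, SS_model 42, SS_error 6
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [6, 7, 8]])
        assert res.sum_of_squares_model == pytest.approx(42.0)
        assert res.sum_of_squares_error == pytest.approx(6.0)
        assert res.sum_of_squares_total == pytest.approx(48.0)
        assert res.mean_square_model == pytest.approx(21.0)
        assert res.mean_square_error == pytest.approx(1.0)
        assert res.f_value == pytest.approx(21.0)
        assert (res.df_model, res.df_error) == (2, 6)

    def test_anova_agrees_with_independent_implementation(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(0, 1, 6), rng.normal(0.5, 1, 5), rng.normal(1, 1, 7)]
        ours = one_way_anova(groups)
        ref = stats.f_oneway(*groups)
        assert ours.f_value == pytest.approx(ref.statistic, rel=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_sums_of_squares_additive(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(size=5) for _ in range(4)]
        res = one_way_anova(groups)
        assert res.sum_of_squares_total == pytest.approx(
            res.sum_of_squares_model + res.sum_of_squares_error, rel=1e-9
        )

    def test_mann_whitney_identical_samples_not_significant(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = mann_whitney(x, list(x))
        assert res.p_value > 0.05
        assert not res.significant

    def test_shapiro_wilk_flags_uniform_tail(self):
        rng = np.random.default_rng(10)
        normal = shapiro_wilk(rng.normal(size=50))
        skewed = shapiro_wilk(rng.exponential(size=50) ** 2)
        assert not normal.significant
        assert skewed.significant


class TestScoreGroups:
    def test_splits_by_rank(self):
        table = proportional_score(TIMES, better="lower")
        groups = score_groups(table, n_groups=2)
        assert sorted(len(v) for v in groups.values()) == [4, 4]
        top = groups[0]
        assert "P1" in top and "P8" not in top


class TestNullCohortHomogeneity:
    def test_both_anovas_usually_non_significant_under_null(self):
        """Homogeneous cohorts: fatigue unrelated to time or torque scores,
        so both cohort ANOVAs should be non-significant in >= 90% of runs."""
        from ergofatigue import SyntheticCohortSpec, generate_cohort

        both_ns = 0
        n_runs = 100
        for i in range(n_runs):
            df = generate_cohort(SyntheticCohortSpec(n_participants=8, seed=10_000 + i))
            slopes = generate_cohort_slopes(8, seed=20_000 + i)
            medians = {pid: float(np.median(v)) for pid, v in slopes.items()}
            results = []
            for key, better in (("time_1000m_s", "lower"),):
                values = dict(zip(df["participant_id"], df[key]))
                table = proportional_score(values, better)
                grouping = score_groups(table, 2)
                res = one_way_anova(
                    [[medians[p] for p in pids] for pids in grouping.values()]
                )
                results.append(res.significant)
            torque_means = {
                row["participant_id"]: dominant_leg(
                    [row[f"torque_L_{a}_nm"] for a in (30, 60, 90)],
                    [row[f"torque_R_{a}_nm"] for a in (30, 60, 90)],
                )[1]
                for _, row in df.iterrows()
            }
            table = proportional_score(torque_means, "higher")
            grouping = score_groups(table, 2)
            results.append(
                one_way_anova(
                    [[medians[p] for p in pids] for pids in grouping.values()]
                ).significant
            )
            if not any(results):
                both_ns += 1
        assert both_ns >= 0.9 * n_runs
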