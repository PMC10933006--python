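"""Fatigue indices and cohort statistics.

The fatigue index of one muscle x trial is the ordinary-least-squares slope
of per-cycle MDF against time: negative slope = spectral compression =
accumulating fatigue. Per participant, indices are pooled over all muscles
and trials and reported as median +/- interquartile range (the fatigue data
are typically non-normal). Cohort analyses: proportional 0-100 scoring of
performance, dominant-leg determination from isokinetic torques,
Shapiro-Wilk normality, Mann-Whitney dominant vs non-dominant comparison,
and one-way ANOVA of fatigue across score groups.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .types import (
    FatigueIndex,
    GroupTestResult,
    MdfSeries,
    ParticipantSummary,
    ScoreRow,
    ScoreTable,
)


def fit_fatigue_index(series: MdfSeries, time_base: str = "seconds") -> FatigueIndex:
    """OLS regression of MDF on time; the slope is the fatigue index.

    ``time_base="seconds"`` regresses on cycle mid-times (slope in Hz/s);
    ``"cycle_index"`` regresses on 0,1,2,... (slope in Hz/cycle). At a
    steady 2 s stroke, slope_per_cycle = 2 x slope_per_second.
    """
    if time_base not in ("seconds", "cycle_index"):
        raise ValidationError(f"unknown time_base {time_base!r}")
    n = len(series)
    if n < 3:
        raise InsufficientDataError(f"regression needs >= 3 cycles, got {n}")
    x = series.mid_times if time_base == "seconds" else np.arange(n, dtype=float)
    fit = stats.linregress(x, series.mdf)
    # constant MDF: r is 0/0; define R^2 = 0 (no variance to explain)
    r_squared = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue**2)
    return FatigueIndex(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r_squared,
        n_cycles=n,
        time_base=time_base,
        channel=series.channel,
        trial_id=series.trial_id,
        participant_id=series.participant_id,
    )


def pool_participant(indices: list) -> ParticipantSummary:
    """Median and IQR over all (muscle x trial) slopes of one participant.

    IQR = Q3 - Q1 with linear-interpolation quantiles. The arithmetic mean
    is carried alongside so either aggregate is available downstream.
    """
    if not indices:
        raise InsufficientDataError("cannot pool an empty index collection")
    slopes = np.array([ix.slope for ix in indices])
    q1, q3 = np.quantile(slopes, [0.25, 0.75])
    return ParticipantSummary(
        participant_id=indices[0].participant_id,
        median_slope=float(np.median(slopes)),
        iqr_slope=float(q3 - q1),
        mean_slope=float(slopes.mean()),
        n_indices=slopes.size,
    )


def proportional_score(values: dict, better: str = "lower") -> ScoreTable:
    """Linear 0-100 scoring: best performer 100 points, worst 0.

    ``values`` maps participant id to the raw value (1000 m time in s with
    ``better="lower"``, torque in Nm with ``better="higher"``). Intermediate
    performances score proportionally, rounded to the nearest integer (half
    away from zero).
    """
    if better not in ("lower", "higher"):
        raise ValidationError(f"better must be 'lower' or 'higher', got {better!r}")
    if len(values) < 2:
        raise ValidationError("scoring needs at least 2 participants")
    raw = np.array(list(values.values()), dtype=float)
    best = raw.min() if better == "lower" else raw.max()
    worst = raw.max() if better == "lower" else raw.min()
    if best == worst:
        raise ValidationError("degenerate scale: all raw values are equal")
    rows = []
    for pid, v in values.items():
        frac = (worst - v) / (worst - best)
        score = int(np.floor(100.0 * frac + 0.5))  # round half away from zero; frac >= 0
        rows.append(ScoreRow(participant_id=pid, value=float(v), score=score))
    return ScoreTable(rows=rows)


def dominant_leg(left_torques, right_torques) -> tuple:
    """Determine the dominant leg from knee-extension torques at 30/60/90 deg.

    Per-leg arithmetic means are compared; the larger mean wins. Returns
    (side, mean_torque_nm) with side ``"indeterminate"`` on an exact tie.
    """
    left = np.asarray(left_torques, dtype=float)
    right = np.asarray(right_torques, dtype=float)
    if left.size != 3 or right.size != 3:
        raise ValidationError("each leg needs exactly 3 torque values (30/60/90 deg)")
    if np.any(left <= 0) or np.any(right <= 0):
        raise ValidationError("torques must be positive")
    lm, rm = float(left.mean()), float(right.mean())
    if lm > rm:
        return "L", lm
    if rm > lm:
        return "R", rm
    return "indeterminate", lm


def shapiro_wilk(values, alpha: float = 0.05) -> GroupTestResult:
    """Shapiro-Wilk normality test; significant = reject normality."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InsufficientDataError("Shapiro-Wilk needs n >= 3")
    stat, p = stats.shapiro(values)
    return GroupTestResult(test_name="shapiro_wilk", statistic=float(stat),
                           p_value=float(p), alpha=alpha)


def mann_whitney(a, b, alpha: float = 0.05) -> GroupTestResult:
    """Two-sided Mann-Whitney U, e.g. dominant vs non-dominant fatigue."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("Mann-Whitney needs two non-empty groups")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupTestResult(test_name="mann_whitney", statistic=float(stat),
                           p_value=float(p), alpha=alpha)


def one_way_anova(groups: list, alpha: float = 0.05) -> GroupTestResult:
    """One-way ANOVA with the full sums-of-squares table.

    SS_model = sum_g n_g (mean_g - grand)^2, SS_error = within-group squared
    deviations, F = MS_model / MS_error; p from the F distribution. The
    result carries model/error/total sums of squares and mean squares.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 1 for a in arrays):
        raise InsufficientDataError("ANOVA needs >= 2 groups, each non-empty")
    all_values = np.concatenate(arrays)
    n_total = all_values.size
    k = len(arrays)
    if n_total - k < 1:
        raise InsufficientDataError("ANOVA needs at least one group with >= 2 values")
    grand = all_values.mean()
    ss_model = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_error = float(sum(np.sum((a - a.mean()) ** 2) for a in arrays))
    df_model, df_error = k - 1, n_total - k
    ms_model = ss_model / df_model
    ms_error = ss_error / df_error
    if ms_error == 0:
        f_value = np.inf if ms_model > 0 else 0.0
        p = 0.0 if ms_model > 0 else 1.0
    else:
        f_value = ms_model / ms_error
        p = float(stats.f.sf(f_value, df_model, df_error))
    return GroupTestResult(
        test_name="one_way_anova",
        statistic=float(f_value),
        p_value=p,
        alpha=alpha,
        sum_of_squares_model=ss_model,
        sum_of_squares_error=ss_error,
        sum_of_squares_total=ss_model + ss_error,
        mean_square_model=ms_model,
        mean_square_error=ms_error,
        f_value=float(f_value),
        df_model=df_model,
        df_error=df_error,
    )


def score_groups(score_table: ScoreTable, n_groups: int = 2) -> dict:
    """Partition participants into score groups for the cohort ANOVA.

    Participants are ranked by score and split into ``n_groups`` contiguous,
    near-equal groups (highest scores first). Returns
    ``{group_index: [participant_id, ...]}``.
    """
    if n_groups < 2:
        raise ValidationError("need at least 2 score groups")
    rows = sorted(score_table.rows, key=lambda r: (-r.score, r.participant_id))
    if len(rows) < n_groups:
        raise ValidationError("more groups than participants")
    splits = np.array_split(np.arange(len(rows)), n_groups)
    return {g: [rows[i].participant_id for i in idx] for g, idx in enumerate(splits)}
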