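"""End-to-end orchestration: filter -> angle -> segmentation -> DWT-MDF ->
regression -> cohort statistics.

`analyze_trial` handles one recording + kinematic trace; `run_pipeline`
drives whole file sets and produces an :class:`AnalysisReport`. Trials with
fewer than 3 complete cycles are excluded (the regression needs >= 3
points) and accounted for in the exclusion log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import fatigue, kinematics, preprocess, wavelet
from .errors import ErgoFatigueError, ProcessingError
from .io import CohortTable, PipelineConfig, log_stage, read_angle_csv, read_emg_csv
from .types import AngleTrace, EmgRecording


@dataclass
class AnalysisReport:
    """Everything the pipeline computed for one run."""

    config: PipelineConfig
    indices: list = field(default_factory=list)  # FatigueIndex rows
    summaries: list = field(default_factory=list)  # ParticipantSummary rows
    score_tables: dict = field(default_factory=dict)  # name -> ScoreTable
    tests: dict = field(default_factory=dict)  # name -> GroupTestResult
    exclusions: list = field(default_factory=list)  # dicts: stage/trial/reason

    def indices_of(self, participant_id: str) -> list:
        return [ix for ix in self.indices if ix.participant_id == participant_id]


def analyze_trial(recording: EmgRecording, angle: AngleTrace,
                  config: PipelineConfig | None = None) -> list:
    """Process one trial into per-channel fatigue indices.

    Stages: Butterworth band-pass (20-500 Hz), knee-angle minima
    segmentation (one segmentation per trial, applied to all channels),
    per-cycle db4 DWT median frequency, and OLS slope of MDF on the
    configured time base.
    """
    config = config or PipelineConfig()
    config.validate_against(recording.sampling_rate)

    filtered = preprocess.bandpass(recording, config.band_low, config.band_high,
                                   config.filter_order)
    log_stage("bandpass", recording.trial_id, "*", recording.n_samples,
              filtered.n_samples)

    segmentation = kinematics.detect_cycle_boundaries(angle, config.stroke_rate_hint)
    if segmentation.n_cycles < 3:
        raise ProcessingError(
            f"trial {recording.trial_id}: only {segmentation.n_cycles} complete "
            "cycles; regression needs >= 3"
        )
    log_stage("segmentation", recording.trial_id, "*", angle.alpha.size,
              segmentation.n_cycles)

    per_channel = preprocess.segment(filtered, segmentation)
    indices = []
    for label, segments in per_channel.items():
        series = wavelet.mdf_series(
            segments,
            wavelet_name=config.wavelet_name,
            depth=config.decomposition_depth,
            band_low=config.band_low,
        )
        series.trial_id = recording.trial_id
        series.participant_id = recording.participant_id
        log_stage("mdf", recording.trial_id, label, len(segments), len(series))
        indices.append(fatigue.fit_fatigue_index(series, config.regression_time_base))
    return indices


def run_pipeline(config: PipelineConfig, emg_paths: list, kinematics_paths: list,
                 cohort: CohortTable | None = None,
                 participant_ids: list | None = None) -> AnalysisReport:
    """Run the full analysis over matched EMG/kinematics file pairs.

    ``emg_paths[i]`` and ``kinematics_paths[i]`` describe the same trial;
    ``participant_ids[i]`` (default: parsed from the recording) attributes
    it. With a cohort table, score tables, dominant-leg calls and the group
    tests (Shapiro-Wilk per participant, Mann-Whitney dominant vs
    non-dominant, ANOVA of fatigue across score groups) are added.
    """
    if len(emg_paths) != len(kinematics_paths):
        raise ProcessingError("emg_paths and kinematics_paths must pair up 1:1")
    report = AnalysisReport(config=config)

    for i, (emg_path, kin_path) in enumerate(zip(emg_paths, kinematics_paths)):
        pid = participant_ids[i] if participant_ids else None
        try:
            recording = read_emg_csv(emg_path, participant_id=pid or "P0")
            if pid:
                recording.participant_id = pid
            angle = read_angle_csv(kin_path)
            report.indices.extend(analyze_trial(recording, angle, config))
        except ErgoFatigueError as exc:
            report.exclusions.append(
                {"stage": "trial", "trial": str(emg_path), "reason": str(exc)}
            )

    by_pid: dict = {}
    for ix in report.indices:
        by_pid.setdefault(ix.participant_id, []).append(ix)
    for pid, indices in sorted(by_pid.items()):
        report.summaries.append(fatigue.pool_participant(indices))

    if cohort is not None:
        _cohort_statistics(report, cohort, by_pid)
    return report


def _cohort_statistics(report: AnalysisReport, cohort: CohortTable, by_pid: dict) -> None:
    """Score tables, dominant leg, normality, Mann-Whitney and the ANOVAs."""
    cfg = report.config
    df = cohort.table

    times = dict(zip(df["participant_id"], df["time_1000m_s"]))
    report.score_tables["time"] = fatigue.proportional_score(times, better="lower")

    have_torque = all(c in df.columns for c in
                      [f"torque_{s}_{a}_nm" for s in ("L", "R") for a in (30, 60, 90)])
    dominant_sides: dict = {}
    if have_torque:
        torques = {}
        for _, row in df.iterrows():
            side, mean_torque = fatigue.dominant_leg(
                [row[f"torque_L_{a}_nm"] for a in (30, 60, 90)],
                [row[f"torque_R_{a}_nm"] for a in (30, 60, 90)],
            )
            torques[row["participant_id"]] = mean_torque
            dominant_sides[row["participant_id"]] = side
        report.score_tables["torque"] = fatigue.proportional_score(torques, better="higher")

        # dominant vs non-dominant leg fatigue, pooled across the cohort
        dom, nondom = [], []
        for pid, indices in by_pid.items():
            dside = dominant_sides.get(pid)
            if dside not in ("L", "R"):
                continue
            for ix in indices:
                if ix.channel is None:
                    continue
                (dom if ix.channel.side == dside else nondom).append(ix.slope)
        if dom and nondom:
            report.tests["mann_whitney_dominant"] = fatigue.mann_whitney(
                dom, nondom, cfg.alpha
            )

    for pid, indices in sorted(by_pid.items()):
        slopes = [ix.slope for ix in indices]
        if len(slopes) >= 3:
            report.tests[f"shapiro_{pid}"] = fatigue.shapiro_wilk(slopes, cfg.alpha)

    medians = {s.participant_id: s.median_slope for s in report.summaries}
    for name, table in report.score_tables.items():
        groups_map = fatigue.score_groups(table, cfg.n_score_groups)
        groups = [
            [medians[pid] for pid in pids if pid in medians]
            for pids in groups_map.values()
        ]
        groups = [g for g in groups if g]
        if len(groups) >= 2 and sum(len(g) for g in groups) > len(groups):
            report.tests[f"anova_{name}"] = fatigue.one_way_anova(groups, cfg.alpha)
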