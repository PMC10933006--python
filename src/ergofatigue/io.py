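"""On-disk formats, pipeline configuration and structured logging.

Everything is plain CSV/JSON/YAML. EMG and kinematic traces travel as CSV
with a ``time_s`` column; EMG channel headers use the fixed SIDE_MUSCLE
dialect (``L_GAS``, ``R_BF``, ...). Results are written as one tidy CSV of
fatigue indices (participant x trial x muscle) plus a JSON summary of the
group tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError
from .types import AngleTrace, ChannelLabel, EmgRecording

logger = logging.getLogger("ergofatigue")

#: Required columns of a cohort CSV; torque columns follow
#: ``torque_{side}_{angle}_nm`` for side L/R and angle 30/60/90.
COHORT_REQUIRED = ("participant_id", "time_1000m_s")
TORQUE_COLUMNS = tuple(
    f"torque_{side}_{angle}_nm" for side in ("L", "R") for angle in (30, 60, 90)
)


@dataclass
class PipelineConfig:
    """Tunable parameters of the analysis, mirrored 1:1 by the YAML config."""

    band_low: float = 20.0  # Hz
    band_high: float = 500.0  # Hz
    filter_order: int = 4
    wavelet_name: str = "db4"
    decomposition_depth: int | str = "auto"
    stroke_rate_hint: float = 30.0  # strokes/min
    regression_time_base: str = "seconds"
    alpha: float = 0.05
    n_score_groups: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValidationError("need 0 < band_low < band_high")
        if self.filter_order < 1 or self.filter_order % 2:
            raise ValidationError("filter_order must be a positive even integer")
        if self.decomposition_depth != "auto":
            if not isinstance(self.decomposition_depth, int) or self.decomposition_depth < 4:
                raise ValidationError("explicit decomposition_depth must be an integer >= 4")
        if self.regression_time_base not in ("seconds", "cycle_index"):
            raise ValidationError("regression_time_base must be 'seconds' or 'cycle_index'")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.stroke_rate_hint <= 0:
            raise ValidationError("stroke_rate_hint must be positive")

    def validate_against(self, sampling_rate: float) -> None:
        if self.band_high >= sampling_rate / 2:
            raise ValidationError(
                f"band_high {self.band_high} Hz violates Nyquist at fs {sampling_rate} Hz"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


@dataclass
class CohortTable:
    """Cohort metadata plus the fatigue indices accumulated per participant."""

    table: pd.DataFrame
    indices: dict = field(default_factory=dict)  # participant_id -> [FatigueIndex]

    def __post_init__(self) -> None:
        ids = self.table["participant_id"]
        if ids.duplicated().any():
            raise ValidationError("participant ids must be unique")
        if (self.table["time_1000m_s"] <= 0).any():
            raise ValidationError("1000 m times must be positive")

    @property
    def participant_ids(self) -> list:
        return list(self.table["participant_id"])


def _check_uniform_time(time: np.ndarray, what: str) -> float:
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise FormatError(f"{what}: time column must be strictly increasing")
    nominal = float(np.median(dt))
    if np.max(np.abs(dt - nominal)) > 0.01 * nominal:
        raise FormatError(f"{what}: non-uniform time base (>1% step deviation)")
    return 1.0 / nominal


def read_emg_csv(path, sampling_rate_override: float | None = None,
                 trial_id: str | None = None, participant_id: str = "P0") -> EmgRecording:
    """Load an EMG CSV (``time_s`` + one SIDE_MUSCLE column per channel)."""
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise FormatError(f"{path}: need a time_s column and >= 1 channel column")
    time = df["time_s"].to_numpy(dtype=float)
    fs = _check_uniform_time(time, str(path))
    if sampling_rate_override is not None:
        fs = sampling_rate_override
    channel_cols = [c for c in df.columns if c != "time_s"]
    labels = []
    for col in channel_cols:
        try:
            labels.append(ChannelLabel.parse(col))
        except ValidationError as exc:
            raise FormatError(f"{path}: bad channel header {col!r}: {exc}") from exc
    samples = df[channel_cols].to_numpy(dtype=float).T
    if not np.isfinite(samples).all():
        raise FormatError(f"{path}: non-finite samples present; file rejected")
    return EmgRecording(
        sampling_rate=fs,
        channels=labels,
        samples=samples,
        trial_id=trial_id or path.stem,
        participant_id=participant_id,
    )


def write_emg_csv(recording: EmgRecording, path) -> None:
    data = {"time_s": recording.time}
    for label, row in zip(recording.channels, recording.samples):
        data[str(label)] = row
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def read_angle_csv(path) -> AngleTrace:
    """Load a knee-angle trace CSV with columns time_s, alpha_deg."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "alpha_deg"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    time = df["time_s"].to_numpy(dtype=float)
    _check_uniform_time(time, str(path))
    return AngleTrace(time=time, alpha=df["alpha_deg"].to_numpy(dtype=float))


def write_angle_csv(trace: AngleTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time, "alpha_deg": trace.alpha}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_distance_csv(path) -> tuple:
    """Load a hip-ankle distance trace CSV (time_s, dist_mm) -> (time, dist)."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "dist_mm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    time = df["time_s"].to_numpy(dtype=float)
    _check_uniform_time(time, str(path))
    return time, df["dist_mm"].to_numpy(dtype=float)


def read_cohort_csv(path) -> CohortTable:
    """Load the cohort table (participant ids, 1000 m times, torque triples)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty cohort file") from exc
    for col in COHORT_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return CohortTable(table=df)


def write_cohort_csv(cohort, path) -> None:
    df = cohort.table if isinstance(cohort, CohortTable) else cohort
    df.to_csv(path, index=False)


def indices_to_frame(indices: list) -> pd.DataFrame:
    """Tidy one-row-per-index frame of fatigue regressions."""
    return pd.DataFrame(
        [
            {
                "participant_id": ix.participant_id,
                "trial_id": ix.trial_id,
                "channel": str(ix.channel) if ix.channel else "",
                "slope": ix.slope,
                "intercept": ix.intercept,
                "r_squared": ix.r_squared,
                "n_cycles": ix.n_cycles,
                "time_base": ix.time_base,
            }
            for ix in indices
        ]
    )


def write_results(report, out_dir) -> dict:
    """Write an AnalysisReport: tidy fatigue-index CSV, participant summary
    CSV, and a JSON of score tables and group tests. Returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    idx_path = out_dir / "fatigue_indices.csv"
    indices_to_frame(report.indices).to_csv(idx_path, index=False, float_format="%.8f")
    paths["indices"] = idx_path

    if report.summaries:
        sum_path = out_dir / "participant_summary.csv"
        pd.DataFrame(
            [
                {
                    "participant_id": s.participant_id,
                    "median_slope": s.median_slope,
                    "iqr_slope": s.iqr_slope,
                    "mean_slope": s.mean_slope,
                    "n_indices": s.n_indices,
                }
                for s in report.summaries
            ]
        ).to_csv(sum_path, index=False, float_format="%.8f")
        paths["summary"] = sum_path

    summary = {"config": dataclasses.asdict(report.config), "exclusions": report.exclusions}
    for name, table in report.score_tables.items():
        summary[f"scores_{name}"] = {r.participant_id: r.score for r in table.rows}
    summary["tests"] = {name: t.to_dict() for name, t in report.tests.items()}
    json_path = out_dir / "group_tests.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    paths["tests"] = json_path
    return paths


def log_stage(stage: str, trial: str, channel: str, n_in: int, n_out: int) -> None:
    logger.info("stage=%s trial=%s channel=%s n_in=%d n_out=%d",
                stage, trial, channel, n_in, n_out)
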