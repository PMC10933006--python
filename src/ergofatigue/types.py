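"""Core domain containers shared across the pipeline.

All public interfaces use degrees for angles, seconds for time, Hz for
frequency and microvolts for EMG amplitude. Containers are plain frozen-ish
dataclasses around numpy arrays; validation happens at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Muscles recorded bilaterally in the rowing protocol.
KNOWN_MUSCLES = ("GAS", "RF", "BF")
SIDES = ("L", "R")


@dataclass
class ChannelLabel:
    """(muscle, side) identity of one sEMG channel, e.g. L_GAS."""

    muscle: str
    side: str

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValidationError(f"channel side must be one of {SIDES}, got {self.side!r}")
        if not self.muscle:
            raise ValidationError("channel muscle label must be non-empty")

    def __str__(self) -> str:  # header dialect: SIDE_MUSCLE
        return f"{self.side}_{self.muscle}"

    @classmethod
    def parse(cls, text: str) -> "ChannelLabel":
        parts = text.strip().split("_", 1)
        if len(parts) != 2 or parts[0] not in SIDES:
            raise ValidationError(
                f"cannot parse channel label {text!r}; expected SIDE_MUSCLE, e.g. 'L_GAS'"
            )
        return cls(muscle=parts[1], side=parts[0])


@dataclass
class EmgRecording:
    """Uniformly sampled multichannel sEMG.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz); 4000 Hz in the rowing protocol.
    channels : list of ChannelLabel
        One label per row of ``samples``.
    samples : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    """

    sampling_rate: float
    channels: list
    samples: np.ndarray
    trial_id: str = "trial"
    participant_id: str = "P0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D (channels x time) array")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if len(self.channels) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} channel labels for {self.samples.shape[0]} sample rows"
            )
        if not np.isfinite(self.samples).all():
            raise ValidationError("EMG samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class AngleTrace:
    """Knee flexion angle alpha(t) in degrees, uniformly sampled."""

    time: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.time.shape != self.alpha.shape or self.time.ndim != 1:
            raise ValidationError("time and alpha must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise ValidationError("angle trace needs at least two samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValidationError("time must be strictly increasing")
        if np.max(np.abs(dt - dt.mean())) > 0.01 * dt.mean():
            raise ValidationError("angle trace is not uniformly sampled (>1% step deviation)")
        if np.any(self.alpha < 0) or np.any(self.alpha > 180):
            raise ValidationError("knee angle must lie in [0, 180] degrees")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))


@dataclass
class CycleSegmentation:
    """Ordered boundary sample indices partitioning a trace into stroke cycles.

    Boundaries are 0-based indices into the parent trace; segment k spans
    [boundary_indices[k], boundary_indices[k+1]) — half-open, so segmentation
    between the first and last boundary is lossless.
    """

    boundary_indices: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.boundary_indices = np.asarray(self.boundary_indices, dtype=int)
        if self.boundary_indices.size < 2:
            raise ValidationError("need at least 2 boundaries to define a cycle")
        if np.any(np.diff(self.boundary_indices) <= 0):
            raise ValidationError("boundary indices must be strictly increasing")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def n_cycles(self) -> int:
        return self.boundary_indices.size - 1

    @property
    def durations(self) -> np.ndarray:
        """Cycle durations in seconds."""
        return np.diff(self.boundary_indices) / self.sampling_rate

    @property
    def boundary_times(self) -> np.ndarray:
        return self.boundary_indices / self.sampling_rate


@dataclass
class EmgSegment:
    """One stroke cycle of one channel, cut at kinematic boundaries."""

    samples: np.ndarray
    sampling_rate: float
    start_time: float
    cycle_index: int
    channel: ChannelLabel

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValidationError("empty EMG segment")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def mid_time(self) -> float:
        return self.start_time + 0.5 * self.duration


@dataclass
class MdfSeries:
    """Per-cycle median-frequency values — the substrate of the fatigue fit."""

    mid_times: np.ndarray
    mdf: np.ndarray
    mnf: np.ndarray | None = None
    channel: ChannelLabel | None = None
    trial_id: str = "trial"
    participant_id: str = "P0"

    def __post_init__(self) -> None:
        self.mid_times = np.asarray(self.mid_times, dtype=float)
        self.mdf = np.asarray(self.mdf, dtype=float)
        if self.mid_times.shape != self.mdf.shape:
            raise ValidationError("mid_times and mdf must have equal length")
        if self.mid_times.size and np.any(np.diff(self.mid_times) <= 0):
            raise ValidationError("cycle mid-times must be strictly increasing")
        if np.any(self.mdf <= 0):
            raise ValidationError("MDF values must be positive")

    def __len__(self) -> int:
        return self.mdf.size


@dataclass
class FatigueIndex:
    """Linear-regression slope of MDF over time for one muscle x trial.

    A negative slope means the median frequency declines as the exercise
    proceeds, the spectral signature of accumulating muscle fatigue.
    """

    slope: float
    intercept: float
    r_squared: float
    n_cycles: int
    time_base: str  # "seconds" or "cycle_index"
    channel: ChannelLabel | None = None
    trial_id: str = "trial"
    participant_id: str = "P0"

    def __post_init__(self) -> None:
        if self.n_cycles < 3:
            raise ValidationError("fatigue index requires at least 3 cycles")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValidationError(f"r_squared {self.r_squared} outside [0, 1]")
        self.r_squared = float(min(max(self.r_squared, 0.0), 1.0))


@dataclass
class ParticipantSummary:
    """Median +/- IQR of a participant's fatigue indices over muscles x trials."""

    participant_id: str
    median_slope: float
    iqr_slope: float
    mean_slope: float
    n_indices: int

    def __post_init__(self) -> None:
        if self.n_indices < 1:
            raise ValidationError("participant summary needs at least one index")


@dataclass
class ScoreRow:
    participant_id: str
    value: float
    score: int


@dataclass
class ScoreTable:
    """Proportional 0-100 scores: best performer 100, worst 0."""

    rows: list = field(default_factory=list)

    def score_of(self, participant_id: str) -> int:
        for row in self.rows:
            if row.participant_id == participant_id:
                return row.score
        raise KeyError(participant_id)

    @property
    def scores(self) -> list:
        return [row.score for row in self.rows]


@dataclass
class GroupTestResult:
    """Outcome of one cohort-level hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    alpha: float = 0.05
    # ANOVA table fields (None for non-ANOVA tests)
    sum_of_squares_model: float | None = None
    sum_of_squares_error: float | None = None
    sum_of_squares_total: float | None = None
    mean_square_model: float | None = None
    mean_square_error: float | None = None
    f_value: float | None = None
    df_model: int | None = None
    df_error: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    def to_dict(self) -> dict:
        out = {
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
        }
        if self.f_value is not None:
            out.update(
                sum_of_squares_model=self.sum_of_squares_model,
                sum_of_squares_error=self.sum_of_squares_error,
                sum_of_squares_total=self.sum_of_squares_total,
                mean_square_model=self.mean_square_model,
                mean_square_error=self.mean_square_error,
                f_value=self.f_value,
                df_model=self.df_model,
                df_error=self.df_error,
            )
        return out


@dataclass
class LimbGeometry:
    """Thigh and shank segment lengths used in the law-of-cosines knee angle."""

    L1: float  # hip-knee, mm
    L2: float  # knee-ankle, mm

    def __post_init__(self) -> None:
        if self.L1 <= 0 or self.L2 <= 0:
            raise ValidationError("segment lengths L1 and L2 must be positive")
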