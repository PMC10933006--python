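"""Synthetic kinematics, sEMG and cohort tables with the statistical structure
the fatigue analysis assumes.

The generator emulates a paced rowing-ergometer trial: a knee angle that
oscillates once per stroke (30 strokes/min, ~2 s cycles), and EMG-band
colored noise whose spectral median drifts linearly in time — the signature
of accumulating muscle fatigue. Synthesis is per-cycle stationary: each
stroke cycle gets a stationary Gaussian segment whose one-sided spectral
median equals ``mdf_start + mdf_drift * t_mid``, so the per-cycle median
frequency — the quantity the pipeline estimates — has an exact known value.

Spectral shaping uses an FFT-domain amplitude mask with a Gaussian-in-log-f
(lognormal) power profile: the analytic median of a lognormal over frequency
is its log-center, so setting the log-center to the target median makes the
profile's median exact without iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ValidationError
from .types import AngleTrace, ChannelLabel, EmgRecording

_EMG_BAND = (20.0, 500.0)  # physiological sEMG band, Hz

#: Default 6-channel montage: left/right gastrocnemius, rectus femoris,
#: biceps femoris — the muscles recorded in the rowing protocol.
DEFAULT_CHANNELS = (
    ChannelLabel("GAS", "L"),
    ChannelLabel("GAS", "R"),
    ChannelLabel("RF", "L"),
    ChannelLabel("RF", "R"),
    ChannelLabel("BF", "L"),
    ChannelLabel("BF", "R"),
)


@dataclass
class SyntheticTrialSpec:
    """Parameters of one synthetic rowing trial.

    Defaults reproduce the study conditions: 4 kHz sampling, 30 strokes/min
    pacing (2 s cycles), multi-minute duration, six bilateral channels, and
    a slow negative median-frequency drift of fatigue magnitude.
    """

    sampling_rate: float = 4000.0  # Hz
    duration: float = 300.0  # s
    stroke_rate: float = 30.0  # strokes/min
    channels: tuple = DEFAULT_CHANNELS
    mdf_start: float | tuple = 120.0  # Hz, scalar or per channel
    mdf_drift: float | tuple = -0.05  # Hz/s, negative = fatigue
    spectral_width: float = 0.3  # lognormal sigma in ln-f units
    activation_depth: float = 0.5  # envelope modulation depth in [0, 1]
    noise_floor: float = 0.02  # relative amplitude of additive white noise
    angle_min: float = 60.0  # degrees, knee angle at the catch
    angle_max: float = 170.0  # degrees, knee angle at full drive
    angle_jitter_sd: float = 1.0  # degrees, smooth stroke-to-stroke variation
    amplitude: float = 100.0  # microvolt RMS scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * _EMG_BAND[1]:
            raise ValidationError(
                f"sampling_rate must exceed twice the upper EMG band edge "
                f"({2 * _EMG_BAND[1]:.0f} Hz); got {self.sampling_rate}"
            )
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        if self.stroke_rate <= 0:
            raise ValidationError("stroke_rate must be positive")
        if not (0 < self.angle_min < self.angle_max <= 180):
            raise ValidationError(
                f"need 0 < angle_min < angle_max <= 180; got "
                f"angle_min={self.angle_min}, angle_max={self.angle_max}"
            )
        if not (0.0 <= self.activation_depth <= 1.0):
            raise ValidationError("activation_depth must lie in [0, 1]")
        if self.noise_floor < 0:
            raise ValidationError("noise_floor must be non-negative")
        if self.angle_jitter_sd < 0:
            raise ValidationError("angle_jitter_sd must be non-negative")
        if self.spectral_width <= 0:
            raise ValidationError("spectral_width must be positive")
        for start, drift in zip(self.mdf_starts(), self.mdf_drifts()):
            for m in (start, start + drift * self.duration):
                if not (_EMG_BAND[0] < m < _EMG_BAND[1]):
                    raise ValidationError(
                        f"target median frequency {m:.1f} Hz leaves the open EMG band "
                        f"({_EMG_BAND[0]:.0f}, {_EMG_BAND[1]:.0f}) Hz during the trial "
                        f"(mdf_start={start}, mdf_drift={drift}, duration={self.duration})"
                    )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def period(self) -> float:
        """Stroke period in seconds (2.0 s at 30 strokes/min)."""
        return 60.0 / self.stroke_rate

    def mdf_starts(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.mdf_start, float), (self.n_channels,))

    def mdf_drifts(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.mdf_drift, float), (self.n_channels,))


@dataclass
class SyntheticCohortSpec:
    """Envelope of a synthetic cohort: 1000 m times and dominant-leg torques."""

    n_participants: int = 8
    time_range: tuple = (177.9, 207.7)  # s, spread of the study's 1000 m times
    torque_range: tuple = (190.3, 303.7)  # Nm, spread of dominant-leg torques
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValidationError("scoring needs at least 2 participants (distinct best/worst)")
        for name, (lo, hi) in (("time_range", self.time_range), ("torque_range", self.torque_range)):
            if not (0 < lo < hi):
                raise ValidationError(f"{name} must satisfy 0 < min < max; got ({lo}, {hi})")


def _cycle_edges(spec: SyntheticTrialSpec) -> np.ndarray:
    """Sample indices of nominal cycle boundaries, 0 .. n_samples inclusive."""
    n_samples = int(round(spec.duration * spec.sampling_rate))
    samples_per_cycle = spec.period * spec.sampling_rate
    edges = np.arange(0, n_samples, samples_per_cycle)
    edges = np.round(edges).astype(int)
    if edges[-1] != n_samples:
        edges = np.append(edges, n_samples)
    return edges


def generate_angle_trace(spec: SyntheticTrialSpec) -> AngleTrace:
    """Cyclic knee-angle trace with minima once per stroke at t = k*T.

    alpha(t) = angle_min + (angle_max - angle_min) * (1 - cos(2 pi t / T)) / 2
    plus smooth (Gaussian-low-passed) jitter of sd ``angle_jitter_sd``; values
    clipped to [0, 180] degrees.
    """
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    span = spec.angle_max - spec.angle_min
    alpha = spec.angle_min + span * (1.0 - np.cos(2.0 * np.pi * t / spec.period)) / 2.0
    if spec.angle_jitter_sd > 0:
        rng = np.random.default_rng([spec.seed, 0])
        white = rng.standard_normal(n)
        # Smooth with a Gaussian kernel of sd 0.1*T so the jitter perturbs
        # minima positions without creating spurious local minima.
        smooth = gaussian_filter1d(white, sigma=0.1 * spec.period * fs, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            alpha = alpha + smooth * (spec.angle_jitter_sd / sd)
    return AngleTrace(time=t, alpha=np.clip(alpha, 0.0, 180.0))


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  median_hz: float, sigma: float) -> np.ndarray:
    """Stationary Gaussian noise whose one-sided PSD is lognormal in f with
    analytic spectral median ``median_hz``; returned at unit RMS."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = np.zeros_like(f)
    pos = f > 0
    log_ratio = np.log(f[pos] / median_hz)
    # power profile S(f) ~ (1/f) exp(-log_ratio^2 / (2 sigma^2));
    # amplitude mask is sqrt(S).
    mask[pos] = np.exp(-log_ratio**2 / (4.0 * sigma**2)) / np.sqrt(f[pos])
    shaped = np.fft.irfft(spectrum * mask, n)
    rms = shaped.std()
    return shaped / rms if rms > 0 else shaped


def generate_emg(spec: SyntheticTrialSpec) -> EmgRecording:
    """Synthesize the multichannel sEMG of one trial.

    Each channel is a concatenation of per-cycle stationary segments whose
    spectral median follows ``mdf_start + mdf_drift * t_mid``, multiplied by
    a raised-cosine activation envelope phase-locked to the stroke (deepest
    at the catch, where the knee angle is minimal), plus additive white
    noise at ``noise_floor`` relative amplitude. Channel and cycle random
    streams are derived from the master seed, so channels are independent
    but the whole trial is reproducible.
    """
    fs = spec.sampling_rate
    edges = _cycle_edges(spec)
    n_samples = edges[-1]
    t = np.arange(n_samples) / fs
    starts = spec.mdf_starts()
    drifts = spec.mdf_drifts()

    envelope = (1.0 - spec.activation_depth) + spec.activation_depth * 0.5 * (
        1.0 - np.cos(2.0 * np.pi * t / spec.period)
    )

    samples = np.empty((spec.n_channels, n_samples))
    for c in range(spec.n_channels):
        channel = np.empty(n_samples)
        for k in range(edges.size - 1):
            lo, hi = edges[k], edges[k + 1]
            t_mid = 0.5 * (lo + hi) / fs
            target = starts[c] + drifts[c] * t_mid
            if not (_EMG_BAND[0] < target < _EMG_BAND[1]):
                raise ValidationError(
                    f"cycle {k} target median {target:.1f} Hz outside the EMG band"
                )
            rng = np.random.default_rng([spec.seed, c + 1, k])
            channel[lo:hi] = _shaped_noise(rng, hi - lo, fs, target, spec.spectral_width)
        noise_rng = np.random.default_rng([spec.seed, spec.n_channels + 1 + c])
        channel = channel * envelope + spec.noise_floor * noise_rng.standard_normal(n_samples)
        samples[c] = spec.amplitude * channel

    return EmgRecording(
        sampling_rate=fs,
        channels=list(spec.channels),
        samples=samples,
        trial_id=f"synth-{spec.seed}",
    )


def generate_cohort(spec: SyntheticCohortSpec):
    """Uniform draws of 1000 m times and per-leg torque triples for a cohort.

    Returns a pandas DataFrame with one row per participant: id, 1000 m time,
    and knee-extension torques for each leg at the 30/60/90 degree positions.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    ids = [f"P{i + 1}" for i in range(spec.n_participants)]
    times = rng.uniform(*spec.time_range, size=spec.n_participants)
    rows = []
    for i, pid in enumerate(ids):
        # per-leg torque triples around a common participant level, one leg
        # slightly stronger so dominance is well-defined
        level = rng.uniform(*spec.torque_range)
        asym = rng.uniform(0.02, 0.10) * level
        stronger = rng.choice(["L", "R"])
        row = {"participant_id": pid, "time_1000m_s": round(float(times[i]), 1)}
        for side in ("L", "R"):
            base = level + (asym / 2 if side == stronger else -asym / 2)
            for angle in (30, 60, 90):
                row[f"torque_{side}_{angle}_nm"] = round(float(base + rng.normal(0, 0.03 * level)), 1)
        rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort_slopes(
    n_participants: int,
    n_indices: int = 18,
    drift_mean: float = -0.05,
    drift_sd: float = 0.02,
    seed: int = 0,
) -> dict:
    """Homogeneous per-participant fatigue-index draws for null-cohort studies.

    Every participant's muscle x trial slopes come from the same normal
    distribution (mean ``drift_mean`` Hz/s, sd ``drift_sd``), i.e. fatigue
    is unrelated to any performance grouping — the null hypothesis of the
    cohort ANOVA. ``n_indices`` defaults to 18 = 6 muscles x 3 trials.
    """
    if n_participants < 2:
        raise ValidationError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    return {
        f"P{i + 1}": rng.normal(drift_mean, drift_sd, size=n_indices)
        for i in range(n_participants)
    }
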