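"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import periodogram

from ergofatigue import ChannelLabel, SyntheticTrialSpec


def periodogram_median_frequency(samples: np.ndarray, fs: float) -> float:
    """Independent median-frequency oracle: cumulative periodogram power.

    Uses a plain FFT periodogram, not the wavelet path under test.
    """
    freqs, psd = periodogram(samples, fs=fs)
    cum = np.cumsum(psd)
    half = cum[-1] / 2.0
    k = int(np.searchsorted(cum, half))
    if k == 0:
        return float(freqs[0])
    # linear interpolation between bin k-1 and k
    frac = (half - cum[k - 1]) / (cum[k] - cum[k - 1])
    return float(freqs[k - 1] + frac * (freqs[k] - freqs[k - 1]))


def dyadic_band_of(f: float, fs: float, depth: int) -> tuple:
    """(f_low, f_high) of the dyadic DWT band containing frequency f."""
    lo, hi = 0.0, fs / 2 ** (depth + 1)
    if f <= hi:
        return lo, hi
    for j in range(depth, 0, -1):
        lo, hi = fs / 2 ** (j + 1), fs / 2**j
        if lo < f <= hi:
            return lo, hi
    return lo, hi


@pytest.fixture(scope="session")
def single_channel() -> tuple:
    return (ChannelLabel("GAS", "L"),)


@pytest.fixture(scope="session")
def short_trial_spec(single_channel) -> SyntheticTrialSpec:
    """60 s, one channel, jitter-free: fast, analytically transparent."""
    return SyntheticTrialSpec(
        duration=60.0, channels=single_channel, angle_jitter_sd=0.0, seed=7
    )


@pytest.fixture(scope="session")
def stationary_trial_spec(single_channel) -> SyntheticTrialSpec:
    """Drift-free trial for stationarity-dependent checks."""
    return SyntheticTrialSpec(
        duration=60.0, channels=single_channel, mdf_drift=0.0,
        angle_jitter_sd=0.0, seed=11
    )
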