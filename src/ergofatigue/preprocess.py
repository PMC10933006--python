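"""Band-limiting of raw EMG and per-cycle segmentation.

Filtering precedes segmentation (filter once per trial, then cut): segments
are short relative to the trial, so filtering whole channels avoids
per-segment edge transients.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import ValidationError
from .types import CycleSegmentation, EmgRecording, EmgSegment


def bandpass(recording: EmgRecording, low: float = 20.0, high: float = 500.0,
             order: int = 4) -> EmgRecording:
    """Zero-phase Butterworth band-pass of every channel.

    The filter is applied forward and backward (``sosfiltfilt``), which
    cancels phase distortion and doubles the effective attenuation order.
    Output length equals input length.
    """
    nyquist = recording.sampling_rate / 2.0
    if not (0 < low < high < nyquist):
        raise ValidationError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyquist:.0f} Hz); "
            f"got low={low}, high={high}"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=recording.sampling_rate,
                 output="sos")
    filtered = sosfiltfilt(sos, recording.samples, axis=1)
    return EmgRecording(
        sampling_rate=recording.sampling_rate,
        channels=list(recording.channels),
        samples=filtered,
        trial_id=recording.trial_id,
        participant_id=recording.participant_id,
    )


def segment(recording: EmgRecording, segmentation: CycleSegmentation) -> dict:
    """Cut every channel into per-cycle segments at the kinematic boundaries.

    Segments are contiguous, non-overlapping and half-open
    ([b_k, b_{k+1})), so concatenating them reproduces the span between the
    first and last boundary exactly. Returns ``{channel_label: [EmgSegment]}``
    with ``len == n_boundaries - 1`` per channel.
    """
    bounds = segmentation.boundary_indices
    if bounds[0] < 0 or bounds[-1] > recording.n_samples:
        raise IndexError(
            f"boundary indices [{bounds[0]}, {bounds[-1]}] outside recording "
            f"of {recording.n_samples} samples"
        )
    fs = recording.sampling_rate
    out: dict = {}
    for ch_idx, label in enumerate(recording.channels):
        segments = []
        for k in range(bounds.size - 1):
            lo, hi = int(bounds[k]), int(bounds[k + 1])
            segments.append(
                EmgSegment(
                    samples=recording.samples[ch_idx, lo:hi],
                    sampling_rate=fs,
                    start_time=lo / fs,
                    cycle_index=k,
                    channel=label,
                )
            )
        out[str(label)] = segments
    return out
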