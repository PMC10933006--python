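"""Knee flexion angle from marker geometry and stroke-cycle boundary detection.

The knee angle is obtained from the law of cosines applied to the
hip-knee (L1) and knee-ankle (L2) segments and the hip-ankle marker
distance D:

    alpha = arccos((L1^2 + L2^2 - D^2) / (2 L1 L2))   [degrees]

Stroke cycles are delimited at the minima of alpha(t): the knee is most
flexed at the catch, so consecutive minima bracket exactly one complete
drive-plus-recovery cycle.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from .errors import GeometryError, SegmentationError, ValidationError
from .types import AngleTrace, CycleSegmentation, LimbGeometry

#: Tolerance on the arccos argument before a triangle-inequality error.
_COS_TOL = 1e-9

#: Smoothing window as a fraction of the expected stroke period.
SMOOTH_WINDOW_FRACTION = 0.1
#: Minimum separation between detected minima, fraction of expected period.
MIN_SEPARATION_FRACTION = 0.5


def knee_angle(geometry: LimbGeometry, D) -> np.ndarray | float:
    """Knee flexion angle (degrees) for hip-ankle distance(s) ``D`` in mm.

    The cosine argument is clamped to [-1, 1] when within 1e-9 of the
    bounds; beyond that tolerance the distance is geometrically impossible
    and a :class:`GeometryError` is raised.
    """
    D_arr = np.asarray(D, dtype=float)
    if np.any(D_arr < 0):
        raise ValidationError("hip-ankle distance D must be non-negative")
    cos_arg = (geometry.L1**2 + geometry.L2**2 - D_arr**2) / (2.0 * geometry.L1 * geometry.L2)
    bad = (cos_arg < -1.0 - _COS_TOL) | (cos_arg > 1.0 + _COS_TOL)
    if np.any(bad):
        idx = int(np.argmax(np.atleast_1d(bad)))
        d_bad = float(np.atleast_1d(D_arr)[idx])
        raise GeometryError(
            f"triangle inequality violated at sample {idx}: "
            f"D={d_bad:.3f} mm with L1={geometry.L1} mm, L2={geometry.L2} mm"
        )
    alpha = np.degrees(np.arccos(np.clip(cos_arg, -1.0, 1.0)))
    return float(alpha) if np.isscalar(D) or np.ndim(D) == 0 else alpha


def angle_trace_from_distance(geometry: LimbGeometry, time, distance) -> AngleTrace:
    """Convert a hip-ankle distance trace (mm) to an :class:`AngleTrace`.

    Elementwise law-of-cosines; sample count is preserved. Geometry errors
    are propagated with the offending sample index.
    """
    alpha = knee_angle(geometry, np.asarray(distance, dtype=float))
    return AngleTrace(time=np.asarray(time, dtype=float), alpha=alpha)


def _smooth(alpha: np.ndarray, window: int) -> np.ndarray:
    """Zero-phase moving average via reflection padding."""
    if window <= 1:
        return alpha.copy()
    kernel = np.ones(window) / window
    padded = np.pad(alpha, window, mode="reflect")
    smoothed = np.convolve(padded, kernel, mode="same")
    return smoothed[window:-window]


def detect_cycle_boundaries(trace: AngleTrace, stroke_rate_hint: float) -> CycleSegmentation:
    """Locate per-cycle minima of the knee angle to serve as segment boundaries.

    A smoothed copy of alpha(t) (zero-phase moving average, window 0.1 x
    expected period) is searched for local minima with an enforced minimum
    separation of 0.5 x expected period; when two candidates fall inside
    the separation window the deeper one is kept (ties: earlier). Endpoint
    samples count as minima when the smoothed trace rises away from them,
    so a trace holding an integer number of cycles yields
    floor(duration/period) + 1 boundaries. Returned indices refer to the
    unsmoothed trace.
    """
    if stroke_rate_hint <= 0:
        raise ValidationError("stroke_rate_hint must be positive")
    fs = trace.sampling_rate
    period = 60.0 / stroke_rate_hint
    duration = (trace.time.size - 1) / fs
    if duration < 2 * period:
        raise SegmentationError(
            f"trace duration {duration:.2f} s shorter than two expected cycles ({2 * period:.2f} s)"
        )

    window = max(1, int(round(SMOOTH_WINDOW_FRACTION * period * fs)))
    smoothed = _smooth(trace.alpha, window)
    min_sep = max(1, int(round(MIN_SEPARATION_FRACTION * period * fs)))

    interior, _ = find_peaks(-smoothed, distance=min_sep)
    candidates = list(interior)

    # Endpoints: admit as minima if the smoothed trace rises away from them
    # over a quarter period (find_peaks never reports edge samples).
    look = max(2, int(round(0.25 * period * fs)))
    if smoothed[0] <= np.min(smoothed[1:look + 1]):
        candidates.insert(0, 0)
    n = smoothed.size
    if smoothed[-1] <= np.min(smoothed[n - look - 1:n - 1]):
        candidates.append(n - 1)

    # Re-enforce the separation across endpoint additions, keeping the deeper.
    candidates = sorted(set(candidates))
    kept: list[int] = []
    for idx in candidates:
        if kept and idx - kept[-1] < min_sep:
            if smoothed[idx] < smoothed[kept[-1]]:
                kept[-1] = idx
        else:
            kept.append(idx)

    if len(kept) < 2:
        raise SegmentationError(
            f"found {len(kept)} knee-angle minima; at least 2 are required to define a cycle"
        )
    return CycleSegmentation(boundary_indices=np.array(kept, dtype=int), sampling_rate=fs)
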