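"""Chromatographic primitives: traces, peak detection, and integration.

A :class:`Trace` is a single extracted-ion chromatogram (XIC) — one m/z
channel's intensity sampled on a uniform retention-time grid.  Peak
detection is deliberately simple and deterministic: local maxima above a
robust noise threshold, with boundaries at the nearest local minimum or
the 1 %-of-apex crossing, whichever is reached first walking away from
the apex.  Areas are trapezoidal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_widths


class TraceError(ValueError):
    """Raised for malformed traces or invalid integration bounds."""


@dataclass
class Trace:
    """One m/z channel's time-intensity series for a single run.

    ``rt`` is in minutes on a strictly increasing, uniformly spaced grid;
    ``intensity`` is nonnegative and the same length.  Traces from the
    same run share the ``rt`` array object, so grid identity can be
    checked cheaply with ``is``.
    """

    mz: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity)
        if self.rt.shape != self.intensity.shape:
            raise TraceError("rt and intensity must have equal length")
        if self.rt.size >= 2 and not np.all(np.diff(self.rt) > 0):
            raise TraceError("rt must be strictly increasing")
        if self.intensity.size and float(self.intensity.min()) < 0:
            raise TraceError("intensities must be nonnegative")

    @property
    def step(self) -> float:
        """Sampling step in minutes."""
        if self.rt.size < 2:
            return float("nan")
        return float(self.rt[1] - self.rt[0])


@dataclass
class Peak:
    """A detected chromatographic peak with trapezoidal area (counts*min)."""

    trace_mz: float
    apex_rt: float
    apex_intensity: float
    left_rt: float
    right_rt: float
    area: float
    fwhm: float


def _noise_level(y: np.ndarray) -> float:
    # 1.4826 * MAD: robust sigma estimate; 0 for noiseless traces.
    med = np.median(y)
    return 1.4826 * float(np.median(np.abs(y - med)))


def detect_peaks(trace: Trace, min_snr: float = 3.0, min_points: int = 4) -> list[Peak]:
    """Find peaks in a trace as local maxima above ``min_snr`` times the
    robust noise level, requiring at least ``min_points`` samples above
    half height.

    Returns an empty list for empty or all-zero traces.  On noiseless
    traces the MAD noise estimate is 0 and every genuine local maximum
    qualifies (the ``min_points`` rule still applies).
    """
    if min_snr <= 0:
        raise ValueError("min_snr must be positive")
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    y = np.asarray(trace.intensity, dtype=float)
    if y.size == 0 or not np.any(y > 0):
        return []
    thr = min_snr * _noise_level(y)
    idx, _ = find_peaks(y, height=thr if thr > 0 else None)
    if idx.size == 0:
        return []
    # samples above half height (contiguous around the apex)
    widths, _, _, _ = peak_widths(y, idx, rel_height=0.5)
    keep = widths + 1 >= min_points
    idx, widths = idx[keep], widths[keep]
    rt = trace.rt
    step = trace.step
    peaks: list[Peak] = []
    for apex, w in zip(idx, widths):
        lo = _walk_boundary(y, apex, -1)
        hi = _walk_boundary(y, apex, +1)
        area = float(np.trapezoid(y[lo : hi + 1], rt[lo : hi + 1]))
        peaks.append(
            Peak(
                trace_mz=trace.mz,
                apex_rt=float(rt[apex]),
                apex_intensity=float(y[apex]),
                left_rt=float(rt[lo]),
                right_rt=float(rt[hi]),
                area=area,
                fwhm=float(w * step),
            )
        )
    return peaks


def _walk_boundary(y: np.ndarray, apex: int, direction: int) -> int:
    """Walk from the apex until the first local minimum or the 1%-of-apex
    crossing, whichever comes first."""
    floor = 0.01 * y[apex]
    i = apex
    n = y.size
    while True:
        j = i + direction
        if j < 0 or j >= n:
            return i
        if y[j] >= y[i]:  # stopped descending -> local minimum at i
            return i
        i = j
        if y[i] <= floor:
            return i


def integrate_peak(trace: Trace, left_rt: float, right_rt: float) -> float:
    """Trapezoidal area of ``trace`` over [left_rt, right_rt] in counts*min.

    Boundary values are linearly interpolated so the result is exact for
    piecewise-linear signals regardless of grid alignment.
    """
    if not left_rt < right_rt:
        raise TraceError("left_rt must be < right_rt")
    rt = trace.rt
    if rt.size == 0 or left_rt < rt[0] or right_rt > rt[-1]:
        raise TraceError("integration bounds outside trace range")
    y = trace.intensity.astype(float)
    lo = int(np.searchsorted(rt, left_rt, side="right"))
    hi = int(np.searchsorted(rt, right_rt, side="left"))
    xs = np.concatenate(([left_rt], rt[lo:hi], [right_rt]))
    ys = np.concatenate(
        ([np.interp(left_rt, rt, y)], y[lo:hi], [np.interp(right_rt, rt, y)])
    )
    return float(np.trapezoid(ys, xs))


def total_ion_chromatogram(traces: list[Trace]) -> Trace:
    """Pointwise sum of traces sharing one rt grid (the run TIC)."""
    if not traces:
        raise TraceError("no traces given")
    grid = traces[0].rt
    total = np.zeros(grid.size, dtype=float)
    for t in traces:
        if t.rt is not grid and (
            t.rt.size != grid.size or not np.allclose(t.rt, grid)
        ):
            raise TraceError("traces do not share an rt grid")
        total += t.intensity
    return Trace(mz=float("nan"), rt=grid, intensity=total)
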