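"""Detection of laser-induced temperature peaks in per-pixel time traces.

Each camera-pixel trace T_i(t) contains one approximately Gaussian bump per
laser pulse that heated that pixel's neighbourhood.  A sliding 1D Gaussian
fit locates each bump in time; detections from neighbouring pixels within
one frame of each other are grouped (one pulse lights up several camera
pixels through heat diffusion) into a single :class:`PeakEvent`, whose
frame is then passed to the 2D sub-pixel localization step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .forward import ThermalStack
from .scenes import ParameterError

__all__ = [
    "TracePeak",
    "PeakEvent",
    "detect_trace_peaks",
    "detect_stack_events",
    "roi_from_max_projection",
    "default_window",
]


@dataclass(frozen=True)
class TracePeak:
    """One fitted temperature bump in a single-pixel trace."""

    time: float       # s, fitted 1D Gaussian centre
    amplitude: float  # °C
    width: float      # s, fitted 1D Gaussian std
    frame: int        # nearest frame index


@dataclass(frozen=True)
class PeakEvent:
    """One laser-induced temperature peak, deduplicated across pixels."""

    col: int
    row: int
    time: float
    frame: int
    amplitude: float  # °C, 1D fitted amplitude at the brightest pixel
    width: float      # s


def default_window(tau_on: float, f_rate: float) -> int:
    """Default sliding-window length: brackets the rise and early decay."""
    return max(5, int(round(2.0 * tau_on * f_rate)))


def _gauss1d(t, amp, tc, s, base):
    return base + amp * np.exp(-((t - tc) ** 2) / (2.0 * s ** 2))


def detect_trace_peaks(trace, f_rate: float, window: int,
                       amp_threshold: float, t_start: float = 0.0,
                       ) -> list[TracePeak]:
    """Find temperature peaks in one pixel trace by windowed Gaussian fits.

    Candidate frames are local maxima of the 3-frame-smoothed trace rising
    at least 0.8·``amp_threshold`` above the trace median (windows that flat
    cannot yield an accepted fit, so they are skipped — a documented
    shortcut over fitting every window position).  Each candidate window is
    fitted to ``amp·exp(−(t−t_c)²/(2s²)) + baseline``; a fit is accepted
    when the centre falls in the central third of the window and the
    amplitude reaches ``amp_threshold``.  Accepted candidates closer than
    ``window/2`` frames are merged keeping the larger amplitude.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ParameterError("trace contains non-finite values")
    if window < 5:
        raise ParameterError("window must be >= 5 frames")
    if len(trace) < window:
        raise ParameterError("trace shorter than the fit window")
    dt = 1.0 / f_rate
    base = float(np.median(trace))
    smooth = np.convolve(trace, np.ones(3) / 3.0, mode="same")
    idx, _ = signal.find_peaks(smooth, height=base + 0.8 * amp_threshold,
                               distance=max(1, window // 2))
    half = window // 2
    accepted: list[TracePeak] = []
    for i in idx:
        lo = int(np.clip(i - half, 0, len(trace) - window))
        win = trace[lo:lo + window]
        tt = (lo + np.arange(window)) * dt
        p0 = (max(trace[i] - np.median(win), amp_threshold),
              i * dt, window * dt / 6.0, float(np.median(win)))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    _gauss1d, tt, win, p0=p0,
                    bounds=([0.0, tt[0], dt / 4.0, -np.inf],
                            [np.inf, tt[-1], window * dt, np.inf]),
                    maxfev=400)
        except (RuntimeError, ValueError):
            continue
        amp, tc, s, _ = popt
        third = window * dt / 3.0
        if amp >= amp_threshold and tt[0] + third <= tc <= tt[-1] - third + dt:
            accepted.append(TracePeak(time=tc + t_start, amplitude=float(amp),
                                      width=float(s),
                                      frame=int(round(tc * f_rate))))
    # merge candidates closer than window/2 frames, keeping larger amplitude
    accepted.sort(key=lambda p: p.time)
    merged: list[TracePeak] = []
    for p in accepted:
        if merged and (p.time - merged[-1].time) * f_rate < window / 2.0:
            if p.amplitude > merged[-1].amplitude:
                merged[-1] = p
        else:
            merged.append(p)
    return merged


def roi_from_max_projection(stack: ThermalStack, netd: float = 0.1,
                            pad: int = 2) -> tuple[int, int, int, int]:
    """Bounding box (col0, row0, col1, row1), half-open, of the heated area.

    Pixels whose temporal maximum exceeds the baseline estimate + 3·NETD,
    padded by ``pad`` pixels and clipped to the frame.  Falls back to the
    full frame (with a warning) when nothing exceeds the threshold.
    """
    if stack.n_frames == 0:
        raise ParameterError("empty stack")
    proj = stack.frames.max(axis=0)
    t0 = stack.T0 if stack.T0 is not None else float(np.median(stack.frames))
    hot = proj > t0 + 3.0 * netd
    n_rows, n_cols = proj.shape
    if not hot.any():
        warnings.warn("no pixel above baseline + 3*NETD; using full frame",
                      stacklevel=2)
        return (0, 0, n_cols, n_rows)
    rows, cols = np.nonzero(hot)
    return (max(0, cols.min() - pad), max(0, rows.min() - pad),
            min(n_cols, cols.max() + 1 + pad), min(n_rows, rows.max() + 1 + pad))


def detect_stack_events(stack: ThermalStack,
                        roi: tuple[int, int, int, int] | None = None,
                        window: int | None = None,
                        amp_threshold: float = 0.3,
                        tau_on: float = 0.3,
                        frame_tol: int | None = None) -> list[PeakEvent]:
    """Detect and deduplicate laser-induced peaks over a stack ROI.

    Runs :func:`detect_trace_peaks` on every ROI pixel, then groups
    detections whose peak frames differ by at most ``frame_tol`` and whose
    pixels are 8-connected (transitively); each group becomes one
    :class:`PeakEvent` at the pixel with the largest 1D amplitude.  The
    default tolerance, τ_on·f_rate/2 frames, absorbs the diffusion delay of
    the peak arrival at neighbouring pixels while staying below the minimum
    τ_on separation of consecutive pulses.
    """
    f_rate = stack.f_rate
    if window is None:
        window = default_window(tau_on, f_rate)
    if frame_tol is None:
        frame_tol = max(1, int(round(tau_on * f_rate / 2.0)))
    if roi is None:
        roi = roi_from_max_projection(stack)
    c0, r0, c1, r1 = roi
    detections = []   # (col, row, TracePeak)
    for row in range(r0, r1):
        for col in range(c0, c1):
            for p in detect_trace_peaks(stack.frames[:, row, col], f_rate,
                                        window, amp_threshold,
                                        t_start=float(stack.timestamps[0])):
                detections.append((col, row, p))
    if not detections:
        return []
    # union-find grouping: frames differ <= 1 AND pixels 8-connected
    n = len(detections)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    order = sorted(range(n), key=lambda k: detections[k][2].frame)
    frames_sorted = [detections[k][2].frame for k in order]
    for ii, a in enumerate(order):
        ca, ra_, pa = detections[a]
        for jj in range(ii + 1, n):
            if frames_sorted[jj] - pa.frame > frame_tol:
                break
            b = order[jj]
            cb, rb_, pb = detections[b]
            if abs(ca - cb) <= 1 and abs(ra_ - rb_) <= 1:
                union(a, b)
    groups: dict[int, list[int]] = {}
    for k in range(n):
        groups.setdefault(find(k), []).append(k)
    events = []
    for members in groups.values():
        best = max(members, key=lambda k: detections[k][2].amplitude)
        col, row, p = detections[best]
        events.append(PeakEvent(col=col, row=row, time=p.time, frame=p.frame,
                                amplitude=p.amplitude, width=p.width))
    events.sort(key=lambda e: e.time)
    return events
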