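"""Modulated raster-scan illumination schedules.

The sample is raster scanned by the focused beam; during each pass only the
scan pixels lying on a sparse square lattice with spacings (Δx, Δy) are
laser-activated (shutter open, dwell τ_on) while all others are visited
silently (shutter closed, dwell τ_off).  Repeating the raster Δx·Δy times
with shifted lattice offsets covers every scan pixel exactly once while
keeping concurrent temperature peaks isolated in space and time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scenes import BeamModel, ParameterError, SampleModel

__all__ = [
    "ScanProtocol",
    "IlluminationEvent",
    "build_schedule",
    "total_time",
    "min_separation",
    "validate_schedule",
    "schedule_to_csv",
]


@dataclass(frozen=True)
class ScanProtocol:
    """Scan-grid geometry and modulation timing.

    ``N_x`` × ``N_y`` square scan pixels of size ``dx`` μm; lattice spacings
    ``lattice_dx``/``lattice_dy`` in scan pixels; dwell ``tau_on`` s at
    activated pixels, ``tau_off`` s at silent ones (shutter closed,
    default 2 ms); ``origin`` is the lab-frame corner of scan pixel (0, 0).
    """

    N_x: int
    N_y: int
    dx: float = 10.0
    lattice_dx: int = 1
    lattice_dy: int = 1
    tau_on: float = 0.3
    tau_off: float = 0.002
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.N_x < 1 or self.N_y < 1:
            raise ParameterError("scan grid must be at least 1x1")
        if not (1 <= self.lattice_dx <= self.N_x):
            raise ParameterError("lattice_dx must satisfy 1 <= lattice_dx <= N_x")
        if not (1 <= self.lattice_dy <= self.N_y):
            raise ParameterError("lattice_dy must satisfy 1 <= lattice_dy <= N_y")
        if self.dx <= 0 or self.tau_on <= 0 or self.tau_off <= 0:
            raise ParameterError("dx, tau_on, tau_off must be > 0")

    @property
    def n_scans(self) -> int:
        return self.lattice_dx * self.lattice_dy

    @property
    def n_pixels(self) -> int:
        return self.N_x * self.N_y

    def pixel_center(self, i, j) -> tuple[np.ndarray, np.ndarray]:
        """Lab-frame centre (x, y) μm of scan pixel (i=col, j=row)."""
        x = self.origin[0] + (np.asarray(i) + 0.5) * self.dx
        y = self.origin[1] + (np.asarray(j) + 0.5) * self.dx
        return x, y


@dataclass(frozen=True)
class IlluminationEvent:
    """A single laser activation: square pulse of duration τ_on at (x0, y0)."""

    i: int            # scan column index
    j: int            # scan row index
    x0: float         # μm
    y0: float         # μm
    t0: float         # start time, s
    duration: float   # = τ_on, s

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration


def build_schedule(protocol: ScanProtocol) -> list[IlluminationEvent]:
    """Ordered illumination events of the full modulated raster scan.

    Scan ``s`` (s = 0..ΔxΔy−1) activates pixels with
    ``(i mod Δx, j mod Δy) == (s mod Δx, s // Δx)`` (row-major offset
    order).  Within a scan, all N_x·N_y pixels are visited in raster order
    (rows top to bottom, columns left to right); time advances by τ_on at
    activated pixels and τ_off at silent ones.  Every pixel is activated
    exactly once over the Δx·Δy scans.
    """
    dx_l, dy_l = protocol.lattice_dx, protocol.lattice_dy
    events: list[IlluminationEvent] = []
    t = 0.0
    cols = np.arange(protocol.N_x)
    for s in range(protocol.n_scans):
        ox, oy = s % dx_l, s // dx_l
        for j in range(protocol.N_y):
            row_active = (j % dy_l) == oy
            active_cols = cols[(cols % dx_l) == ox] if row_active else np.empty(0, int)
            if not row_active or len(active_cols) == 0:
                t += protocol.N_x * protocol.tau_off
                continue
            # silent pixels between activations advance time by tau_off each
            prev = -1
            for i in active_cols:
                t += (i - prev - 1) * protocol.tau_off
                x0, y0 = protocol.pixel_center(int(i), j)
                events.append(IlluminationEvent(int(i), j, float(x0), float(y0),
                                                t, protocol.tau_on))
                t += protocol.tau_on
                prev = int(i)
            t += (protocol.N_x - prev - 1) * protocol.tau_off
    return events


def total_time(protocol: ScanProtocol) -> float:
    """Closed-form total acquisition time, s.

    t_tot = N_x N_y τ_on + N_x N_y τ_off (ΔxΔy − 1): every pixel is
    activated once (dwell τ_on) and visited silently ΔxΔy − 1 times.
    """
    n = protocol.n_pixels
    return n * protocol.tau_on + n * protocol.tau_off * (protocol.n_scans - 1)


def min_separation(sample: SampleModel, tau_on: float, beam: BeamModel,
                   safety_k: float = 3.0) -> tuple[float, float]:
    """Heuristic minimum spacing of concurrent activations.

    Returns ``(dx_min_um, dt_min_s)``: peaks closer than ``dx_min`` in space
    AND ``dt_min`` in time risk overlapping in the camera frames.  Uses the
    diffusion-length rule ``dx_min = k·sqrt(ω₀²/4 + 4 D τ_on)`` and
    ``dt_min = k·max(τ_on, τ_d)`` with safety factor ``k`` (default 3).
    """
    if tau_on <= 0:
        raise ParameterError("tau_on must be > 0")
    dx_min = safety_k * float(np.sqrt(beam.w0 ** 2 / 4.0 + 4.0 * sample.D * tau_on))
    dt_min = safety_k * max(tau_on, sample.tau_d)
    return dx_min, dt_min


def validate_schedule(events: list[IlluminationEvent], dx_min: float,
                      dt_min: float) -> list[tuple[int, int]]:
    """Report pairs of events closer than ``dx_min`` in space AND ``dt_min``
    in time (indices into ``events``).  Reports rather than refuses."""
    n = len(events)
    t0 = np.array([e.t0 for e in events])
    x = np.array([e.x0 for e in events])
    y = np.array([e.y0 for e in events])
    violations = []
    for a in range(n):
        # events are time ordered: only look ahead while within dt_min
        for b in range(a + 1, n):
            if t0[b] - t0[a] >= dt_min:
                break
            d = np.hypot(x[b] - x[a], y[b] - y[a])
            if d < dx_min:
                violations.append((a, b))
    return violations


def schedule_to_csv(events: list[IlluminationEvent], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(k, e.i, e.j, e.x0, e.y0, e.t0, e.duration)
         for k, e in enumerate(events)],
        columns=["event", "i", "j", "x0_um", "y0_um", "t0_s", "duration_s"],
    ).to_csv(path, index=False)
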