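"""Ground-truth scenes and physical models for photo-thermal imaging.

The objects here describe *what is on the sample plane* and *how it turns
light into heat*:

* :class:`AbsorberMap` — a high-resolution grid of absorptance values in
  [0, 1] standing in for ink patterns or nanoparticle clusters.  It is the
  ground truth against which super-resolved reconstructions are scored.
* :class:`SampleModel` — emissivity, thermal diffusivity, baseline
  temperature, heating amplitude and a lumped heat-loss time.
* :class:`BeamModel` — the focused Gaussian excitation beam.

Coordinate convention (used package-wide): lab-frame continuous coordinates
in micrometres, ``x`` rightward, ``y`` downward.  Grid indices are
``(row, col)``, zero-based, with the centre of cell ``(0, 0)`` at
``origin + (0.5*pitch, 0.5*pitch)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AbsorberMap",
    "SampleModel",
    "BeamModel",
    "make_stripe_grid",
    "make_sparse_clusters",
    "make_uniform_square",
    "ink_sample_model",
    "biopsy_sample_model",
    "beam_56um",
    "beam_22um",
]


class ParameterError(ValueError):
    """Invalid geometry or physical parameter."""


@dataclass
class AbsorberMap:
    """Absorptance grid with lab-frame geometry and ground-truth metadata.

    Parameters
    ----------
    values : ndarray, shape (n_rows, n_cols)
        Relative absorptance in [0, 1] (dimensionless).  Absolute absorbed
        power enters only through :attr:`SampleModel.A`.
    pitch : float
        Grid cell size, μm.
    origin : (float, float)
        Lab-frame (x, y) position of the *corner* of cell (0, 0), μm; the
        cell centre sits at ``origin + 0.5*pitch``.
    centers : list of (float, float)
        Ground-truth feature centres (μm) recorded by the generators.
    """

    values: np.ndarray
    pitch: float
    origin: tuple[float, float] = (0.0, 0.0)
    centers: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ParameterError("absorber map must be a non-empty 2D grid")
        if self.pitch <= 0:
            raise ParameterError("pitch must be > 0")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ParameterError("absorptance values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float]:
        """Field size (width, height) in μm."""
        return (self.shape[1] * self.pitch, self.shape[0] * self.pitch)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of all cell centres, μm."""
        ox, oy = self.origin
        x = ox + (np.arange(self.shape[1]) + 0.5) * self.pitch
        y = oy + (np.arange(self.shape[0]) + 0.5) * self.pitch
        return np.meshgrid(x, y)

    def absorptance_at(self, x, y) -> np.ndarray:
        """Nearest-cell absorptance at lab coordinates (0 outside the grid)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.pitch).astype(int)
        row = np.floor((y - self.origin[1]) / self.pitch).astype(int)
        ok = (col >= 0) & (col < self.shape[1]) & (row >= 0) & (row < self.shape[0])
        out = np.zeros(np.broadcast(x, y).shape)
        out[ok] = self.values[row[ok], col[ok]]
        return out

    # -- TIFF + JSON sidecar round trip ---------------------------------
    def write(self, path: str | Path) -> None:
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.values.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({
            "pitch_um": self.pitch,
            "origin_um": list(self.origin),
            "centers_um": [list(c) for c in self.centers],
        }))

    @classmethod
    def read(cls, path: str | Path) -> "AbsorberMap":
        import tifffile

        path = Path(path)
        values = tifffile.imread(path).astype(float)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(values=values, pitch=meta["pitch_um"],
                   origin=tuple(meta["origin_um"]),
                   centers=[tuple(c) for c in meta["centers_um"]])


@dataclass(frozen=True)
class SampleModel:
    """Thermo-physical sample description.

    Parameters
    ----------
    emissivity : float
        Gray-body emissivity ε in (0, 1].
    D : float
        In-plane thermal diffusivity, μm²/s.  Water-like tissue is
        ~1.4e5 μm²/s (0.14 mm²/s).
    T0 : float
        Equilibrium baseline temperature without illumination, °C.
    A : float
        Heating amplitude, °C/s of temperature rise at the beam centre per
        unit absorptance in the no-diffusion, no-loss limit.  Lumps absorbed
        power, heat capacity and sample thickness.
    tau_d : float
        Lumped exponential heat-loss time to the environment, s (Newton
        cooling); sets the rise-saturation and decay time of a peak.
    """

    emissivity: float = 0.95
    D: float = 1.4e5
    T0: float = 19.85  # 293 K, the typical equilibrium temperature
    A: float = 6.0e4
    tau_d: float = 0.2

    def __post_init__(self):
        if not (0 < self.emissivity <= 1):
            raise ParameterError("emissivity must be in (0, 1]")
        if self.D < 0:
            raise ParameterError("diffusivity must be >= 0")
        if self.A < 0:
            raise ParameterError("heating amplitude must be >= 0")
        if self.tau_d <= 0:
            raise ParameterError("loss time tau_d must be > 0")

    @property
    def T0_kelvin(self) -> float:
        return self.T0 + 273.15


@dataclass(frozen=True)
class BeamModel:
    """Gaussian excitation beam.

    ``diameter_1e2`` is the 1/e² *intensity* diameter (= 2ω₀); the intensity
    profile exp(−2r²/ω₀²) then has per-axis variance ω₀²/4.
    """

    wavelength_nm: float = 633.0
    power_mw: float = 15.0
    diameter_1e2: float = 22.0

    def __post_init__(self):
        if self.diameter_1e2 <= 0:
            raise ParameterError("beam diameter must be > 0")
        if self.power_mw < 0:
            raise ParameterError("beam power must be >= 0")

    @property
    def w0(self) -> float:
        """1/e² intensity radius ω₀, μm."""
        return self.diameter_1e2 / 2.0

    @property
    def variance(self) -> float:
        """Per-axis variance of the intensity profile, μm² (= ω₀²/4)."""
        return self.w0 ** 2 / 4.0

    def intensity(self, dx, dy) -> np.ndarray:
        """Normalized intensity exp(−2r²/ω₀²) at offsets (dx, dy) μm."""
        r2 = np.asarray(dx, float) ** 2 + np.asarray(dy, float) ** 2
        return np.exp(-2.0 * r2 / self.w0 ** 2)


# ---------------------------------------------------------------------------
# Scene generators
# ---------------------------------------------------------------------------

def make_stripe_grid(stripe_width: float, gap: float, n_stripes: int,
                     pitch: float, *, margin: float = 0.0,
                     height: float | None = None) -> AbsorberMap:
    """Vertical absorbing stripes (ink-grid pattern) on a zero background.

    Stripe centres are spaced ``stripe_width + gap`` apart.  ``margin`` adds
    empty field on all four sides; ``height`` defaults to the pattern width.
    """
    if stripe_width <= 0 or gap <= 0 or pitch <= 0 or n_stripes < 1:
        raise ParameterError("stripe_width, gap, pitch must be > 0; n_stripes >= 1")
    if pitch > stripe_width / 4:
        raise ParameterError("pitch must be <= stripe_width/4 to sample stripes")
    period = stripe_width + gap
    pattern_w = n_stripes * stripe_width + (n_stripes - 1) * gap
    width = pattern_w + 2 * margin
    if height is None:
        height = pattern_w
    n_cols = int(round(width / pitch))
    n_rows = max(1, int(round(height / pitch)))
    xc = (np.arange(n_cols) + 0.5) * pitch
    inside = np.zeros(n_cols, dtype=bool)
    centers = []
    for k in range(n_stripes):
        lo = margin + k * period
        hi = lo + stripe_width
        inside |= (xc >= lo) & (xc < hi)
        centers.append(((lo + hi) / 2.0, height / 2.0))
    values = np.zeros((n_rows, n_cols))
    values[:, inside] = 1.0
    return AbsorberMap(values=values, pitch=pitch, centers=centers)


def make_sparse_clusters(n_clusters: int, cluster_radius: float,
                         field_um: tuple[float, float], seed: int,
                         pitch: float) -> AbsorberMap:
    """Sparse absorbing disks at uniformly drawn centres.

    Emulates a sparse nanoparticle-cluster distribution in tissue.  Centres
    are drawn ``cluster_radius`` away from the field edges; overlap is
    allowed.  The drawn centres are retained as ground truth.
    """
    if pitch <= 0:
        raise ParameterError("pitch must be > 0")
    w, h = field_um
    if n_clusters > 0 and (w < 2 * cluster_radius or h < 2 * cluster_radius):
        raise ParameterError("field too small to hold a cluster")
    n_cols = int(round(w / pitch))
    n_rows = int(round(h / pitch))
    values = np.zeros((n_rows, n_cols))
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    if n_clusters > 0:
        cx = rng.uniform(cluster_radius, w - cluster_radius, size=n_clusters)
        cy = rng.uniform(cluster_radius, h - cluster_radius, size=n_clusters)
        xg = (np.arange(n_cols) + 0.5) * pitch
        yg = (np.arange(n_rows) + 0.5) * pitch
        X, Y = np.meshgrid(xg, yg)
        for x0, y0 in zip(cx, cy):
            disk = (X - x0) ** 2 + (Y - y0) ** 2 <= cluster_radius ** 2
            # guarantee the stored centre lies on an absorbing cell even for
            # sub-pitch radii
            disk[int(y0 / pitch), int(x0 / pitch)] = True
            values[disk] = 1.0
            centers.append((float(x0), float(y0)))
    return AbsorberMap(values=values, pitch=pitch, centers=centers)


def make_uniform_square(side: float, pitch: float,
                        *, margin: float | None = None) -> AbsorberMap:
    """Filled absorbing square of size ``side`` centred in a zero field.

    The square is aligned to cell boundaries so the absorbing-cell count is
    exactly ``round(side/pitch)**2``.  ``margin`` (default ``side/2`` per
    side) sets the surrounding empty border.
    """
    if pitch <= 0:
        raise ParameterError("pitch must be > 0")
    if side < pitch:
        raise ParameterError("square side must be >= pitch")
    n_sq = int(round(side / pitch))
    if margin is None:
        margin = side / 2.0
    n_margin = int(round(margin / pitch))
    n = n_sq + 2 * n_margin
    values = np.zeros((n, n))
    values[n_margin:n_margin + n_sq, n_margin:n_margin + n_sq] = 1.0
    c = n * pitch / 2.0
    return AbsorberMap(values=values, pitch=pitch, centers=[(c, c)])


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def ink_sample_model(**overrides) -> SampleModel:
    """Microfiche ink-on-film sample: ε = 0.8, film-like diffusivity."""
    params = dict(emissivity=0.8, D=1.0e5, T0=19.85, A=6.0e4, tau_d=0.2)
    params.update(overrides)
    return SampleModel(**params)


def biopsy_sample_model(**overrides) -> SampleModel:
    """Skin-biopsy sample: ε = 0.95, water-like diffusivity."""
    params = dict(emissivity=0.95, D=1.4e5, T0=19.85, A=6.0e4, tau_d=0.2)
    params.update(overrides)
    return SampleModel(**params)


def beam_56um(power_mw: float = 4.6) -> BeamModel:
    """56 μm 1/e² diameter beam (no beam reducer)."""
    return BeamModel(wavelength_nm=633.0, power_mw=power_mw, diameter_1e2=56.0)


def beam_22um(power_mw: float = 15.0) -> BeamModel:
    """22 μm 1/e² diameter beam (with the Keplerian beam reducer)."""
    return BeamModel(wavelength_nm=633.0, power_mw=power_mw, diameter_1e2=22.0)
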