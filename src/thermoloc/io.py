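"""File I/O for thermal stacks, localizations and schedules.

Stacks travel as multi-page float TIFF with a JSON sidecar carrying the
geometry (pixel pitch, frame rate, origin, baseline temperature), or as
vendor-style per-frame CSV matrices (one file per frame, lexicographically
sorted, values in °C, optional header lines skipped by count).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import PeakEvent
from .forward import ThermalStack
from .localize import Localization
from .scenes import ParameterError

__all__ = ["write_stack", "read_stack", "write_localizations",
           "read_localizations", "write_events"]

_REQUIRED_META = ("a_um", "f_rate_hz")


def write_stack(stack: ThermalStack, path: str | Path,
                extra_meta: dict | None = None) -> None:
    """Write a stack as multi-page float32 TIFF plus a JSON sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {
        "a_um": stack.a,
        "f_rate_hz": stack.f_rate,
        "origin_um": list(stack.origin),
        "T0_C": stack.T0,
        "t_start_s": float(stack.timestamps[0]),
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_stack(path: str | Path, dialect: str = "tiff",
               skip_header: int = 0, delimiter: str = ",",
               **meta_overrides) -> ThermalStack:
    """Read a thermal stack from TIFF (+sidecar) or per-frame CSV files.

    ``dialect="tiff"``: ``path`` is the multi-page TIFF written by
    :func:`write_stack`; metadata come from the sidecar, overridable by
    keyword (``a_um``, ``f_rate_hz``, ``origin_um``, ``T0_C``).

    ``dialect="csv_frames"``: ``path`` is a directory of one-frame CSV
    matrices in °C; files are sorted lexicographically, the first
    ``skip_header`` lines of each are skipped, and the required metadata
    must be supplied by keyword.
    """
    path = Path(path)
    meta: dict = {}
    if dialect == "tiff":
        import tifffile

        frames = tifffile.imread(path).astype(float)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
    elif dialect == "csv_frames":
        files = sorted(path.glob("*.csv"))
        if not files:
            raise ParameterError(f"no CSV frames found in {path}")
        mats = [np.loadtxt(f, delimiter=delimiter, skiprows=skip_header)
                for f in files]
        shapes = {m.shape for m in mats}
        if len(shapes) != 1:
            raise ParameterError(f"frame shape mismatch across CSV files: {shapes}")
        frames = np.stack(mats)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    meta.update(meta_overrides)
    missing = [k for k in _REQUIRED_META if meta.get(k) is None]
    if missing:
        raise ParameterError(
            "missing stack metadata key(s): " + ", ".join(missing))
    t0 = float(meta.get("t_start_s", 0.0))
    times = t0 + np.arange(len(frames)) / float(meta["f_rate_hz"])
    return ThermalStack(frames=frames, timestamps=times,
                        a=float(meta["a_um"]),
                        origin=tuple(meta.get("origin_um", (0.0, 0.0))),
                        T0=meta.get("T0_C"))


_LOC_COLS = ["x_c", "y_c", "sigma_x", "sigma_y", "dTmax", "zeta2", "model",
             "chi2red", "frame"]


def write_localizations(locs: list[Localization], path: str | Path) -> None:
    pd.DataFrame(
        [(l.x_c, l.y_c, l.sigma_x, l.sigma_y, l.dT_max, l.zeta2, l.model,
          l.chi2red, l.frame) for l in locs],
        columns=_LOC_COLS).to_csv(path, index=False)


def read_localizations(path: str | Path) -> list[Localization]:
    df = pd.read_csv(path)
    return [Localization(x_c=r.x_c, y_c=r.y_c, sigma_x=r.sigma_x,
                         sigma_y=r.sigma_y, dT_max=r.dTmax, zeta2=r.zeta2,
                         offset=0.0, model=r.model, chi2red=r.chi2red,
                         frame=int(r.frame))
            for r in df.itertuples()]


def write_events(events: list[PeakEvent], path: str | Path) -> None:
    pd.DataFrame(
        [(e.col, e.row, e.frame, e.time, e.amplitude, e.width)
         for e in events],
        columns=["col", "row", "frame", "time_s", "amplitude_C", "width_s"],
    ).to_csv(path, index=False)
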