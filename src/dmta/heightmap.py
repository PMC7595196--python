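"""Areal surface height maps.

A :class:`HeightMap` is a regular x/y grid of surface elevations (µm) with a
per-point validity mask.  Non-measured points (instrument dropouts, manually
masked dirt or spikes) are flagged invalid and excluded from every downstream
fit and parameter sum; they are never interpolated.

Processing stages move strictly forward::

    raw -> levelled -> form_removed -> scale_limited

``scale_limited`` is the roughness surface left after form removal and
bandwidth-limiting filtration, the input to ISO 25178-2 parameter
computation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["HeightMap", "Stage", "ParseError", "read_surface", "write_surface"]

#: Ordered processing stages.
STAGES = ("raw", "levelled", "form_removed", "scale_limited")

Stage = str


class ParseError(ValueError):
    """Raised when a surface file is malformed; message names the offending field."""


@dataclass(frozen=True)
class HeightMap:
    """Regular-grid areal surface.

    Parameters
    ----------
    heights : ndarray, shape (ny, nx)
        Elevations in µm.  Invalid points may hold NaN.
    dx, dy : float
        Sample spacing in µm along x (columns) and y (rows).
    mask : ndarray of bool, shape (ny, nx)
        True where the point was measured and is usable.
    stage : str
        One of ``raw``, ``levelled``, ``form_removed``, ``scale_limited``.
    provenance : tuple of str
        Human-readable processing history.
    """

    heights: np.ndarray
    dx: float
    dy: float
    mask: np.ndarray = None  # type: ignore[assignment]
    stage: Stage = "raw"
    provenance: tuple = field(default_factory=tuple)

    def __post_init__(self):
        h = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "heights", h)
        if h.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if self.mask is None:
            object.__setattr__(self, "mask", np.isfinite(h))
        else:
            m = np.asarray(self.mask, dtype=bool) & np.isfinite(h)
            object.__setattr__(self, "mask", m)
        if self.mask.shape != h.shape:
            raise ValueError("mask and heights must have identical dimensions")
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError("sample spacings dx, dy must be positive")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.heights.shape

    @property
    def extent_um(self) -> tuple:
        """Physical (x, y) extent in µm spanned by the grid."""
        ny, nx = self.heights.shape
        return ((nx - 1) * self.dx, (ny - 1) * self.dy)

    @property
    def valid_fraction(self) -> float:
        return float(self.mask.mean())

    def valid_heights(self) -> np.ndarray:
        return self.heights[self.mask]

    def grid_coords(self):
        """x (per column) and y (per row) coordinates in µm."""
        ny, nx = self.heights.shape
        return np.arange(nx) * self.dx, np.arange(ny) * self.dy

    # -- stage bookkeeping ------------------------------------------------
    def advance(self, new_heights: np.ndarray, stage: Stage, note: str,
                mask: np.ndarray | None = None) -> "HeightMap":
        """Return a copy at a later stage; stage transitions only move forward."""
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise ValueError(
                f"stage may only advance: {self.stage!r} -> {stage!r} not allowed")
        return replace(self, heights=np.asarray(new_heights, dtype=float),
                       mask=self.mask if mask is None else mask,
                       stage=stage, provenance=self.provenance + (note,))

    def require_stage(self, stage: Stage) -> None:
        if self.stage != stage:
            raise ValueError(f"operation requires a {stage!r} surface, got {self.stage!r}")


# ---------------------------------------------------------------------------
# File I/O
#
# ASCII grid format: header lines "nx", "ny", "dx_um", "dy_um" (key value),
# then ny rows of nx heights, row-major; NaN marks invalid points.
# SDF-style: the ASCII surface data file layout (aBCR-0 style header with
# NumPoints/NumProfiles/Xscale/Yscale/Zscale, '*'-terminated sections).
# ---------------------------------------------------------------------------

def _parse_ascii_grid(text: str, path: str) -> HeightMap:
    lines = text.splitlines()
    header: dict = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if not parts or line.lstrip().startswith("#"):
            continue
        if parts[0] in ("nx", "ny", "dx_um", "dy_um"):
            header[parts[0]] = parts[1] if len(parts) > 1 else None
        else:
            break
    for key in ("nx", "ny", "dx_um", "dy_um"):
        if key not in header or header[key] is None:
            raise ParseError(f"{path}: missing header field {key!r}")
    try:
        nx, ny = int(header["nx"]), int(header["ny"])
        dx, dy = float(header["dx_um"]), float(header["dy_um"])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric header field ({exc})") from None
    if nx <= 0 or ny <= 0:
        raise ParseError(f"{path}: grid dimensions nx/ny must be positive")
    if dx <= 0 or dy <= 0:
        raise ParseError(f"{path}: sample spacing dx_um/dy_um must be positive")
    rows = []
    for j, line in enumerate(lines[i:], start=i + 1):
        parts = line.split()
        if not parts or line.lstrip().startswith("#"):
            continue
        try:
            row = [float(v) for v in parts]
        except ValueError:
            raise ParseError(f"{path}: non-numeric height on line {j}") from None
        if len(row) != nx:
            raise ParseError(
                f"{path}: row on line {j} has {len(row)} values, expected nx={nx}")
        rows.append(row)
    if len(rows) != ny:
        raise ParseError(f"{path}: found {len(rows)} data rows, expected ny={ny}")
    heights = np.array(rows, dtype=float)
    return HeightMap(heights=heights, dx=dx, dy=dy, stage="raw",
                     provenance=(f"read ascii_grid {path}",))


def _parse_sdf(text: str, path: str) -> HeightMap:
    """ASCII SDF (surface data file): 'key = value' header, '*'-separated sections."""
    sections = text.split("*")
    if len(sections) < 2:
        raise ParseError(f"{path}: SDF file lacks a '*' header terminator")
    header: dict = {}
    for line in sections[0].splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
    def _get(key, cast):
        if key not in header:
            raise ParseError(f"{path}: missing SDF header field {key!r}")
        try:
            return cast(header[key])
        except ValueError:
            raise ParseError(f"{path}: non-numeric SDF field {key!r}") from None
    nx = _get("NumPoints", int)
    ny = _get("NumProfiles", int)
    xscale = _get("Xscale", float)   # metres per sample
    yscale = _get("Yscale", float)
    zscale = float(header.get("Zscale", "1"))
    if nx <= 0 or ny <= 0:
        raise ParseError(f"{path}: NumPoints/NumProfiles must be positive")
    if xscale <= 0 or yscale <= 0:
        raise ParseError(f"{path}: Xscale/Yscale must be positive")
    tokens = sections[1].split()
    if len(tokens) != nx * ny:
        raise ParseError(
            f"{path}: SDF data block has {len(tokens)} values, expected {nx * ny}")
    bad = header.get("InvalidPointValue")
    vals = np.empty(nx * ny)
    for k, tok in enumerate(tokens):
        if bad is not None and tok == bad:
            vals[k] = np.nan
            continue
        try:
            vals[k] = float(tok)
        except ValueError:
            raise ParseError(f"{path}: non-numeric SDF data value {tok!r}") from None
    heights = vals.reshape(ny, nx) * zscale * 1e6  # metres -> µm
    return HeightMap(heights=heights, dx=xscale * 1e6, dy=yscale * 1e6,
                     stage="raw", provenance=(f"read sdf {path}",))


def read_surface(path, format: str = "ascii_grid") -> HeightMap:
    """Read a raw-stage areal surface from disk.

    Parameters
    ----------
    path : str or Path
        File to read.
    format : {"ascii_grid", "sdf"}
        ``ascii_grid``: header lines ``nx``, ``ny``, ``dx_um``, ``dy_um``
        followed by row-major heights, ``NaN`` = invalid.
        ``sdf``: ASCII surface-data-file layout (NumPoints/NumProfiles/
        Xscale/Yscale header in metres, '*'-terminated sections).

    Non-measured points are flagged invalid in the mask, never interpolated.
    """
    text = Path(path).read_text()
    if format == "ascii_grid":
        return _parse_ascii_grid(text, str(path))
    if format == "sdf":
        return _parse_sdf(text, str(path))
    raise ValueError(f"unknown surface format {format!r}")


def write_surface(h: HeightMap, path) -> None:
    """Write a surface in the ASCII grid format with a provenance header."""
    ny, nx = h.shape
    buf = io.StringIO()
    buf.write(f"# stage: {h.stage}\n")
    for note in h.provenance:
        buf.write(f"# {note}\n")
    buf.write(f"nx {nx}\nny {ny}\ndx_um {h.dx!r}\ndy_um {h.dy!r}\n")
    out = np.where(h.mask, h.heights, np.nan)
    np.savetxt(buf, out, fmt="%.9g")
    Path(path).write_text(buf.getvalue())
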