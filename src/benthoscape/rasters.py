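"""Regular planar grids in projected metre coordinates.

A :class:`Raster` is a rectangular grid of floats with a cell size in
metres and a lower-left origin; ``NaN`` marks cells outside the analysis
mask.  Row 0 is the *northernmost* row, matching the on-disk layout of the
ESRI ASCII grid format used for text serialisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "GridSpec", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a target grid: origin (xll, yll), cell size and shape."""

    origin: tuple[float, float]
    cell_size_m: float
    ncols: int
    nrows: int

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def n_cells(self) -> int:
        return self.ncols * self.nrows

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (nrows, ncols); row 0 is northernmost."""
        x0, y0 = self.origin
        c = self.cell_size_m
        xs = x0 + (np.arange(self.ncols) + 0.5) * c
        ys = y0 + (self.nrows - np.arange(self.nrows) - 0.5) * c
        return np.meshgrid(xs, ys)

    def empty(self) -> "Raster":
        return Raster(np.full((self.nrows, self.ncols), np.nan),
                      self.cell_size_m, self.origin)


@dataclass
class Raster:
    """2-D grid of reals; NaN = outside mask; origin is the lower-left corner."""

    values: np.ndarray
    cell_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")

    @property
    def spec(self) -> GridSpec:
        nr, nc = self.values.shape
        return GridSpec(tuple(self.origin), self.cell_size_m, nc, nr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        return self.spec.cell_centres()

    def finite_values(self) -> np.ndarray:
        v = self.values.ravel()
        return v[np.isfinite(v)]

    def copy_with(self, values: np.ndarray) -> "Raster":
        if values.shape != self.values.shape:
            raise ValueError("replacement values must match raster shape")
        return Raster(np.asarray(values, dtype=float), self.cell_size_m,
                      self.origin)


def write_ascii_grid(raster: Raster, path: str | Path,
                     nodata: float = -9999.0) -> None:
    """Write a raster as an ESRI ASCII grid (plain text)."""
    nr, nc = raster.values.shape
    vals = np.where(np.isfinite(raster.values), raster.values, nodata)
    header = (
        f"ncols {nc}\n"
        f"nrows {nr}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.cell_size_m:.6f}\n"
        f"NODATA_value {nodata:g}\n"
    )
    body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in vals)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid missing header field {key!r}")
    nodata = header.get("nodata_value", -9999.0)
    body = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    if body.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"ASCII grid body shape {body.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})")
    body[body == nodata] = np.nan
    return Raster(body, header["cellsize"],
                  (header["xllcorner"], header["yllcorner"]))
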