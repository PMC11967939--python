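"""Patch delineation and landscape metrics on kriged coverage surfaces.

A predicted-coverage raster is thresholded (default 0.2 proportional
coverage — with five substratum classes, 0.2 is the level above which a
class is more than proportionally represented) and the above-threshold
cells are aggregated into connected patches.  Per patch we report area,
perimeter, the perimeter-to-area ratio (RPA) and a perimeter-area fractal
dimension index (FDI) measuring edge complexity.  Because kriged layers
are per-class mixtures rather than exclusive classifications, patches of
different substrata may overlap; layers are processed independently and
never merged.

Diversity hotspots are the cells above the upper-quantile threshold of a
kriged inverse-Simpson surface (default: the upper 20%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as _sk_label

from .rasters import Raster

__all__ = ["PatchSet", "threshold_patches", "patch_metrics", "hotspot_mask"]


@dataclass
class PatchSet:
    """Labelled connected patches of a thresholded raster.

    ``labels`` is an integer grid (0 = background, patches numbered
    1..n_patches); ``table`` holds one row per patch with n_cells, area
    and perimeter in both cell units and metres, rpa and fdi (cell units,
    the primary convention for these shape indices).
    """

    labels: np.ndarray
    table: pd.DataFrame
    threshold: float
    connectivity: int
    cell_size_m: float

    @property
    def n_patches(self) -> int:
        return int(self.labels.max())


def _perimeter_edges(mask: np.ndarray) -> int:
    """Count cell edges adjacent to background or the grid boundary."""
    m = np.pad(mask, 1, constant_values=False)
    edges = 0
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        edges += int(np.sum(m & ~np.roll(m, shift, axis=(0, 1))))
    return edges


def patch_metrics(mask: np.ndarray, cell_size_m: float = 1.0,
                  ) -> tuple[float, float, float, float]:
    """(area, perimeter, rpa, fdi) of one patch, in cell units.

    area = n cells; perimeter = exposed cell edges; rpa = perimeter/area;
    fdi = 2 ln(0.25 perimeter) / ln(area), the perimeter-area fractal
    dimension (1 for squares, approaching 2 for maximally convoluted
    patches), defined as 1 for single-cell patches.  ``cell_size_m``
    scales only the metric-unit variants reported elsewhere; the returned
    tuple is in cell units.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("patch is empty")
    perim = _perimeter_edges(mask)
    area = float(n)
    rpa = perim / area
    fdi = 1.0 if n == 1 else 2.0 * np.log(0.25 * perim) / np.log(area)
    return area, float(perim), rpa, float(fdi)


def threshold_patches(raster: Raster | np.ndarray, threshold: float = 0.2,
                      connectivity: int = 8) -> PatchSet:
    """Label connected above-threshold patches and compute their metrics.

    Cells with value > ``threshold`` form the patch mask (NaN cells are
    background); connected components are labelled under 4- or
    8-connectivity (default 8, the usual landscape-metrics convention:
    diagonal neighbours join).
    """
    if isinstance(raster, Raster):
        values, cell = raster.values, raster.cell_size_m
    else:
        values, cell = np.asarray(raster, dtype=float), 1.0
    if values.size == 0:
        raise ValueError("empty raster")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.where(np.isfinite(values), values > threshold, False)
    labels = _sk_label(mask, connectivity=1 if connectivity == 4 else 2)
    rows = []
    for pid in range(1, labels.max() + 1):
        pmask = labels == pid
        area_c, perim_c, rpa, fdi = patch_metrics(pmask)
        rows.append({
            "patch_id": pid,
            "n_cells": int(area_c),
            "area_cells": area_c,
            "perimeter_cells": perim_c,
            "area_m2": area_c * cell ** 2,
            "perimeter_m": perim_c * cell,
            "rpa": rpa,
            "fdi": fdi,
        })
    cols = ["patch_id", "n_cells", "area_cells", "perimeter_cells",
            "area_m2", "perimeter_m", "rpa", "fdi"]
    table = pd.DataFrame(rows, columns=cols)
    return PatchSet(labels, table, threshold, connectivity, cell)


def hotspot_mask(diversity_raster: Raster | np.ndarray,
                 upper_fraction: float = 0.2,
                 ) -> tuple[np.ndarray, float]:
    """Mask of cells in the upper ``upper_fraction`` of predicted diversity.

    The threshold is the empirical quantile at (1 - upper_fraction) over
    finite cells, with the linear-interpolation quantile definition; the
    mask selects cells strictly above it.  A constant raster yields an
    empty mask (with a warning).
    """
    values = diversity_raster.values if isinstance(diversity_raster, Raster) \
        else np.asarray(diversity_raster, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("raster has no finite cells")
    if not 0.0 < upper_fraction < 1.0:
        raise ValueError("upper_fraction must be in (0, 1)")
    thresh = float(np.quantile(finite, 1.0 - upper_fraction))
    mask = np.where(np.isfinite(values), values > thresh, False)
    if not mask.any():
        warnings.warn("constant or degenerate raster: empty hotspot mask",
                      stacklevel=2)
    return mask, thresh
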