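"""Proportional substratum coverage from gridded image annotations.

Each survey station contributes one seabed still image overlaid with a
10 x 10 grid; an annotator records the majority substratum of every cell,
or ``unknown`` where the image is obscured.  This module turns those cell
labels into a per-station composition over the five analysis classes
(algae, gravel, mud, sand, pebble), merging the sparse raw classes first
(maerl into gravel, seagrass into sand, boulder into pebble, all algal
types into algae) and excluding unknown cells from the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RAW_CLASSES", "ANALYSIS_CLASSES", "DEFAULT_MERGE_MAP", "UNKNOWN",
    "CellAnnotation", "CoverageProfile", "merge_classes",
    "profile_from_annotation", "annotations_from_long",
    "annotations_from_wide", "profiles_to_frame",
]

UNKNOWN = "unknown"

#: Raw annotation vocabulary (substratum classes an annotator may record).
RAW_CLASSES = ("algae", "seagrass", "maerl", "gravel", "mud", "sand",
               "boulder", "pebble", UNKNOWN)

#: The five analysis classes retained after merging sparse raw classes.
ANALYSIS_CLASSES = ("algae", "gravel", "mud", "sand", "pebble")

#: Default merge: maerl (live or dead) -> gravel, seagrass -> sand,
#: boulder -> pebble; the five analysis classes map to themselves.
DEFAULT_MERGE_MAP: dict[str, str] = {
    "algae": "algae",
    "seagrass": "sand",
    "maerl": "gravel",
    "gravel": "gravel",
    "mud": "mud",
    "sand": "sand",
    "boulder": "pebble",
    "pebble": "pebble",
    UNKNOWN: UNKNOWN,
}

GRID_SHAPE = (10, 10)
N_CELLS = GRID_SHAPE[0] * GRID_SHAPE[1]


def merge_classes(raw_label: str,
                  merge_map: Mapping[str, str] | None = None) -> str:
    """Map a raw annotation label to its analysis class.

    Parameters
    ----------
    raw_label
        Label recorded by the annotator.
    merge_map
        Optional replacement for :data:`DEFAULT_MERGE_MAP`; must map every
        accepted raw label (including ``unknown``) to an analysis class or
        ``unknown``.

    Raises
    ------
    ValueError
        If ``raw_label`` is not in the merge map's vocabulary.
    """
    mapping = DEFAULT_MERGE_MAP if merge_map is None else merge_map
    try:
        return mapping[raw_label]
    except KeyError:
        raise ValueError(
            f"unrecognised substratum label {raw_label!r}; expected one of "
            f"{sorted(mapping)}") from None


@dataclass
class CellAnnotation:
    """A station's 10 x 10 grid of majority-substratum cell labels."""

    station_id: str
    cells: np.ndarray
    merge_map: Mapping[str, str] = field(default_factory=lambda: DEFAULT_MERGE_MAP)

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=object)
        if cells.size != N_CELLS:
            raise ValueError(
                f"station {self.station_id!r}: expected {N_CELLS} cells, "
                f"got {cells.size}")
        self.cells = cells.reshape(GRID_SHAPE)
        bad = sorted({c for c in self.cells.ravel() if c not in self.merge_map})
        if bad:
            raise ValueError(
                f"station {self.station_id!r}: unrecognised labels {bad}")


@dataclass
class CoverageProfile:
    """Proportions of the five analysis classes at one station.

    ``proportions`` sums to 1 when any cell was identifiable;
    ``n_known_cells`` counts cells that were not ``unknown``.  ``flagged``
    marks stations whose identifiable-cell count fell below the configured
    minimum (they are retained, not dropped).
    """

    station_id: str
    proportions: dict[str, float]
    n_known_cells: int
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.n_known_cells > 0:
            total = sum(self.proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"station {self.station_id!r}: proportions sum to "
                    f"{total}, not 1")
        for k, v in self.proportions.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"station {self.station_id!r}: proportion {k}={v} "
                    "outside [0, 1]")

    def as_array(self, classes: Iterable[str] = ANALYSIS_CLASSES) -> np.ndarray:
        return np.array([self.proportions.get(c, 0.0) for c in classes])


def profile_from_annotation(annotation: CellAnnotation,
                            min_known_cells: int = 50) -> CoverageProfile:
    """Convert cell labels into a proportional coverage profile.

    Unknown cells are excluded from the denominator; the remaining cells
    are merged to analysis classes and counted.  A station with no
    identifiable cell has no defined composition and is rejected.
    """
    labels = [merge_classes(c, annotation.merge_map)
              for c in annotation.cells.ravel()]
    known = [c for c in labels if c != UNKNOWN]
    n_known = len(known)
    if n_known == 0:
        raise ValueError(
            f"station {annotation.station_id!r}: all cells unknown, "
            "no usable cells")
    props = {c: known.count(c) / n_known for c in ANALYSIS_CLASSES}
    flagged = n_known < min_known_cells
    if flagged:
        warnings.warn(
            f"station {annotation.station_id!r}: only {n_known} identifiable "
            f"cells (< {min_known_cells})", stacklevel=2)
    return CoverageProfile(annotation.station_id, props, n_known, flagged)


def annotations_from_long(table: pd.DataFrame,
                          merge_map: Mapping[str, str] | None = None,
                          ) -> list[CellAnnotation]:
    """Build annotations from a long table (station_id, row, col, label)."""
    required = {"station_id", "row", "col", "label"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"long annotation table missing columns {sorted(missing)}")
    mapping = DEFAULT_MERGE_MAP if merge_map is None else merge_map
    out = []
    for sid, grp in table.groupby("station_id", sort=True):
        cells = np.full(GRID_SHAPE, None, dtype=object)
        for _, r in grp.iterrows():
            cells[int(r["row"]), int(r["col"])] = str(r["label"])
        if (cells == None).any():  # noqa: E711 - elementwise object compare
            raise ValueError(f"station {sid!r}: incomplete 10x10 grid")
        out.append(CellAnnotation(str(sid), cells, mapping))
    return out


def annotations_from_wide(table: pd.DataFrame,
                          merge_map: Mapping[str, str] | None = None,
                          ) -> list[CellAnnotation]:
    """Build annotations from a wide table: station_id + 100 cell columns."""
    if "station_id" not in table.columns:
        raise ValueError("wide annotation table missing 'station_id'")
    cell_cols = [c for c in table.columns if c != "station_id"]
    if len(cell_cols) != N_CELLS:
        raise ValueError(
            f"wide annotation table needs {N_CELLS} cell columns, "
            f"got {len(cell_cols)}")
    mapping = DEFAULT_MERGE_MAP if merge_map is None else merge_map
    return [CellAnnotation(str(r["station_id"]),
                           r[cell_cols].to_numpy(dtype=object), mapping)
            for _, r in table.iterrows()]


def profiles_to_frame(profiles: Iterable[CoverageProfile],
                      coords: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabulate profiles (station_id, x, y, five classes, n_known_cells).

    ``coords`` is an optional frame with station_id, x, y to merge in.
    """
    rows = [{"station_id": p.station_id,
             **{c: p.proportions.get(c, 0.0) for c in ANALYSIS_CLASSES},
             "n_known_cells": p.n_known_cells}
            for p in profiles]
    frame = pd.DataFrame(rows)
    if coords is not None:
        frame = coords[["station_id", "x", "y"]].merge(frame, on="station_id",
                                                       how="right")
    cols = ["station_id"] + (["x", "y"] if coords is not None else []) \
        + list(ANALYSIS_CLASSES) + ["n_known_cells"]
    return frame[cols]
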