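"""Readers/writers for the pipeline's delimited-text and geometry formats.

Coordinates must arrive already projected to a metric CRS: kriging
distances, the 500 m station-separation rule and the 500 m zonal grid are
all metric, so geodesy stays at the boundary of the package and never
enters the compute modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape

from .coverage import ANALYSIS_CLASSES
from .zonal import ZonePolygon

__all__ = ["read_station_table", "write_station_table",
           "read_species_table", "read_zones", "RunConfig"]

_STATION_COLS = ["station_id", "x", "y", *ANALYSIS_CLASSES]


def read_station_table(path: str | Path, renorm_tol: float = 1e-6,
                       ) -> pd.DataFrame:
    """Read and validate a station profile table.

    Requires station_id, x, y and the five substratum-class columns;
    proportions are renormalised when within ``renorm_tol`` of summing to
    one and rejected otherwise, with the offending rows named.
    """
    table = pd.read_csv(path)
    missing = set(_STATION_COLS) - set(table.columns)
    if missing:
        raise ValueError(
            f"station table {path} missing columns {sorted(missing)}")
    for col in ("x", "y", *ANALYSIS_CLASSES):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.isna()].tolist()
        if bad:
            raise ValueError(
                f"station table {path}: non-numeric {col!r} in rows {bad}")
        table[col] = vals
    props = table[list(ANALYSIS_CLASSES)].to_numpy(dtype=float)
    if (props < 0).any() or (props > 1).any():
        bad = np.unique(np.where((props < 0) | (props > 1))[0]).tolist()
        raise ValueError(
            f"station table {path}: proportions outside [0, 1] in rows {bad}")
    totals = props.sum(axis=1)
    off = np.abs(totals - 1.0) > renorm_tol
    if off.any():
        raise ValueError(
            f"station table {path}: proportions off the simplex in rows "
            f"{np.where(off)[0].tolist()} (sums "
            f"{np.round(totals[off], 6).tolist()})")
    table[list(ANALYSIS_CLASSES)] = props / totals[:, None]
    if table["station_id"].duplicated().any():
        dups = table.loc[table["station_id"].duplicated(),
                         "station_id"].tolist()
        raise ValueError(f"station table {path}: duplicate ids {dups}")
    return table


def write_station_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.12g")


def read_species_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format species table (station_id, species, maxn)."""
    table = pd.read_csv(path)
    missing = {"station_id", "species", "maxn"} - set(table.columns)
    if missing:
        raise ValueError(
            f"species table {path} missing columns {sorted(missing)}")
    table["maxn"] = pd.to_numeric(table["maxn"], errors="raise")
    if (table["maxn"] < 0).any():
        raise ValueError(f"species table {path}: negative MaxN values")
    return table


def read_zones(path: str | Path) -> list[ZonePolygon]:
    """Read management-zone polygons from a GeoJSON FeatureCollection."""
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    zones = []
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties", {}) or {}
        zone_id = str(props.get("zone_id", f"zone_{i}"))
        rc = str(props.get("restriction_class", "none"))
        zones.append(ZonePolygon(zone_id, rc, shape(feat["geometry"])))
    if not zones:
        raise ValueError(f"{path}: no zone features found")
    return zones


@dataclass
class RunConfig:
    """Configuration for an end-to-end pipeline run.

    Defaults follow the mapping constants used throughout the package: a
    0.2 proportional-coverage patch threshold, the upper-20% diversity
    hotspot rule, a 500 m zonal grid and 5-fold cross-validation.
    """

    station_table: str = "stations.csv"
    species_table: str | None = "species.csv"
    zones_file: str | None = "zones.geojson"
    outdir: str = "benthoscape_out"
    grid_origin: tuple[float, float] | None = None
    grid_cell_size_m: float = 200.0
    grid_ncols: int | None = None
    grid_nrows: int | None = None
    threshold: float = 0.2
    hotspot_fraction: float = 0.2
    grid_size_m: float = 500.0
    connectivity: int = 8
    k_folds: int = 5
    cutoff: float | None = None
    n_bins: int = 15
    seed: int = 0
    families: tuple[str, ...] = ("spherical", "exponential", "gaussian")

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if not 0.0 < self.hotspot_fraction < 1.0:
            raise ValueError("hotspot_fraction must be in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "grid_origin" in raw and raw["grid_origin"] is not None:
            raw["grid_origin"] = tuple(raw["grid_origin"])
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dict(self.__dict__)
        d["families"] = list(self.families)
        if self.grid_origin is not None:
            d["grid_origin"] = list(self.grid_origin)
        return d
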