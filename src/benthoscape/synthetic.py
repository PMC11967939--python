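"""Synthetic video surveys with known ground truth.

Real benthic video surveys leave no deposited raster truth to validate
against, so every stage of the pipeline is exercised on simulated surveys
whose generating process is fully known:

1. one zero-mean Gaussian random field per substratum class, simulated by
   dense covariance factorisation with the same variogram families the
   kriging module fits (C(h) = sill - gamma(h));
2. a softmax link turning the K fields into a per-cell composition on the
   simplex (spatially smooth, strictly positive, summing to one);
3. station locations drawn by rejection sampling with a minimum pairwise
   separation of 500 m, emulating the survey design rule that camera
   deployments sit more than 500 m apart;
4. a 10 x 10 grid of cell annotations per station, each cell independently
   `unknown` with a fixed rate or else a class drawn from the station's
   true composition (the forward model of majority-rule image annotation);
5. species MaxN counts whose expected inverse-Simpson diversity increases
   with the local substratum mixture (and a per-zone additive offset),
   encoding "mixed seabed carries more effective species" as a
   controllable ground truth.

Default parameters are the package's study conditions: a 10 km x 10 km
domain on a 50 x 50 grid (200 m cells), 150 stations, unknown rate 0.1,
a 20-species pool, coupling 0.75 and a quadrant zone layout with
restriction classes BT / TND / DTDC / NTZ and diversity offsets
0 / 0.5 / 0.5 / 1.0.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.distance import cdist, pdist, squareform
from shapely.geometry import box, mapping

from .coverage import (ANALYSIS_CLASSES, CellAnnotation, CoverageProfile,
                       GRID_SHAPE, N_CELLS, UNKNOWN,
                       profile_from_annotation)
from .geostat import VariogramModel
from .rasters import GridSpec, Raster, write_ascii_grid
from .zonal import ZonePolygon, assign_zones

__all__ = [
    "SimulationConfig", "SurveyBundle", "simulate_grf",
    "fields_to_composition", "sample_stations", "observe_coverage",
    "simulate_species", "simulate_survey", "write_bundle",
    "default_variograms", "default_zone_layout",
]

_MAX_DENSE_CELLS = 10_000


def default_variograms() -> dict[str, VariogramModel]:
    """Per-class field variograms: algae patchy at short range, sand and
    mud smooth and extensive, gravel and pebble intermediate."""
    return {
        "algae": VariogramModel("spherical", 0.05, 1.0, 800.0),
        "gravel": VariogramModel("spherical", 0.05, 1.0, 1500.0),
        "mud": VariogramModel("spherical", 0.05, 1.0, 2500.0),
        "sand": VariogramModel("spherical", 0.05, 1.0, 2500.0),
        "pebble": VariogramModel("spherical", 0.05, 1.0, 1200.0),
    }


def default_zone_layout(extent: tuple[float, float, float, float],
                        offsets: Mapping[str, float] | None = None,
                        ) -> tuple[list[ZonePolygon], dict[str, float]]:
    """Quadrant management zones with per-zone diversity offsets.

    The domain splits into four rectangles labelled BT, TND, DTDC, NTZ
    (increasingly restrictive), with default diversity offsets
    {BT: 0.0, TND: 0.5, DTDC: 0.5, NTZ: 1.0}.
    """
    x0, x1, y0, y1 = extent
    xm, ym = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    zones = [
        ZonePolygon("BT", "BT", box(x0, y0, xm, ym)),
        ZonePolygon("TND", "TND", box(xm, y0, x1, ym)),
        ZonePolygon("DTDC", "DTDC", box(x0, ym, xm, y1)),
        ZonePolygon("NTZ", "NTZ", box(xm, ym, x1, y1)),
    ]
    if offsets is None:
        offsets = {"BT": 0.0, "TND": 0.5, "DTDC": 0.5, "NTZ": 1.0}
    missing = {z.zone_id for z in zones} - set(offsets)
    if missing:
        raise ValueError(f"no diversity offset for zones {sorted(missing)}")
    return zones, dict(offsets)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic survey."""

    extent: tuple[float, float, float, float] = (0.0, 10_000.0, 0.0, 10_000.0)
    cell_size_m: float = 200.0
    variograms: dict[str, VariogramModel] = field(
        default_factory=default_variograms)
    temperature: float = 1.0
    n_stations: int = 150
    min_separation_m: float = 500.0
    n_grid_cells: int = N_CELLS
    unknown_rate: float = 0.1
    species_pool: int = 20
    coupling: float = 0.75
    total_maxn_mean: float = 60.0
    zone_offsets: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        x0, x1, y0, y1 = self.extent
        if x1 <= x0 or y1 <= y0 or self.cell_size_m <= 0:
            raise ValueError("invalid extent or cell size")
        if not 0.0 <= self.unknown_rate < 1.0:
            raise ValueError("unknown_rate must be in [0, 1)")
        if self.temperature <= 0:
            raise ValueError("softmax temperature must be positive")

    @property
    def grid(self) -> GridSpec:
        x0, x1, y0, y1 = self.extent
        nc = int(round((x1 - x0) / self.cell_size_m))
        nr = int(round((y1 - y0) / self.cell_size_m))
        return GridSpec((x0, y0), self.cell_size_m, nc, nr)

    def to_jsonable(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "variograms"}
        d["extent"] = list(self.extent)
        d["variograms"] = {k: vars(v) for k, v in self.variograms.items()}
        return d


# Cholesky factors are expensive for desk-scale grids; identical
# (model, coordinates) requests recur across replicates, so cache them.
_CHOL_CACHE: dict[tuple, np.ndarray] = {}


def _cholesky_for(points: np.ndarray, model: VariogramModel) -> np.ndarray:
    key = (model.family, model.nugget, model.partial_sill, model.range_m,
           hashlib.sha1(np.ascontiguousarray(points).tobytes()).hexdigest())
    fac = _CHOL_CACHE.get(key)
    if fac is None:
        d = squareform(pdist(points))
        cov = model.covariance(d)
        np.fill_diagonal(cov, model.sill)
        jitter = 1e-10 * max(model.sill, 1.0)
        for _ in range(3):
            try:
                fac = np.linalg.cholesky(cov + jitter * np.eye(len(points)))
                break
            except np.linalg.LinAlgError:
                jitter *= 100.0
        else:
            raise np.linalg.LinAlgError(
                "covariance not positive definite even after jitter")
        if len(_CHOL_CACHE) > 16:
            _CHOL_CACHE.clear()
        _CHOL_CACHE[key] = fac
    return fac


def simulate_grf(grid: GridSpec | np.ndarray, model: VariogramModel,
                 seed: int | np.random.Generator = 0,
                 ) -> Raster | np.ndarray:
    """Zero-mean Gaussian random field with covariance sill - gamma(h).

    ``grid`` is either a :class:`GridSpec` (returns a Raster) or an
    (n, 2) array of point coordinates (returns a value array).  Dense
    Cholesky factorisation: guarded to <= 10^4 locations.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if isinstance(grid, GridSpec):
        X, Y = grid.cell_centres()
        pts = np.column_stack([X.ravel(), Y.ravel()])
    else:
        pts = np.asarray(grid, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("grid must be a GridSpec or an (n, 2) array")
    if len(pts) > _MAX_DENSE_CELLS:
        raise ValueError(
            f"{len(pts)} cells exceeds the dense-factorisation guard "
            f"({_MAX_DENSE_CELLS}); use a coarser grid")
    fac = _cholesky_for(pts, model)
    z = fac @ rng.standard_normal(len(pts))
    if isinstance(grid, GridSpec):
        return Raster(z.reshape(grid.nrows, grid.ncols), grid.cell_size_m,
                      grid.origin)
    return z


def fields_to_composition(fields: Mapping[str, np.ndarray],
                          temperature: float = 1.0,
                          ) -> dict[str, np.ndarray]:
    """Softmax link: p_k = exp(f_k / tau) / sum_j exp(f_j / tau) per cell.

    Guarantees simplex-valued, strictly positive compositions that vary
    smoothly wherever the fields do; small tau sharpens toward one-hot.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    names = list(fields)
    if len(names) < 2:
        raise ValueError("need at least 2 substratum fields")
    stack = np.stack([np.asarray(fields[k], dtype=float) for k in names])
    stack = stack / temperature
    stack -= stack.max(axis=0, keepdims=True)
    e = np.exp(stack)
    e /= e.sum(axis=0, keepdims=True)
    return {k: e[i] for i, k in enumerate(names)}


def sample_stations(extent: tuple[float, float, float, float], n: int,
                    min_separation_m: float = 500.0,
                    seed: int | np.random.Generator = 0,
                    max_rejections: int = 100_000) -> np.ndarray:
    """Uniform random station layout with a minimum pairwise separation.

    Rejection sampling; an area heuristic rejects upfront configurations
    whose disc packing cannot plausibly fit the domain.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    x0, x1, y0, y1 = extent
    area = (x1 - x0) * (y1 - y0)
    if n < 1:
        raise ValueError("need n >= 1 stations")
    disc_area = n * np.pi * (min_separation_m / 2.0) ** 2
    if n > 1 and disc_area > 0.6 * area:
        raise ValueError(
            f"{n} stations at {min_separation_m} m separation cannot "
            f"plausibly fit a {area / 1e6:.1f} km^2 domain; reduce n or "
            "the separation")
    pts = np.empty((n, 2))
    count = 0
    rejections = 0
    while count < n:
        cand = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
        if count == 0 or min_separation_m <= 0 or \
                np.min(np.hypot(*(pts[:count] - cand).T)) >= min_separation_m:
            pts[count] = cand
            count += 1
            rejections = 0
        else:
            rejections += 1
            if rejections > max_rejections:
                raise RuntimeError(
                    f"placed {count}/{n} stations before exceeding "
                    f"{max_rejections} consecutive rejections; try fewer "
                    "points or a smaller separation")
    return pts


def observe_coverage(true_proportions: Mapping[str, float] | np.ndarray,
                     n_cells: int = N_CELLS, unknown_rate: float = 0.0,
                     seed: int | np.random.Generator = 0,
                     station_id: str = "synthetic") -> CellAnnotation:
    """Forward model of the 10 x 10 majority-rule image annotation.

    Each cell is independently ``unknown`` with probability
    ``unknown_rate``, otherwise a class drawn from the station's true
    composition.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if n_cells != N_CELLS:
        raise ValueError(f"annotation grid is fixed at {N_CELLS} cells")
    p = np.asarray([true_proportions[c] for c in ANALYSIS_CLASSES]
                   if isinstance(true_proportions, Mapping)
                   else true_proportions, dtype=float)
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("true proportions must lie on the simplex")
    classes = np.array(ANALYSIS_CLASSES, dtype=object)
    labels = classes[rng.choice(len(classes), size=n_cells, p=p)]
    if unknown_rate > 0:
        labels[rng.random(n_cells) < unknown_rate] = UNKNOWN
    return CellAnnotation(station_id, labels.reshape(GRID_SHAPE))


def _geometric_abundances(target_d: float, pool: int) -> np.ndarray:
    """Relative abundances p_i ~ k(1-k)^(i-1) (geometric species-abundance
    series) with k chosen so the inverse Simpson of the series is
    ``target_d``."""
    if target_d < 1.0 - 1e-9:
        raise ValueError(f"target diversity {target_d} < 1 is impossible")
    if target_d <= 1.0 + 1e-9:
        out = np.zeros(pool)
        out[0] = 1.0
        return out
    if target_d >= pool - 1e-9:
        return np.full(pool, 1.0 / pool)

    def simpson_gap(k: float) -> float:
        p = k * (1.0 - k) ** np.arange(pool)
        p /= p.sum()
        return 1.0 / np.sum(p ** 2) - target_d

    k = brentq(simpson_gap, 1e-9, 1.0 - 1e-9)
    p = k * (1.0 - k) ** np.arange(pool)
    return p / p.sum()


def simulate_species(coverage: CoverageProfile | Mapping[str, float],
                     zone_offset: float = 0.0, coupling: float = 0.75,
                     pool: int = 20,
                     seed: int | np.random.Generator = 0,
                     total_maxn_mean: float = 60.0) -> dict[str, int]:
    """Species MaxN counts whose diversity tracks the substratum mixture.

    The target effective species number is D* = 1 + coupling * E_sub +
    zone_offset, with E_sub the inverse-Simpson evenness of the substratum
    proportions (1 for a pure station, up to 5 for a perfectly even one).
    Abundances follow a geometric series tuned so the plug-in inverse
    Simpson has expectation ~ D*; integer MaxN values arise by Poisson
    thinning of the expected per-species counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    props = coverage.proportions if isinstance(coverage, CoverageProfile) \
        else coverage
    p = np.asarray([props.get(c, 0.0) for c in ANALYSIS_CLASSES], dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("coverage proportions must sum to 1")
    e_sub = 1.0 / np.sum((p / p.sum()) ** 2)
    target_d = 1.0 + coupling * e_sub + zone_offset
    if target_d < 1.0:
        raise ValueError(f"target diversity {target_d} < 1 (check coupling "
                         "and zone offsets)")
    target_d = min(target_d, pool - 1e-6)
    abund = _geometric_abundances(target_d, pool)
    counts = rng.poisson(total_maxn_mean * abund)
    if counts.sum() == 0:
        counts[int(np.argmax(abund))] = 1  # guarantee an observation
    return {f"sp_{i + 1:02d}": int(c) for i, c in enumerate(counts) if c > 0}


@dataclass
class SurveyBundle:
    """Everything a pipeline run needs, plus the generating truth."""

    config: SimulationConfig
    stations: pd.DataFrame
    annotations: list[CellAnnotation]
    species: pd.DataFrame
    zones: list[ZonePolygon]
    zone_offsets: dict[str, float]
    true_composition: dict[str, Raster]
    true_fields: dict[str, Raster]


def simulate_survey(config: SimulationConfig | None = None,
                    seed: int | None = None) -> SurveyBundle:
    """Generate a complete synthetic survey under the study conditions."""
    cfg = config if config is not None else SimulationConfig()
    if seed is not None:
        cfg = SimulationConfig(**{**cfg.__dict__, "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid
    fields = {c: simulate_grf(grid, m, rng)
              for c, m in cfg.variograms.items()}
    comp = fields_to_composition({c: r.values for c, r in fields.items()},
                                 cfg.temperature)
    comp_rasters = {c: fields[c].copy_with(v) for c, v in comp.items()}

    pts = sample_stations(cfg.extent, cfg.n_stations, cfg.min_separation_m,
                          rng)
    zones, offsets = default_zone_layout(cfg.extent, cfg.zone_offsets)
    zone_labels = assign_zones(pts[:, 0], pts[:, 1], zones)

    X, Y = grid.cell_centres()
    centres = np.column_stack([X.ravel(), Y.ravel()])
    nearest = np.argmin(cdist(pts, centres), axis=1)

    annotations, station_rows, species_rows = [], [], []
    for i, (xy, zl) in enumerate(zip(pts, zone_labels)):
        sid = f"st_{i + 1:03d}"
        true_p = {c: float(comp[c].ravel()[nearest[i]])
                  for c in cfg.variograms}
        ann = observe_coverage(true_p, unknown_rate=cfg.unknown_rate,
                               seed=rng, station_id=sid)
        annotations.append(ann)
        profile = profile_from_annotation(ann)
        counts = simulate_species(
            profile, zone_offset=offsets.get(zl, 0.0),
            coupling=cfg.coupling, pool=cfg.species_pool, seed=rng,
            total_maxn_mean=cfg.total_maxn_mean)
        for sp, c in counts.items():
            species_rows.append({"station_id": sid, "species": sp,
                                 "maxn": c})
        station_rows.append({
            "station_id": sid, "x": float(xy[0]), "y": float(xy[1]),
            "zone": zl,
            **{c: profile.proportions[c] for c in ANALYSIS_CLASSES},
            "n_known_cells": profile.n_known_cells,
            **{f"true_{c}": true_p[c] for c in cfg.variograms},
        })
    return SurveyBundle(
        config=cfg,
        stations=pd.DataFrame(station_rows),
        annotations=annotations,
        species=pd.DataFrame(species_rows),
        zones=zones,
        zone_offsets=offsets,
        true_composition=comp_rasters,
        true_fields=fields,
    )


def write_bundle(bundle: SurveyBundle, outdir: str | Path) -> Path:
    """Write a survey bundle in the formats the pipeline reads.

    Emits stations.csv, species.csv, zones.geojson, true_<class>.asc
    ground-truth rasters and a manifest.json recording config and seed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.stations.to_csv(out / "stations.csv", index=False,
                           float_format="%.10g")
    bundle.species.to_csv(out / "species.csv", index=False)
    features = [{"type": "Feature",
                 "properties": {"zone_id": z.zone_id,
                                "restriction_class": z.restriction_class,
                                "diversity_offset":
                                    bundle.zone_offsets.get(z.zone_id, 0.0)},
                 "geometry": mapping(z.geometry)} for z in bundle.zones]
    (out / "zones.geojson").write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))
    for c, r in bundle.true_composition.items():
        write_ascii_grid(r, out / f"true_{c}.asc")
    manifest = {"config": bundle.config.to_jsonable(),
                "n_stations": len(bundle.stations),
                "files": sorted(p.name for p in out.iterdir())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return out
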