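"""End-to-end run: coverage tables -> kriged surfaces -> patches -> zones.

`run_pipeline` executes the full mapping workflow on a station profile
table (plus optional species table and zone polygons):

1. per-substratum ordinary kriging with standard errors and k-fold
   cross-validation (predictions clamped to [0, 1]; classes are kriged
   independently and never renormalised across classes, because kriged
   layers are per-class mixtures, not an exclusive classification);
2. inverse-Simpson diversity per station, kriged the same way;
3. patch delineation at the coverage threshold with landscape metrics,
   and the upper-quantile diversity hotspot mask;
4. 500 m zonal aggregation with zone labels and rank-based comparisons
   (diversity across modal substrata; diversity across zones at both the
   station and grid-square pathway).

Every stage failure is re-raised naming the stage; outputs written so far
are preserved.  A manifest records config, seed and the fitted variogram
parameters, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coverage import ANALYSIS_CLASSES
from .diversity import diversity_table
from .geostat import OrdinaryKriging, cross_validate
from .io import (RunConfig, read_species_table, read_station_table,
                 read_zones)
from .landscape import hotspot_mask, threshold_patches
from .rasters import GridSpec, Raster, write_ascii_grid
from .zonal import (assign_zones, compare_groups, grid_aggregate_many,
                    modal_substratum)

__all__ = ["run_pipeline", "PipelineResult", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineResult:
    outdir: Path
    stations: pd.DataFrame
    predictions: dict[str, Raster]
    standard_errors: dict[str, Raster]
    variograms: dict[str, dict]
    cv_reports: pd.DataFrame
    patch_tables: dict[str, pd.DataFrame]
    hotspot_threshold: float | None
    zonal_summary: pd.DataFrame | None
    test_reports: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def _grid_from_config(cfg: RunConfig, stations: pd.DataFrame) -> GridSpec:
    if cfg.grid_origin is not None and cfg.grid_ncols and cfg.grid_nrows:
        return GridSpec(tuple(cfg.grid_origin), cfg.grid_cell_size_m,
                        cfg.grid_ncols, cfg.grid_nrows)
    # Derive from the station bounding box, padded by one cell.
    c = cfg.grid_cell_size_m
    x0 = np.floor(stations["x"].min() / c - 1) * c
    y0 = np.floor(stations["y"].min() / c - 1) * c
    x1 = np.ceil(stations["x"].max() / c + 1) * c
    y1 = np.ceil(stations["y"].max() / c + 1) * c
    return GridSpec((x0, y0), c, int(round((x1 - x0) / c)),
                    int(round((y1 - y0) / c)))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


@_stage("krige")
def _krige_variable(name, pts, values, grid, cfg, clamp):
    ok = OrdinaryKriging(variogram="auto", families=cfg.families,
                         cutoff=cfg.cutoff, n_bins=cfg.n_bins)
    ok.fit(pts, values)
    X, Y = grid.cell_centres()
    targets = np.column_stack([X.ravel(), Y.ravel()])
    pred, se = ok.predict(targets, return_std=True)
    if clamp is not None:
        pred = np.clip(pred, *clamp)
    vg = ok.variogram_
    return (Raster(pred.reshape(grid.nrows, grid.ncols), grid.cell_size_m,
                   grid.origin),
            Raster(se.reshape(grid.nrows, grid.ncols), grid.cell_size_m,
                   grid.origin),
            {"family": vg.family, "nugget": vg.nugget,
             "partial_sill": vg.partial_sill, "range_m": vg.range_m})


def run_pipeline(config: RunConfig, quiet: bool = False) -> PipelineResult:
    """Execute the full mapping pipeline described in the module docstring."""
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    def log(msg: str) -> None:
        if not quiet:
            import sys
            print(f"[benthoscape] {msg}", file=sys.stderr)

    try:
        stations = read_station_table(cfg.station_table)
    except Exception as exc:
        raise PipelineError("read_stations", exc) from exc
    log(f"read {len(stations)} stations from {cfg.station_table}")

    variables: dict[str, np.ndarray] = {
        c: stations[c].to_numpy(dtype=float) for c in ANALYSIS_CLASSES}
    if cfg.species_table:
        try:
            species = read_species_table(cfg.species_table)
            div = diversity_table(species)
            stations = stations.merge(div, on="station_id", how="left")
        except Exception as exc:
            raise PipelineError("diversity", exc) from exc
        have = stations["inverse_simpson"].notna()
        log(f"diversity computed for {int(have.sum())} stations")

    grid = _grid_from_config(cfg, stations)
    pts = stations[["x", "y"]].to_numpy(dtype=float)

    predictions, std_errors, variograms = {}, {}, {}
    cv_rows = []
    targets_list = list(ANALYSIS_CLASSES)
    if "inverse_simpson" in stations.columns:
        targets_list.append("inverse_simpson")
    for name in targets_list:
        if name == "inverse_simpson":
            mask = stations["inverse_simpson"].notna().to_numpy()
            v = stations.loc[mask, "inverse_simpson"].to_numpy(dtype=float)
            p = pts[mask]
            clamp = None
        else:
            v, p, clamp = variables[name], pts, (0.0, 1.0)
        pred, se, vg = _krige_variable(name, p, v, grid, cfg, clamp)
        predictions[name], std_errors[name], variograms[name] = pred, se, vg
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = cross_validate(p, v, model_spec="auto", k=cfg.k_folds,
                                     seed=cfg.seed, families=cfg.families,
                                     cutoff=cfg.cutoff, n_bins=cfg.n_bins)
        except Exception as exc:
            raise PipelineError("cross_validate", exc) from exc
        cv_rows.append({"variable": name, **rep.as_dict(),
                        "k": cfg.k_folds, "seed": cfg.seed})
        write_ascii_grid(pred, out / f"pred_{name}.asc")
        write_ascii_grid(se, out / f"se_{name}.asc")
        log(f"kriged {name}: {vg['family']} variogram, "
            f"range {vg['range_m']:.0f} m")
    cv_reports = pd.DataFrame(cv_rows)
    cv_reports.to_csv(out / "cv_report.csv", index=False,
                      float_format="%.10g")

    patch_tables: dict[str, pd.DataFrame] = {}
    try:
        all_patches = []
        for name in ANALYSIS_CLASSES:
            ps = threshold_patches(predictions[name], cfg.threshold,
                                   cfg.connectivity)
            t = ps.table.copy()
            t.insert(0, "substratum", name)
            patch_tables[name] = t
            all_patches.append(t)
            np.savetxt(out / f"patches_{name}.txt", ps.labels, fmt="%d")
        pd.concat(all_patches, ignore_index=True).to_csv(
            out / "patch_metrics.csv", index=False, float_format="%.10g")
        log(f"patches delineated at threshold {cfg.threshold}")
    except Exception as exc:
        raise PipelineError("patches", exc) from exc

    hot_thresh = None
    if "inverse_simpson" in predictions:
        try:
            mask, hot_thresh = hotspot_mask(predictions["inverse_simpson"],
                                            cfg.hotspot_fraction)
            hot = predictions["inverse_simpson"].copy_with(
                mask.astype(float))
            write_ascii_grid(hot, out / "hotspots.asc")
            log(f"diversity hotspot threshold {hot_thresh:.3f}")
        except Exception as exc:
            raise PipelineError("hotspots", exc) from exc

    zonal_summary = None
    test_reports = None
    try:
        summary = grid_aggregate_many(predictions, cfg.grid_size_m)
        zones = read_zones(cfg.zones_file) if cfg.zones_file else []
        if zones:
            summary["zone"] = assign_zones(summary["x"], summary["y"], zones)
            stations["zone"] = assign_zones(stations["x"], stations["y"],
                                            zones)
        zonal_summary = summary
        summary.to_csv(out / "zonal_summary.csv", index=False,
                       float_format="%.10g")
    except Exception as exc:
        raise PipelineError("zonal_aggregate", exc) from exc

    if "inverse_simpson" in stations.columns:
        try:
            reports = []
            sdiv = stations[stations["inverse_simpson"].notna()].copy()
            sdiv["modal"] = [modal_substratum(r)
                             for _, r in sdiv.iterrows()]
            if sdiv["modal"].nunique() > 1:
                reports.append(compare_groups(
                    sdiv["inverse_simpson"], sdiv["modal"],
                    comparison="diversity~substratum(stations)"))
            if "zone" in sdiv.columns and sdiv["zone"].nunique() > 1:
                reports.append(compare_groups(
                    sdiv["inverse_simpson"], sdiv["zone"],
                    comparison="diversity~zone(stations)"))
            if zonal_summary is not None and "zone" in zonal_summary.columns \
                    and "inverse_simpson" in zonal_summary.columns:
                zs = zonal_summary[
                    zonal_summary["inverse_simpson"].notna()]
                if zs["zone"].nunique() > 1:
                    reports.append(compare_groups(
                        zs["inverse_simpson"], zs["zone"],
                        comparison="diversity~zone(grid)"))
            if reports:
                test_reports = pd.concat(reports, ignore_index=True)
                test_reports.to_csv(out / "test_report.csv", index=False,
                                    float_format="%.10g")
        except Exception as exc:
            raise PipelineError("zone_tests", exc) from exc

    stations.to_csv(out / "stations_enriched.csv", index=False,
                    float_format="%.10g")
    manifest = {
        "package": "benthoscape",
        "version": __version__,
        "config": cfg.to_jsonable(),
        "grid": {"origin": list(grid.origin),
                 "cell_size_m": grid.cell_size_m,
                 "ncols": grid.ncols, "nrows": grid.nrows},
        "variables": targets_list,
        "variograms": variograms,
        "hotspot_threshold": hot_thresh,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    log(f"run complete: outputs in {out}")
    return PipelineResult(out, stations, predictions, std_errors,
                          variograms, cv_reports, patch_tables, hot_thresh,
                          zonal_summary, test_reports, manifest)
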