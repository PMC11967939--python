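"""Zonal aggregation and nonparametric comparisons.

Predicted surfaces are averaged over a coarse square grid (default
500 m x 500 m), each square is attached to the fishing-management zone
containing its centroid, and diversity is compared among substrata or
zones with rank-based tests: Kruskal-Wallis across groups, Dunn's
pairwise post-hoc with Bonferroni adjustment, and the two-sided rank-sum
(Wilcoxon/Mann-Whitney) test for single pairs.  Rank tests are used
because coverage and diversity values over a patchy seascape are far from
normal and heteroscedastic across substrata.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon

from .coverage import ANALYSIS_CLASSES
from .rasters import Raster

__all__ = [
    "ZonePolygon", "RESTRICTION_CLASSES", "grid_aggregate",
    "grid_aggregate_many", "assign_zones", "modal_substratum",
    "kruskal_wallis", "dunn_posthoc", "ranksum", "compare_groups",
]

#: Fishing-restriction classes: Trawl-and-Dredge ban (TND), Beam-Trawl
#: derogation (BT), Demersal-Trawl-Dredge-and-Creel ban (DTDC), No Take
#: Zone (NTZ), or unrestricted.
RESTRICTION_CLASSES = ("TND", "BT", "DTDC", "NTZ", "none")


@dataclass
class ZonePolygon:
    """A management zone: identifier, restriction class and geometry."""

    zone_id: str
    restriction_class: str
    geometry: Polygon

    def __post_init__(self) -> None:
        if self.restriction_class not in RESTRICTION_CLASSES:
            raise ValueError(
                f"zone {self.zone_id!r}: restriction_class "
                f"{self.restriction_class!r} not in {RESTRICTION_CLASSES}")
        if not self.geometry.is_valid or self.geometry.is_empty:
            raise ValueError(f"zone {self.zone_id!r}: invalid geometry")


def grid_aggregate(raster: Raster, grid_size_m: float = 500.0,
                   origin: tuple[float, float] | None = None,
                   value_name: str = "mean") -> pd.DataFrame:
    """Mean of finite raster cells per square of a coarse grid overlay.

    A raster cell belongs to the square containing its centre; squares
    with no finite cell are omitted.  Returns cell_id, square indices,
    centroid coordinates, the per-square mean and the contributing cell
    count.
    """
    if grid_size_m < raster.cell_size_m:
        raise ValueError("grid_size_m must be >= the raster cell size")
    gx0, gy0 = origin if origin is not None else raster.origin
    X, Y = raster.cell_centres()
    v = raster.values
    fin = np.isfinite(v)
    ix = np.floor((X[fin] - gx0) / grid_size_m).astype(int)
    iy = np.floor((Y[fin] - gy0) / grid_size_m).astype(int)
    frame = pd.DataFrame({"ix": ix, "iy": iy, "value": v[fin]})
    agg = (frame.groupby(["ix", "iy"], sort=True)["value"]
           .agg(["mean", "count"]).reset_index())
    agg["cell_id"] = [f"g{a}_{b}" for a, b in zip(agg["ix"], agg["iy"])]
    agg["x"] = gx0 + (agg["ix"] + 0.5) * grid_size_m
    agg["y"] = gy0 + (agg["iy"] + 0.5) * grid_size_m
    agg = agg.rename(columns={"mean": value_name, "count": "n_cells"})
    return agg[["cell_id", "ix", "iy", "x", "y", value_name, "n_cells"]]


def grid_aggregate_many(rasters: Mapping[str, Raster],
                        grid_size_m: float = 500.0) -> pd.DataFrame:
    """Aggregate several co-registered rasters onto one grid overlay."""
    out = None
    for name, raster in rasters.items():
        t = grid_aggregate(raster, grid_size_m, value_name=name)
        t = t.drop(columns=["n_cells"])
        keys = ["cell_id", "ix", "iy", "x", "y"]
        out = t if out is None else out.merge(t, on=keys, how="outer")
    return out.sort_values(["ix", "iy"]).reset_index(drop=True)


def assign_zones(x: np.ndarray, y: np.ndarray,
                 zones: Sequence[ZonePolygon]) -> list[str]:
    """Zone label per point by polygon membership of the point itself.

    Grid squares are assigned by their centroid.  Points in no zone get
    "none"; overlapping zones resolve to the first zone listed.
    """
    labels = []
    for xi, yi in zip(np.asarray(x, float), np.asarray(y, float)):
        p = Point(xi, yi)
        hit = next((z for z in zones
                    if z.geometry.contains(p) or z.geometry.touches(p)),
                   None)
        labels.append(hit.zone_id if hit is not None else "none")
    return labels


def modal_substratum(profile_row: Mapping[str, float]) -> str:
    """Most common substratum class at a station; ties break by the fixed
    class order (algae, gravel, mud, sand, pebble)."""
    vals = [float(profile_row[c]) for c in ANALYSIS_CLASSES]
    return ANALYSIS_CLASSES[int(np.argmax(vals))]


def kruskal_wallis(groups: Sequence[Sequence[float]],
                   ) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test with tie correction: (H, df, p).

    p comes from the chi-squared upper tail with df = n_groups - 1.  If
    every pooled value is identical the statistic is 0 and p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one value")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), df, float(p)


def _midranks_and_ties(pooled: np.ndarray) -> tuple[np.ndarray, float]:
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts ** 3 - counts))
    return ranks, tie_sum


def dunn_posthoc(groups: Sequence[Sequence[float]],
                 names: Sequence[str] | None = None,
                 adjustment: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise post-hoc test on pooled midranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tied values; two-sided normal p-values,
    Bonferroni-multiplied by the number of pairs and capped at 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    if names is None:
        names = [f"group{i}" for i in range(len(arrays))]
    sizes = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks, tie_sum = _midranks_and_ties(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean()
                  for i in range(len(arrays))]
    var_term = (n_total * (n_total + 1) / 12.0
                - tie_sum / (12.0 * (n_total - 1)))
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        denom = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * n_pairs) if adjustment == "bonferroni" else p
        rows.append({"group_a": names[i], "group_b": names[j],
                     "z": float(z), "p": float(p),
                     "p_adjusted": float(p_adj)})
    return pd.DataFrame(rows)


def ranksum(group_a: Sequence[float], group_b: Sequence[float],
            ) -> tuple[float, float]:
    """Two-sided rank-sum test with tie-corrected normal approximation.

    Returns (W, p) where W is the midrank sum of ``group_a`` in the
    pooled sample.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, m = a.size, b.size
    big_n = n + m
    ranks, tie_sum = _midranks_and_ties(pooled)
    w = float(ranks[:n].sum())
    mean_w = n * (big_n + 1) / 2.0
    var_w = (n * m / 12.0) * ((big_n + 1)
                              - tie_sum / (big_n * (big_n - 1)))
    if var_w <= 0:
        return w, 1.0
    z = (w - mean_w) / np.sqrt(var_w)
    return w, float(2.0 * stats.norm.sf(abs(z)))


def compare_groups(values: Sequence[float], labels: Sequence[str],
                   comparison: str = "groups") -> pd.DataFrame:
    """Kruskal-Wallis plus Dunn post-hoc on values split by label.

    Returns a tidy report table (comparison, test, groups, statistic, df,
    p, p_adjusted) with one Kruskal-Wallis row and one row per Dunn pair.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = [str(u) for u in pd.unique(labels)]
    groups = [values[labels == u] for u in names]
    h, df, p = kruskal_wallis(groups)
    rows = [{"comparison": comparison, "test": "kruskal_wallis",
             "groups": "all", "statistic": h, "df": df, "p": p,
             "p_adjusted": np.nan}]
    dunn = dunn_posthoc(groups, names=names)
    for _, r in dunn.iterrows():
        rows.append({"comparison": comparison, "test": "dunn",
                     "groups": f"{r['group_a']}|{r['group_b']}",
                     "statistic": r["z"], "df": np.nan, "p": r["p"],
                     "p_adjusted": r["p_adjusted"]})
    return pd.DataFrame(rows)
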