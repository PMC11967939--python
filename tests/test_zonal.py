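"""Zonal aggregation and nonparametric comparisons."""

import numpy as np
import pytest
from shapely.geometry import box

from benthoscape.rasters import Raster
from benthoscape.zonal import (ZonePolygon, assign_zones, dunn_posthoc,
                               grid_aggregate, grid_aggregate_many,
                               kruskal_wallis, modal_substratum, ranksum)


def midranks(pooled):
    """Independent midrank computation via argsort (no scipy)."""
    pooled = np.asarray(pooled, dtype=float)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and \
                pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def kw_oracle(groups):
    """Rank-formula oracle: H = 12/(N(N+1)) sum R_i^2/n_i - 3(N+1),
    divided by the tie-correction factor."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)].sum()
        h += r ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n_total ** 3 - n_total)
    return h / tie


def dunn_oracle(groups):
    """Independent mean-rank Dunn computation for every pair."""
    from math import erf, sqrt
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = midranks(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    mean_r = [ranks[bounds[i]:bounds[i + 1]].mean()
              for i in range(len(groups))]
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts ** 3 - counts)
    var = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    n_pairs = len(groups) * (len(groups) - 1) // 2
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            z = (mean_r[i] - mean_r[j]) / sqrt(
                var * (1 / len(groups[i]) + 1 / len(groups[j])))
            p = 2 * (1 - 0.5 * (1 + erf(abs(z) / sqrt(2))))
            out.append((z, min(1.0, p * n_pairs)))
    return out


class TestGridAggregate:
    def test_constant_raster_means_equal_constant(self):
        r = Raster(np.full((10, 10), 0.7), 100.0)
        table = grid_aggregate(r, 500.0)
        assert np.allclose(table["mean"], 0.7)
        assert table["n_cells"].sum() == 100

    def test_two_cell_square_mean(self):
        r = Raster(np.array([[0.2, 0.4]]), 250.0)
        table = grid_aggregate(r, 500.0)
        assert len(table) == 1
        assert table.loc[0, "mean"] == pytest.approx(0.3)

    def test_matches_point_in_square_enumeration(self):
        rng = np.random.default_rng(7)
        r = Raster(rng.random((13, 17)), 120.0, (300.0, -200.0))
        table = grid_aggregate(r, 500.0).set_index(["ix", "iy"])
        X, Y = r.cell_centres()
        for (ix, iy), row in table.iterrows():
            inside = ((np.floor((X - 300.0) / 500.0) == ix)
                      & (np.floor((Y + 200.0) / 500.0) == iy))
            assert row["mean"] == pytest.approx(r.values[inside].mean())
            assert row["n_cells"] == int(inside.sum())

    def test_global_mean_conserved_when_squares_fully_covered(self):
        rng = np.random.default_rng(8)
        r = Raster(rng.random((20, 20)), 100.0)  # 4x4 full 500 m squares
        table = grid_aggregate(r, 500.0)
        weighted = np.average(table["mean"], weights=table["n_cells"])
        assert weighted == pytest.approx(r.values.mean())

    def test_rejects_grid_finer_than_raster(self):
        with pytest.raises(ValueError):
            grid_aggregate(Raster(np.ones((5, 5)), 100.0), 50.0)

    def test_many_rasters_share_grid(self):
        r1 = Raster(np.full((10, 10), 0.2), 100.0)
        r2 = Raster(np.full((10, 10), 3.0), 100.0)
        table = grid_aggregate_many({"cov": r1, "div": r2}, 500.0)
        assert np.allclose(table["cov"], 0.2)
        assert np.allclose(table["div"], 3.0)


class TestAssignZones:
    def test_centroid_membership_and_none(self):
        zones = [ZonePolygon("west", "NTZ", box(0, 0, 100, 100)),
                 ZonePolygon("east", "BT", box(100, 0, 200, 100))]
        labels = assign_zones([50, 150, 500], [50, 50, 50], zones)
        assert labels == ["west", "east", "none"]


class TestModalSubstratum:
    def test_modal_and_tie_break_by_class_order(self):
        row = {"algae": 0.1, "gravel": 0.4, "mud": 0.4, "sand": 0.05,
               "pebble": 0.05}
        assert modal_substratum(row) == "gravel"  # tie -> earlier class
        row["mud"] = 0.5
        assert modal_substratum(row) == "mud"


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        h, df, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert h == 0.0 and df == 1 and p == 1.0

    def test_textbook_two_group_value(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert df == 1
        assert h == pytest.approx(kw_oracle([[1, 2, 3], [4, 5, 6]]))
        assert h == pytest.approx(3.857, abs=2e-3)

    def test_tie_corrected_against_hand_oracle(self):
        groups = [[1.0, 1.0, 2.0], [2.0, 3.0, 3.0]]
        h, _, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kw_oracle(groups), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=8), rng.normal(1, 1, size=10)]
        h1, _, _ = kruskal_wallis(groups)
        h2, _, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestDunnPosthoc:
    def test_identical_groups_z_zero_p_one(self):
        out = dunn_posthoc([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert out.loc[0, "z"] == pytest.approx(0.0)
        assert out.loc[0, "p_adjusted"] == 1.0

    def test_matches_mean_rank_oracle_on_random_data(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            k = rng.integers(2, 5)
            groups = [rng.integers(0, 12, size=rng.integers(3, 9))
                      .astype(float) for _ in range(k)]
            ours = dunn_posthoc(groups)
            oracle = dunn_oracle(groups)
            for (z, p_adj), (_, row) in zip(oracle, ours.iterrows()):
                assert row["z"] == pytest.approx(z, abs=1e-10)
                assert row["p_adjusted"] == pytest.approx(p_adj, abs=1e-10)

    def test_only_differing_pair_stands_out(self):
        a = [1.0, 1.1, 0.9, 1.05, 0.95]
        b = [1.0, 1.04, 0.96, 1.06, 0.94]
        c = [9.0, 9.1, 8.9, 9.05, 8.95]
        out = dunn_posthoc([a, b, c], names=["a", "b", "c"])
        out = out.set_index(["group_a", "group_b"])
        assert out.loc[("a", "c"), "p_adjusted"] < \
            out.loc[("a", "b"), "p_adjusted"]
        assert out.loc[("b", "c"), "p_adjusted"] < \
            out.loc[("a", "b"), "p_adjusted"]

    def test_bonferroni_never_below_raw_p(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(size=6) for _ in range(4)]
        out = dunn_posthoc(groups)
        assert (out["p_adjusted"] >= out["p"] - 1e-15).all()
        assert (out["p_adjusted"] <= 1.0).all()


class TestRanksum:
    def test_identical_groups_p_near_one(self):
        w, p = ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.99

    def test_fully_separated_groups_extreme_rank_sum(self):
        w, p = ranksum([1, 2, 3], [10, 11, 12])
        assert w == 1 + 2 + 3  # minimal possible rank sum for group a
        assert p < 0.1

    def test_shift_invariance(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=10), rng.normal(size=12)
        assert ranksum(a, b) == pytest.approx(ranksum(a + 5.0, b + 5.0))

    def test_matches_mann_whitney_normal_approximation(self):
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(13)
        for _ in range(10):
            a = rng.integers(0, 10, size=8).astype(float)
            b = rng.integers(0, 10, size=11).astype(float)
            _, p = ranksum(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic",
                               use_continuity=False).pvalue
            assert p == pytest.approx(ref, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ranksum([], [1.0])
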