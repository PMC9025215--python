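import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rangeshift import range_dynamics as rd
from rangeshift.grid import GridSpec, Raster


@pytest.fixture()
def grid3():
    return GridSpec(nrows=3, ncols=3, xmin=0.0, ymin=40.0, cellsize=1.0)


def bmap(grid, values, scenario="future"):
    return rd.BinaryMap(grid=grid, values=np.asarray(values, dtype=float),
                        threshold=0.5, scenario=scenario)


class TestBinarize:
    def test_threshold_zero_all_ones(self, grid3, rng):
        suit = Raster(grid3, rng.uniform(0, 1, (3, 3)))
        out = rd.binarize(suit, 0.0)
        assert (out.values == 1.0).all()

    def test_threshold_above_max_all_zero(self, grid3, rng):
        suit = Raster(grid3, rng.uniform(0, 1, (3, 3)))
        out = rd.binarize(suit, 1.5)
        assert (out.values == 0.0).all()

    def test_hand_pattern_and_nan(self, grid3):
        vals = np.array([[0.9, 0.1, 0.5], [np.nan, 0.49, 0.51], [0.0, 1.0, 0.5]])
        out = rd.binarize(Raster(grid3, vals), 0.5)
        expected = np.array([[1, 0, 1], [np.nan, 0, 1], [0, 1, 1]], dtype=float)
        np.testing.assert_array_equal(out.values, expected)


class TestRangeChange:
    def test_identity_no_change(self, grid3, rng):
        cur = bmap(grid3, rng.integers(0, 2, (3, 3)))
        cur.values[0, 0] = 1  # ensure at least one presence
        rep = rd.range_change(cur, bmap(grid3, cur.values.copy()))
        assert rep.loss_pct == 0.0 and rep.gain_pct == 0.0 and rep.overall_change_pct == 0.0

    def test_hand_counts(self):
        g = GridSpec(nrows=4, ncols=5, xmin=0, ymin=0, cellsize=1.0)
        cur = np.zeros((4, 5))
        cur.ravel()[:10] = 1  # 10 current cells
        fut = np.zeros((4, 5))
        fut.ravel()[:6] = 1  # keep 6
        fut.ravel()[10:13] = 1  # gain 3
        rep = rd.range_change(bmap(g, cur, "cur"), bmap(g, fut))
        assert rep.loss_pct == pytest.approx(40.0)
        assert rep.gain_pct == pytest.approx(30.0)
        assert rep.overall_change_pct == pytest.approx(-10.0)
        assert rep.counts == {"lost": 4, "stable": 6, "gained": 3, "absent": 7}

    def test_overall_identity_on_printed_row(self):
        # gain - loss must reproduce the printed overall change (MR, 2070, SSP1-2.6)
        assert 14.36 - 38.29 == pytest.approx(-23.93, abs=0.01)

    def test_missing_cells_excluded(self, grid3):
        cur = np.ones((3, 3))
        fut = np.ones((3, 3))
        fut[0, 0] = np.nan  # masked in future -> excluded entirely
        fut[1, 1] = 0.0
        rep = rd.range_change(bmap(grid3, cur, "cur"), bmap(grid3, fut))
        assert rep.counts["stable"] == 7
        assert rep.counts["lost"] == 1
        assert rep.loss_pct == pytest.approx(100.0 / 8)

    def test_empty_current_error(self, grid3):
        with pytest.raises(ValueError):
            rd.range_change(bmap(grid3, np.zeros((3, 3)), "cur"), bmap(grid3, np.ones((3, 3))))

    def test_invariant_overall_equals_gain_minus_loss(self, rng):
        g = GridSpec(nrows=10, ncols=10, xmin=0, ymin=0, cellsize=0.5)
        for _ in range(10):
            cur = rng.integers(0, 2, (10, 10)).astype(float)
            fut = rng.integers(0, 2, (10, 10)).astype(float)
            if cur.sum() == 0:
                cur[0, 0] = 1
            rep = rd.range_change(bmap(g, cur, "c"), bmap(g, fut))
            assert rep.overall_change_pct == pytest.approx(rep.gain_pct - rep.loss_pct, abs=1e-9)


class TestTransitionMap:
    def test_codes(self, grid3):
        cur = np.array([[1, 1, 0], [0, 0, 0], [0, 0, 0]], dtype=float)
        fut = np.array([[1, 0, 1], [0, 0, 0], [0, 0, np.nan]], dtype=float)
        tm = rd.transition_map(bmap(grid3, cur, "c"), bmap(grid3, fut))
        assert tm.values[0, 0] == rd.TRANSITION_CODES["stable"]
        assert tm.values[0, 1] == rd.TRANSITION_CODES["lost"]
        assert tm.values[0, 2] == rd.TRANSITION_CODES["gained"]
        assert tm.values[1, 0] == rd.TRANSITION_CODES["absent"]
        assert np.isnan(tm.values[2, 2])


class TestOccurrencesLost:
    def occ(self, grid):
        lon, lat = grid.cell_center(np.array([0, 0, 1, 2]), np.array([0, 1, 1, 2]))
        return pd.DataFrame({"lon": lon, "lat": lat})

    def test_future_all_suitable_zero(self, grid3):
        assert rd.occurrences_lost(self.occ(grid3), bmap(grid3, np.ones((3, 3)))) == 0.0

    def test_future_all_unsuitable_hundred(self, grid3):
        assert rd.occurrences_lost(self.occ(grid3), bmap(grid3, np.zeros((3, 3)))) == 100.0

    def test_hand_fraction(self):
        g = GridSpec(nrows=5, ncols=4, xmin=0, ymin=0, cellsize=1.0)
        rows = np.repeat(np.arange(5), 4)
        cols = np.tile(np.arange(4), 5)
        lon, lat = g.cell_center(rows, cols)
        occ = pd.DataFrame({"lon": lon, "lat": lat})  # 20 records, one per cell
        fut = np.ones((5, 4))
        fut.ravel()[:8] = 0  # exactly 8 of 20 records in lost cells
        assert rd.occurrences_lost(occ, bmap(g, fut)) == pytest.approx(40.0)

    def test_no_usable_records_error(self, grid3):
        occ = pd.DataFrame({"lon": [500.0], "lat": [0.0]})
        with pytest.raises(ValueError):
            rd.occurrences_lost(occ, bmap(grid3, np.ones((3, 3))))


class TestAggregateScenarios:
    def table(self):
        # per-GCM values for one severe-scenario transition, in the layout
        # of a published range-change table
        return pd.DataFrame(
            {
                "ssp": ["SSP585"] * 3,
                "time_slice": ["2070"] * 3,
                "gcm": ["BC", "MI", "MR"],
                "loss_pct": [51.42, 20.03, 44.00],
                "gain_pct": [23.89, 29.36, 15.44],
                "overall_change_pct": [-27.54, 9.33, -28.55],
                "occ_lost_pct": [38.46, 13.37, 31.13],
            }
        )

    def test_published_row_means(self):
        out = rd.aggregate_scenarios(self.table())
        row = out.iloc[0]
        assert row["loss_pct"] == 38.48
        assert row["gain_pct"] == 22.90
        assert row["overall_change_pct"] == -15.59
        assert row["occ_lost_pct"] == 27.65

    def test_single_report_identity(self):
        t = self.table().iloc[:1]
        out = rd.aggregate_scenarios(t)
        assert out.iloc[0]["loss_pct"] == pytest.approx(51.42)

    def test_grouping_by_ssp_and_time(self):
        t = pd.concat([self.table(), self.table().assign(ssp="SSP126", loss_pct=10.0)])
        out = rd.aggregate_scenarios(t)
        assert len(out) == 2


class TestRoundHalfUp:
    def test_half_up(self):
        assert rd.round_half_up(0.125, 2) == 0.13
        assert rd.round_half_up(-15.585, 2) == -15.59
        assert rd.round_half_up(38.4833, 2) == 38.48


class TestCentroids:
    def test_single_cell(self, grid3):
        vals = np.zeros((3, 3))
        vals[1, 2] = 1
        lon, lat = rd.median_centroid(bmap(grid3, vals))
        elon, elat = grid3.cell_center(1, 2)
        assert (lon, lat) == (elon, elat)

    def test_symmetric_cross(self):
        g = GridSpec(nrows=5, ncols=5, xmin=0, ymin=0, cellsize=1.0)
        vals = np.zeros((5, 5))
        vals[2, :] = 1
        vals[:, 2] = 1
        lon, lat = rd.median_centroid(bmap(g, vals))
        elon, elat = g.cell_center(2, 2)
        assert (lon, lat) == (elon, elat)

    def test_median_matches_bruteforce(self, rng):
        g = GridSpec(nrows=12, ncols=12, xmin=0, ymin=40, cellsize=0.25)
        for _ in range(5):
            vals = (rng.uniform(0, 1, (12, 12)) > 0.6).astype(float)
            if vals.sum() == 0:
                vals[0, 0] = 1
            lon, lat = rd.median_centroid(bmap(g, vals))
            rows, cols = np.nonzero(vals == 1)
            lons, lats = g.cell_center(rows, cols)
            assert lon == pytest.approx(np.median(lons))
            assert lat == pytest.approx(np.median(lats))

    def test_geometric_option(self, grid3):
        vals = np.zeros((3, 3))
        vals[0, 0] = vals[0, 2] = vals[2, 2] = 1
        lon_m, _ = rd.median_centroid(bmap(grid3, vals))
        lon_g, _ = rd.median_centroid(bmap(grid3, vals), geometric=True)
        assert lon_g != lon_m

    def test_empty_error(self, grid3):
        with pytest.raises(ValueError):
            rd.median_centroid(bmap(grid3, np.zeros((3, 3))))


class TestCentroidDistance:
    def test_identical_zero(self):
        assert rd.centroid_distance((5.0, 45.0), (5.0, 45.0)) == 0.0

    def test_one_degree(self):
        assert rd.centroid_distance((0.0, 0.0), (0.0, 1.0)) == pytest.approx(111.19, abs=0.01)

    def test_symmetry_and_matrix(self):
        cents = {"a": (0.0, 40.0), "b": (1.0, 41.0), "c": (2.0, 42.0)}
        mat = rd.centroid_distance_matrix(cents)
        assert mat.loc["a", "b"] == mat.loc["b", "a"]
        assert (np.diag(mat) == 0).all()


class TestMeanAltitude:
    def test_constant_elevation(self, grid3):
        vals = np.zeros((3, 3))
        vals[1, 1] = vals[0, 0] = 1
        elev = Raster(grid3, np.full((3, 3), 100.0))
        assert rd.mean_altitude(bmap(grid3, vals), elev) == 100.0

    def test_two_cells(self, grid3):
        vals = np.zeros((3, 3))
        vals[0, 0] = vals[0, 1] = 1
        z = np.zeros((3, 3))
        z[0, 1] = 1000.0
        assert rd.mean_altitude(bmap(grid3, vals), Raster(grid3, z)) == 500.0

    def test_bruteforce_oracle(self, rng):
        g = GridSpec(nrows=10, ncols=10, xmin=0, ymin=40, cellsize=0.5)
        z = rng.uniform(0, 2000, (10, 10))
        vals = (rng.uniform(0, 1, (10, 10)) > 0.5).astype(float)
        vals[0, 0] = 1
        got = rd.mean_altitude(bmap(g, vals), Raster(g, z))
        assert got == pytest.approx(z[vals == 1].mean())

    def test_empty_error(self, grid3):
        with pytest.raises(ValueError):
            rd.mean_altitude(bmap(grid3, np.zeros((3, 3))), Raster(grid3, np.zeros((3, 3))))


class TestShiftTests:
    def test_seven_groups_df_six(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.1, 1, 50) for i in range(7)}
        res = rd.shift_tests(groups)
        assert res.kw_df == 6

    def test_identical_groups_null(self):
        x = np.arange(30, dtype=float)
        res = rd.shift_tests({"a": x, "b": x.copy(), "c": x.copy()})
        assert res.kw_stat == pytest.approx(0.0, abs=1e-9)
        assert res.kw_p > 0.99

    def test_separated_groups_significant(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(5, 1, 100)
        res = rd.shift_tests({"lo": a, "hi": b})
        assert res.kw_p < 0.001
        assert res.pairwise_p.loc["lo", "hi"] < 0.001

    def test_empty_group_error(self, rng):
        with pytest.raises(ValueError):
            rd.shift_tests({"a": rng.normal(0, 1, 10), "b": np.array([])})

    def test_holm_adjustment_matches_manual(self, rng):
        groups = {f"g{i}": rng.normal(0.3 * i, 1, 40) for i in range(4)}
        res = rd.shift_tests(groups)
        names = list(groups)
        raw = {}
        for i in range(4):
            for j in range(i + 1, 4):
                raw[(i, j)] = stats.mannwhitneyu(
                    groups[names[i]], groups[names[j]], alternative="two-sided"
                ).pvalue
        # manual Holm: sort ascending, multiply by (m - rank), enforce monotonicity
        items = sorted(raw.items(), key=lambda kv: kv[1])
        m = len(items)
        running = 0.0
        for rank, ((i, j), p) in enumerate(items):
            running = max(running, (m - rank) * p)
            assert res.pairwise_p.iloc[i, j] == pytest.approx(min(running, 1.0))

    def test_kw_matches_scipy(self, rng):
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(1, 1, 30)}
        res = rd.shift_tests(groups)
        kw = stats.kruskal(groups["a"], groups["b"])
        assert res.kw_stat == pytest.approx(kw.statistic)
        assert res.kw_p == pytest.approx(kw.pvalue)


class TestReportSerialization:
    def test_to_row_rounding(self):
        rep = rd.RangeChangeReport(
            scenario="s", loss_pct=38.4833, gain_pct=22.8967, overall_change_pct=-15.5866,
            counts={"lost": 1, "stable": 2, "gained": 3, "absent": 4},
            occ_lost_pct=27.6533, centroid=(1.0, 2.0), mean_altitude_m=542.55,
        )
        row = rep.to_row()
        assert row["loss_pct"] == 38.48
        assert row["gain_pct"] == 22.90
        assert row["overall_change_pct"] == -15.59
        assert row["occ_lost_pct"] == 27.65
        assert row["mean_altitude_m"] == 542.6
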