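import numpy as np
import pytest
from sklearn.preprocessing import MinMaxScaler

from seascapes.features import (FeatureTable, RangeScaler, assess_collinearity,
                                build_feature_table, range_standardize,
                                resample_bicubic, scatter_to_grid, _cubic_kernel)
from seascapes.grids import GridGeo, RasterGrid
from seascapes.synthetic import VARIABLES


def _grid(geo, values, mask=None, name="f"):
    values = np.asarray(values, float)
    mask = np.ones(geo.shape, bool) if mask is None else mask
    v = values.copy()
    v[~mask] = np.nan
    return RasterGrid(geo=geo, values=v, mask=mask, name=name)


def _oracle_bicubic(grid, target, a=-0.5):
    """Independent per-point oracle: 1-D cubic kernel applied to rows at the
    target longitudes, then to the resulting column at each target latitude."""
    src = grid.geo
    vals = grid.values
    xs, ys = src.lon_centers(), src.lat_centers()

    def interp1d(samples, coords, t):
        step = coords[1] - coords[0]
        u = (t - coords[0]) / step
        i0 = int(np.floor(u))
        out = 0.0
        for tap in range(i0 - 1, i0 + 3):
            w = float(_cubic_kernel(np.array([u - tap]), a)[0])
            out += w * samples[min(max(tap, 0), len(samples) - 1)]
        return out

    out = np.empty(target.shape)
    for i, lat in enumerate(target.lat_centers()):
        for j, lon in enumerate(target.lon_centers()):
            rowvals = np.array([interp1d(vals[r], xs, lon) for r in range(src.n_rows)])
            out[i, j] = interp1d(rowvals, -ys, -lat)  # kernel needs increasing coords
    return out


class TestResampleBicubic:
    def setup_method(self):
        self.src = GridGeo(0, 12, 0, 9, 9, 12)
        self.dst = GridGeo(2, 10, 2, 7, 15, 24)

    def test_constant_field(self):
        out = resample_bicubic(_grid(self.src, np.full(self.src.shape, 5.5)), self.dst)
        np.testing.assert_allclose(out.values, 5.5, atol=1e-12)

    def test_exact_on_bilinear_ramp(self):
        lon, lat = np.meshgrid(self.src.lon_centers(), self.src.lat_centers())
        ramp = 1.0 + 0.3 * lon + 0.7 * lat
        out = resample_bicubic(_grid(self.src, ramp), self.dst)
        lon_t, lat_t = np.meshgrid(self.dst.lon_centers(), self.dst.lat_centers())
        np.testing.assert_allclose(out.values, 1.0 + 0.3 * lon_t + 0.7 * lat_t, atol=1e-9)

    def test_matches_separable_oracle(self):
        rng = np.random.default_rng(8)
        field = rng.normal(size=self.src.shape)
        out = resample_bicubic(_grid(self.src, field), self.dst)
        np.testing.assert_allclose(out.values, _oracle_bicubic(
            _grid(self.src, field), self.dst), atol=1e-9)

    def test_commutes_with_adding_constant(self):
        rng = np.random.default_rng(9)
        field = rng.normal(size=self.src.shape)
        base = resample_bicubic(_grid(self.src, field), self.dst)
        shifted = resample_bicubic(_grid(self.src, field + 3.25), self.dst)
        np.testing.assert_allclose(shifted.values, base.values + 3.25, atol=1e-9)

    def test_land_prefill_keeps_values_finite(self):
        rng = np.random.default_rng(10)
        field = rng.normal(size=self.src.shape)
        mask = np.ones(self.src.shape, bool)
        mask[:3, :4] = False  # coastal block of land
        out = resample_bicubic(_grid(self.src, field, mask), self.dst)
        assert np.isfinite(out.values[out.mask]).all()

    def test_target_outside_source_raises(self):
        with pytest.raises(ValueError):
            resample_bicubic(_grid(self.src, np.zeros(self.src.shape)),
                             GridGeo(-30, -20, 0, 9, 5, 5))


class TestCollinearity:
    def _table(self, X):
        n = len(X)
        geo = GridGeo(0, 10, 0, max(n, 2), max(n, 2), 10)
        idx = np.column_stack([np.arange(n), np.zeros(n, int)])
        return FeatureTable(values=X, pixel_index=idx, geo=geo)

    def test_duplicated_column_flagged(self, rng):
        X = rng.normal(size=(50, 6))
        X[:, 1] = X[:, 0]
        with pytest.warns(UserWarning, match="collinear"):
            corr, flags = assess_collinearity(self._table(X))
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert (VARIABLES[0], VARIABLES[1]) in [(a, b) for a, b, _ in flags]

    def test_negated_column_flagged(self, rng):
        X = rng.normal(size=(50, 6))
        X[:, 2] = -X[:, 0]
        with pytest.warns(UserWarning):
            corr, flags = assess_collinearity(self._table(X))
        assert corr.iloc[0, 2] == pytest.approx(-1.0)
        assert any(v == pytest.approx(-1.0) for _, _, v in flags)

    def test_independent_noise_unflagged(self):
        X = np.random.default_rng(0).normal(size=(10_000, 6))
        corr, flags = assess_collinearity(self._table(X))
        off = corr.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05
        assert flags == []

    def test_zero_variance_column_raises(self, rng):
        X = rng.normal(size=(50, 6))
        X[:, 3] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            assess_collinearity(self._table(X))


class TestRangeScaler:
    def test_simple_column(self):
        out = RangeScaler().fit_transform(np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(out.ravel(), [0, 0.5, 1])

    def test_unit_interval_unchanged(self):
        X = np.array([[0.0], [0.25], [1.0]])
        np.testing.assert_allclose(RangeScaler().fit_transform(X), X)

    def test_extremes_attained_exactly(self, rng):
        X = rng.normal(size=(200, 6)) * rng.uniform(1, 50, 6) + rng.uniform(-5, 5, 6)
        out = RangeScaler().fit_transform(X)
        np.testing.assert_array_equal(out.min(axis=0), np.zeros(6))
        np.testing.assert_array_equal(out.max(axis=0), np.ones(6))

    def test_round_trip_inverse(self, rng):
        X = rng.normal(size=(100, 6)) * 10
        sc = RangeScaler().fit(X)
        np.testing.assert_allclose(sc.inverse_transform(sc.transform(X)), X, atol=1e-12)

    def test_matches_sklearn_minmax(self, rng):
        X = rng.normal(size=(80, 4))
        np.testing.assert_allclose(RangeScaler().fit_transform(X),
                                   MinMaxScaler().fit_transform(X), atol=1e-12)

    def test_constant_column_aborts(self):
        X = np.ones((10, 2))
        X[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="constant"):
            RangeScaler().fit(X)


class TestFeatureTable:
    def _grids(self, geo, masks=None):
        rng = np.random.default_rng(4)
        out = {}
        for i, v in enumerate(VARIABLES):
            mask = np.ones(geo.shape, bool) if masks is None else masks[i]
            out[v] = _grid(geo, rng.normal(size=geo.shape) + i, mask, name=v)
        return out

    def test_all_valid_rows_in_row_major_order(self):
        geo = GridGeo(0, 2, 0, 2, 2, 2)
        table = build_feature_table(self._grids(geo), np.ones((2, 2), bool))
        assert len(table) == 4
        np.testing.assert_array_equal(table.pixel_index,
                                      [[0, 0], [0, 1], [1, 0], [1, 1]])

    def test_pixel_invalid_anywhere_drops_row(self):
        geo = GridGeo(0, 2, 0, 2, 2, 2)
        masks = [np.ones(geo.shape, bool) for _ in range(6)]
        masks[3][1, 0] = False
        table = build_feature_table(self._grids(geo, masks), np.ones((2, 2), bool))
        assert len(table) == 3
        assert [1, 0] not in table.pixel_index.tolist()

    def test_row_count_equals_mask_conjunction(self, planted):
        fields, truth = planted["fields"], planted["truth"]
        expected = truth.sea_mask.copy()
        for g in fields.values():
            expected &= g.mask
        assert len(planted["table"]) == expected.sum()

    def test_scatter_back_is_identity(self, planted):
        table = planted["table"]
        for j in range(3):
            grid = scatter_to_grid(table, table.values[:, j])
            back = grid[table.pixel_index[:, 0], table.pixel_index[:, 1]]
            np.testing.assert_array_equal(back, table.values[:, j])

    def test_csv_round_trip(self, planted, tmp_path):
        p = tmp_path / "t.csv"
        planted["table"].to_csv(p)
        back = FeatureTable.from_csv(p, planted["geo"])
        np.testing.assert_allclose(back.values, planted["table"].values, atol=1e-9)
        np.testing.assert_array_equal(back.pixel_index, planted["table"].pixel_index)

    def test_zero_usable_pixels_raises(self):
        geo = GridGeo(0, 2, 0, 2, 2, 2)
        with pytest.raises(ValueError):
            build_feature_table(self._grids(geo), np.zeros((2, 2), bool))


class TestRangeStandardizeTable:
    def test_standardize_and_invert(self, planted):
        std, params = planted["std"], planted["params"]
        np.testing.assert_array_equal(std.values.min(axis=0), 0.0)
        np.testing.assert_array_equal(std.values.max(axis=0), 1.0)
        raw = std.values * (params.maxs - params.mins) + params.mins
        np.testing.assert_allclose(raw, planted["table"].values, atol=1e-12)

    def test_params_json_round_trip(self, planted, tmp_path):
        p = tmp_path / "params.json"
        planted["params"].to_json(p)
        from seascapes.features import StandardizationParams
        back = StandardizationParams.from_json(p)
        np.testing.assert_allclose(back.mins, planted["params"].mins)
        np.testing.assert_allclose(back.maxs, planted["params"].maxs)
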