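"""Synthetic landscape generation, lookup geometry, seasonal masking."""

import numpy as np
import pytest

import memstep as ms
from memstep.errors import OutOfDomainError
from memstep.landscape import SeasonalWindow, day_of_year


def _morans_i(raster: np.ndarray) -> float:
    """Moran's I with rook-neighbour weights (direct definition)."""
    z = raster - raster.mean()
    num = (z[:-1, :] * z[1:, :]).sum() + (z[:, :-1] * z[:, 1:]).sum()
    n_pairs = z[:-1, :].size + z[:, :-1].size
    return (num / n_pairs) / (z ** 2).mean()


class TestGeneration:
    def test_constant_layer(self):
        ls = ms.generate_random_landscape(
            0, 8, 8, 1.0, [{"name": "c", "kind": "constant", "value": 1.0}])
        assert np.all(ls.layers["c"] == 1.0)

    def test_same_seed_bit_identical(self):
        specs = [{"name": "f", "kind": "smooth", "smoothness": 3},
                 {"name": "d", "kind": "distance", "n_features": 2}]
        a = ms.generate_random_landscape(5, 16, 16, 0.5, specs)
        b = ms.generate_random_landscape(5, 16, 16, 0.5, specs)
        for name in a.names:
            assert np.array_equal(a.layers[name], b.layers[name])

    def test_smoothness_raises_spatial_autocorrelation(self):
        rough = ms.generate_random_landscape(
            3, 50, 50, 1.0, [{"name": "f", "kind": "smooth", "smoothness": 0}])
        smooth = ms.generate_random_landscape(
            3, 50, 50, 1.0, [{"name": "f", "kind": "smooth", "smoothness": 5}])
        assert _morans_i(smooth.layers["f"]) > _morans_i(rough.layers["f"])

    def test_smooth_fields_standardized(self):
        ls = ms.generate_random_landscape(
            3, 60, 60, 1.0, [{"name": "f", "kind": "smooth", "smoothness": 4}])
        assert abs(ls.layers["f"].mean()) < 1e-12
        assert abs(ls.layers["f"].std() - 1.0) < 1e-12

    @pytest.mark.parametrize("kwargs", [
        dict(n_rows=2, n_cols=8), dict(n_rows=8, n_cols=3),
        dict(cell_size=0.0), dict(cell_size=-1.0)])
    def test_invalid_dimensions_rejected(self, kwargs):
        kw = dict(seed=0, n_rows=8, n_cols=8, cell_size=1.0,
                  layer_specs=[{"name": "c", "kind": "constant", "value": 0}])
        kw.update(kwargs)
        with pytest.raises(ValueError):
            ms.generate_random_landscape(**kw)


class TestDistance:
    def test_feature_cell_is_zero(self):
        # feature exactly at a cell centre
        ls = ms.generate_random_landscape(
            0, 8, 8, 1.0,
            [{"name": "d", "kind": "distance", "features": [[2.5, 3.5]]}])
        assert ls.layers["d"][3, 2] == 0.0

    def test_three_four_five(self):
        grid = ((0.0, 0.0), 1.0, 1, 1)  # single cell, centre (0.5, 0.5)
        d = ms.distance_to_features(grid, [[0.2, 0.1]])
        assert d[0, 0] == pytest.approx(0.5)

    def test_minimum_over_features(self):
        rng = np.random.default_rng(1)
        feats = rng.uniform(0, 8, size=(5, 2))
        grid = ((0.0, 0.0), 0.5, 16, 16)
        combined = ms.distance_to_features(grid, feats)
        per_feature = np.stack([ms.distance_to_features(grid, [f])
                                for f in feats])
        assert np.allclose(combined, per_feature.min(axis=0))

    def test_triangle_inequality_between_neighbours(self):
        grid = ((0.0, 0.0), 0.5, 20, 20)
        d = ms.distance_to_features(grid, [[3.0, 7.0], [-1.0, 2.0]])
        assert np.all(np.abs(np.diff(d, axis=0)) <= 0.5 + 1e-12)
        assert np.all(np.abs(np.diff(d, axis=1)) <= 0.5 + 1e-12)

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            ms.distance_to_features(((0, 0), 1.0, 4, 4), [])


class TestLookup:
    def test_half_open_cells(self, small_landscape):
        ls = small_landscape
        row, col = ls.cell_index([[0.5, 1.0]])  # on shared edges
        assert (row[0], col[0]) == (2, 1)

    def test_out_of_extent_raises(self, small_landscape):
        with pytest.raises(OutOfDomainError):
            small_landscape.covariates_at((-1.0, 5.0))

    def test_nonseasonal_equals_raw(self, small_landscape):
        ls = small_landscape
        pt = (5.3, 7.1)
        r = ls.covariates_at(pt, doy=200, seasonal=False)
        row, col = ls.cell_index([pt])
        expected = [ls.layers[n][row[0], col[0]] for n in ls.names]
        assert np.allclose(r, expected)


class TestSeasonal:
    def test_default_windows_match_calendar(self, small_landscape):
        w = small_landscape.windows
        assert (w["berries"].start_doy, w["berries"].end_doy) == (213, 334)
        assert (w["riparian"].start_doy, w["riparian"].end_doy) == (130, 289)
        assert (w["squirrels"].start_doy, w["squirrels"].end_doy) == (254, 334)
        assert (w["sweetvetch"].start_doy, w["sweetvetch"].end_doy) == (91, 166)
        assert w["settlements"] is None and w["cabins"] is None

    def test_berry_zero_before_august(self, small_landscape):
        # doy 200 (Jul 19) precedes the berry window
        r = small_landscape.covariates_at((5.0, 5.0), doy=200, seasonal=True)
        i = small_landscape.names.index("berries")
        assert r[i] == 0.0

    def test_riparian_unmasked_in_june(self, small_landscape):
        ls = small_landscape
        doy_jun1 = day_of_year(np.datetime64("2004-06-01"))
        r = ls.covariates_at((5.0, 5.0), doy=doy_jun1, seasonal=True)
        raw = ls.covariates_at((5.0, 5.0), seasonal=False)
        i = ls.names.index("riparian")
        assert r[i] == raw[i] != 0.0

    def test_human_layers_never_masked(self, small_landscape):
        ls = small_landscape
        for doy in (1, 150, 366):
            r = ls.covariates_at((9.0, 3.0), doy=doy, seasonal=True)
            raw = ls.covariates_at((9.0, 3.0), seasonal=False)
            for name in ("settlements", "cabins"):
                i = ls.names.index(name)
                assert r[i] == raw[i]

    def test_masking_idempotent_and_zero_only(self, small_landscape):
        ls = small_landscape
        mask = ls.seasonal_mask(40)  # mid-winter: only human layers on
        assert set(np.unique(mask)) <= {0.0, 1.0}
        raw = ls.covariates_at((5.0, 5.0), seasonal=False)
        once = raw * mask
        assert np.allclose(once * mask, once)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            SeasonalWindow(200, 100)
        with pytest.raises(ValueError):
            SeasonalWindow(0, 100)


class TestDayOfYear:
    def test_common_year_dates(self):
        assert day_of_year(np.datetime64("2003-08-01")) == 213
        assert day_of_year(np.datetime64("2003-11-30")) == 334
        assert day_of_year(np.datetime64("2003-04-01")) == 91

    def test_leap_day_maps_to_366(self):
        assert day_of_year(np.datetime64("2004-02-29")) == 366
        # post-Feb dates keep their common-year day-of-year
        assert day_of_year(np.datetime64("2004-08-01")) == 213
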