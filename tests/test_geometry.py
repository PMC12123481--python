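import numpy as np
import pandas as pd
import pytest

from synchrospread.fields import SpatioTemporalField
from synchrospread.geometry import (
    ClimateRaster,
    DensitySurface,
    TransectFan,
    buffer_mean,
    fit_indicator_model,
    fit_indicator_surface,
    mask_treatments,
    region_buffer_diameter,
    spread_rates,
    transect_crossings,
)


def traps_df(xy, catch, year=2000):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "year": year,
            "x_km": xy[:, 0],
            "y_km": xy[:, 1],
            "catch": np.asarray(catch, dtype=float),
            "treated": 0,
        }
    )


class TestMaskTreatments:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.traps = traps_df(rng.uniform(0, 20, size=(10, 2)), rng.poisson(5, 10))

    def test_no_sites_identity(self):
        out = mask_treatments(self.traps, np.empty((0, 2)))
        pd.testing.assert_frame_equal(out, self.traps)

    def test_boundary_inclusive(self):
        traps = traps_df([[0.0, 0.0], [10.0, 10.0]], [1, 2])
        out = mask_treatments(traps, [[1.5, 0.0]], radius=1.5)
        assert len(out) == 1
        assert out["x_km"].iloc[0] == 10.0

    def test_count_matches_brute_force(self):
        sites = np.array([[5.0, 5.0], [15.0, 2.0]])
        out = mask_treatments(self.traps, sites, radius=1.5)
        # oracle: explicit distance check per trap
        pts = self.traps[["x_km", "y_km"]].to_numpy()
        d = np.sqrt(((pts[:, None, :] - sites[None]) ** 2).sum(-1)).min(axis=1)
        assert len(out) == int((d > 1.5).sum())

    def test_all_removed_is_error(self):
        traps = traps_df([[0.0, 0.0], [1.0, 0.0]], [1, 2])
        with pytest.raises(ValueError, match="unusable"):
            mask_treatments(traps, [[0.5, 0.0]], radius=5.0)


class TestIndicatorSurface:
    def test_degenerate_all_occupied(self):
        rng = np.random.default_rng(1)
        traps = traps_df(rng.uniform(0, 10, (12, 2)), np.full(12, 50))
        with pytest.raises(ValueError, match="degenerate"):
            fit_indicator_model(traps, threshold_catch=10)

    def test_near_degenerate_single_zero(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 10, (15, 2))
        catch = np.full(15, 50.0)
        catch[0] = 0.0
        model = fit_indicator_model(traps_df(xy, catch), threshold_catch=10)
        far = xy[np.argmax(np.hypot(*(xy - xy[0]).T))]
        assert model.predict([far])[0] > 0.9

    def test_kriging_exact_at_traps(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 20, (30, 2))
        catch = np.where(xy[:, 0] < 10, 50.0, 0.0)
        model = fit_indicator_model(traps_df(xy, catch), threshold_catch=10)
        pred = model.predict(xy)
        np.testing.assert_allclose(pred, model.indicator, atol=1e-6)

    def test_1d_level_falls_between_classes(self):
        # traps on a line: occupied for x <= 10, empty for x >= 12
        x = np.concatenate([np.arange(0, 10.5, 1.0), np.arange(12, 22.5, 1.0)])
        xy = np.column_stack([x, np.zeros_like(x)])
        catch = np.where(x <= 10, 50.0, 0.0)
        model = fit_indicator_model(traps_df(xy, catch), threshold_catch=10)
        probes = np.arange(0.0, 22.0, 0.05)
        p = model.predict(np.column_stack([probes, np.zeros_like(probes)]))
        crossing = probes[np.argmax(p < 0.5)]
        assert 10.0 < crossing < 12.0

    def test_idw_and_kriging_agree_on_crossing(self):
        x = np.arange(0.0, 30.0, 1.0)
        xy = np.column_stack([x, np.zeros_like(x)])
        catch = np.where(x <= 14, 50.0, 0.0)
        probes = np.column_stack([np.arange(5, 25, 0.05), np.zeros(400)])
        cross = {}
        for method in ("kriging", "idw"):
            model = fit_indicator_model(traps_df(xy, catch), method=method)
            p = model.predict(probes)
            cross[method] = probes[np.argmax(p < 0.5), 0]
        assert abs(cross["kriging"] - cross["idw"]) < 1.0


def analytic_surface(fn, extent=60, cell=1.0, year=2000):
    xs = np.arange(-extent, extent + cell, cell)
    ys = np.arange(-extent, extent + cell, cell)
    gx, gy = np.meshgrid(xs, ys)
    return DensitySurface(
        p=fn(gx, gy), x0=float(xs[0]), y0=float(ys[0]), cell_km=cell,
        year=year, threshold_catch=10.0,
    )


class TestTransectCrossings:
    def test_half_plane_front(self):
        surf = analytic_surface(lambda x, y: (np.hypot(x, y) < 40).astype(float))
        fan = TransectFan((0.0, 0.0), np.arange(0, 90, 10.0))
        out = transect_crossings(surf, fan, step_km=0.25)
        assert not out["missing"].any()
        np.testing.assert_allclose(out["distance_km"], 40.0, atol=1.0)

    def test_island_outer_edge(self):
        def fn(x, y):
            d = np.hypot(x, y)
            return (((d < 20) | ((d > 30) & (d < 40)))).astype(float)

        surf = analytic_surface(fn)
        fan = TransectFan((0.0, 0.0), np.array([45.0]))
        out = transect_crossings(surf, fan)
        # outermost transition: the island's outer edge near 40
        assert abs(out["distance_km"].iloc[0] - 40.0) < 1.5

    def test_monotone_profile_matches_root_oracle(self):
        from scipy.optimize import brentq

        prof = lambda d: 1.0 / (1.0 + np.exp((d - 35.0) / 4.0))
        surf = analytic_surface(lambda x, y: prof(np.hypot(x, y)))
        fan = TransectFan((0.0, 0.0), np.arange(10, 80, 7.5))
        out = transect_crossings(surf, fan, step_km=0.25)
        oracle = brentq(lambda d: prof(d) - 0.5, 1, 59)
        np.testing.assert_allclose(out["distance_km"], oracle, atol=0.5)

    def test_rotation_invariance(self):
        prof = lambda d: np.clip(1.2 - d / 40.0, 0, 1)
        surf = analytic_surface(lambda x, y: prof(np.hypot(x, y)))
        fan_a = TransectFan((0.0, 0.0), np.arange(0, 40, 5.0))
        fan_b = TransectFan((0.0, 0.0), np.arange(90, 130, 5.0))
        a = transect_crossings(surf, fan_a)["distance_km"].to_numpy()
        b = transect_crossings(surf, fan_b)["distance_km"].to_numpy()
        np.testing.assert_allclose(a, b, atol=0.05)

    def test_all_occupied_ray_is_missing(self):
        surf = analytic_surface(lambda x, y: np.ones_like(x))
        fan = TransectFan((0.0, 0.0), np.array([0.0]))
        out = transect_crossings(surf, fan)
        assert bool(out["missing"].iloc[0])


class TestSpreadRates:
    @staticmethod
    def crossings(dists):
        rows = []
        for (bearing, year), d in dists.items():
            rows.append(
                {"bearing": bearing, "year": year, "distance_km": d,
                 "missing": not np.isfinite(d)}
            )
        return pd.DataFrame(rows)

    def test_simple_displacement(self):
        df = self.crossings({(0.0, 2000): 40.0, (0.0, 2001): 50.0})
        field = spread_rates(df)
        assert field.values[0, 0] == pytest.approx(10.0)

    def test_static_front_zero(self):
        df = self.crossings(
            {(b, y): 40.0 for b in (0.0, 1.0) for y in (2000, 2001, 2002)}
        )
        field = spread_rates(df)
        np.testing.assert_allclose(field.values, 0.0)

    def test_missing_propagates(self):
        df = self.crossings({(0.0, 2000): 40.0, (0.0, 2001): np.nan, (0.0, 2002): 60.0})
        field = spread_rates(df)
        assert np.isnan(field.values[0]).all()

    def test_telescoping(self):
        rng = np.random.default_rng(4)
        d = {(0.0, 2000 + t): 40.0 + float(rng.uniform(-2, 5)) for t in range(10)}
        field = spread_rates(self.crossings(d))
        total = d[(0.0, 2009)] - d[(0.0, 2000)]
        assert field.values[0].sum() == pytest.approx(total, abs=1e-12)


class TestBufferMean:
    @staticmethod
    def raster(values, cell=1.0, x0=-20.0, y0=-20.0):
        return ClimateRaster(values=np.asarray(values, float), x0=x0, y0=y0, cell_km=cell)

    def test_uniform(self):
        r = self.raster(np.full((41, 41), 7.0))
        mean, n = buffer_mean(r, (0.0, 0.0), diameter=10.0)
        assert mean == pytest.approx(7.0)
        assert n > 0

    def test_linear_gradient_symmetry(self):
        xs = np.arange(-20, 21, 1.0)
        vals = np.tile(xs, (41, 1))  # value = x
        r = self.raster(vals)
        mean, _ = buffer_mean(r, (3.0, -2.0), diameter=12.0)
        assert mean == pytest.approx(3.0, abs=1e-9)

    def test_step_field_enumeration(self):
        xs = np.arange(-20, 21, 1.0)
        vals = np.tile((xs >= 0).astype(float) * 10.0, (41, 1))
        r = self.raster(vals)
        mean, n = buffer_mean(r, (0.0, 0.0), diameter=9.0)
        # oracle: enumerate covered cells directly
        gx, gy = np.meshgrid(xs, xs)
        inside = np.hypot(gx, gy) <= 4.5
        assert n == int(inside.sum())
        assert mean == pytest.approx(vals[inside].mean())

    def test_empty_buffer_error(self):
        r = self.raster(np.full((5, 5), 1.0), x0=0.0, y0=0.0)
        with pytest.raises(ValueError, match="no raster cells"):
            buffer_mean(r, (100.0, 100.0), diameter=2.0)


class TestRegionBufferDiameter:
    @staticmethod
    def field(values, regions):
        values = np.asarray(values, float)
        return SpatioTemporalField(
            values, np.arange(values.shape[0]), np.arange(values.shape[1]),
            regions=np.asarray(regions),
        )

    def test_constant(self):
        f = self.field(np.full((3, 4), 12.0), ["A"] * 3)
        assert region_buffer_diameter(f, "A") == pytest.approx(12.0)

    def test_signed_vs_absolute(self):
        f = self.field([[10.0, -10.0]], ["A"])
        assert region_buffer_diameter(f, "A") == pytest.approx(0.0)
        assert region_buffer_diameter(f, "A", mode="absolute") == pytest.approx(10.0)

    def test_mixed_matrix_brute_force(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(8, 3, size=(4, 6))
        f = self.field(vals, ["A", "A", "B", "B"])
        assert region_buffer_diameter(f, "B") == pytest.approx(vals[2:].mean())

    def test_all_missing_error(self):
        f = self.field(np.full((2, 3), np.nan), ["A", "A"])
        with pytest.raises(ValueError):
            region_buffer_diameter(f, "A")


class TestFanValidation:
    def test_strictly_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            TransectFan((0, 0), [0.0, 0.0, 1.0])

    def test_constant_step(self):
        with pytest.raises(ValueError, match="constant"):
            TransectFan((0, 0), [0.0, 0.5, 1.5])
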