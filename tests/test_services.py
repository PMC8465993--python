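import numpy as np
import pytest

from ecoclues.grids import MONTH_DAYS, ClimateStack, DriverStack, GridRaster, LandUseMap
from ecoclues.services import (
    biodiversity_suitability,
    climate_erosivity,
    estimate_runoff,
    potential_evapotranspiration,
    sand_fixation,
    soil_conservation,
    surface_roughness,
    water_conservation,
    wind_at_height,
)
from ecoclues.synthio import SpeciesOccurrences


def const(v, shape=(2, 2), cell=1.0):
    return GridRaster(np.full(shape, float(v)), cell)


class TestWaterConservation:
    def test_balanced_budget_zero(self):
        lu = LandUseMap(np.ones((2, 2), dtype=int))
        _, _, tq = water_conservation(const(500), const(200), const(300), lu)
        assert tq == 0.0

    def test_hand_unit_conversion(self):
        # 1 km2 cell, P=600, R=200, ET=300 -> 100 mm depth = 1e5 m3
        lu = LandUseMap(np.ones((1, 1), dtype=int))
        cells, totals, tq = water_conservation(
            const(600, (1, 1)), const(200, (1, 1)), const(300, (1, 1)), lu
        )
        assert cells.values[0, 0] == pytest.approx(1.0e5)
        assert tq == pytest.approx(1.0e5)

    def test_additive_over_class_relabelling(self, rng):
        p, r, et = (GridRaster(rng.uniform(0, 800, (10, 10))) for _ in range(3))
        one_class = LandUseMap(np.ones((10, 10), dtype=int))
        two_class = LandUseMap(rng.integers(1, 3, (10, 10)))
        tq1 = water_conservation(p, r, et, one_class)[2]
        tq2 = water_conservation(p, r, et, two_class)[2]
        assert tq1 == pytest.approx(tq2)

    def test_negative_cells_allowed_in_total(self):
        lu = LandUseMap(np.ones((1, 1), dtype=int))
        _, _, tq = water_conservation(
            const(100, (1, 1)), const(90, (1, 1)), const(100, (1, 1)), lu
        )
        assert tq == pytest.approx(-9.0e4)


class TestRunoff:
    def test_extreme_coefficients(self):
        lu = LandUseMap(np.ones((2, 2), dtype=int))
        p = const(800)
        assert np.all(estimate_runoff(p, lu, {1: 0.0}).values == 0)
        assert np.allclose(estimate_runoff(p, lu, {1: 1.0}).values, 800.0)

    def test_hand_product(self):
        lu = LandUseMap(np.full((2, 2), 4, dtype=int))
        r = estimate_runoff(const(800), lu, {4: 0.35})
        assert np.allclose(r.values, 280.0)

    def test_missing_class_coefficient_rejected(self):
        lu = LandUseMap(np.full((2, 2), 2, dtype=int))
        with pytest.raises(ValueError):
            estimate_runoff(const(800), lu, {1: 0.3})


class TestSoilConservation:
    def test_full_cover_zero_conservation(self):
        ac, _, _ = soil_conservation(const(100), const(0.3), 1.0, 2.0, const(1.0))
        assert np.allclose(ac.values, 0.0)

    def test_hand_product_48(self):
        ac, ap, ar = soil_conservation(const(100), const(0.3), 1.0, 2.0, const(0.2))
        assert ac.values[0, 0] == pytest.approx(48.0)
        assert ap.values[0, 0] == pytest.approx(60.0)

    def test_identity_ac_equals_ap_minus_ar(self, rng):
        r = GridRaster(rng.uniform(0, 500, (8, 8)))
        k = GridRaster(rng.uniform(0, 1, (8, 8)))
        c = GridRaster(rng.uniform(0, 1, (8, 8)))
        s = GridRaster(rng.uniform(0, 5, (8, 8)))
        ac, ap, ar = soil_conservation(r, k, 1.0, s, c)
        assert np.allclose(ac.values, ap.values - ar.values)

    def test_monotone_decreasing_in_cover(self):
        lo, _, _ = soil_conservation(const(100), const(0.3), 1.0, 2.0, const(0.2))
        hi, _, _ = soil_conservation(const(100), const(0.3), 1.0, 2.0, const(0.8))
        assert np.all(lo.values > hi.values)

    def test_cover_above_one_rejected(self):
        with pytest.raises(ValueError):
            soil_conservation(const(100), const(0.3), 1.0, 2.0, const(1.2))


class TestPotentialEvapotranspiration:
    def test_saturated_air_zero(self):
        assert potential_evapotranspiration(15.0, 1.0) == 0.0

    def test_cold_clamp(self):
        assert potential_evapotranspiration(-20.0, 0.3) == 0.0
        assert potential_evapotranspiration(-35.0, 0.3) == 0.0

    def test_hand_value_85_5(self):
        # 0.19 * (20+10)^2 * (1-0.5) = 85.5 mm
        assert potential_evapotranspiration(10.0, 0.5) == pytest.approx(85.5)

    def test_humidity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            potential_evapotranspiration(10.0, 1.2)


class TestWindProfile:
    def test_same_height_unchanged(self):
        assert wind_at_height(5.0, 10.0, 10.0) == pytest.approx(5.0)

    def test_hand_power_law(self):
        assert wind_at_height(4.0, 10.0, 2.0) == pytest.approx(4 * 0.2 ** (1 / 7))

    def test_strictly_increasing_in_target_height(self):
        speeds = [wind_at_height(4.0, 10.0, z) for z in (1, 2, 5, 10, 20)]
        assert speeds == sorted(speeds)

    def test_nonpositive_heights_rejected(self):
        with pytest.raises(ValueError):
            wind_at_height(4.0, 0.0, 2.0)


def climate_with(u, t, r, p, active_month=0):
    """Climate stack where only one month has the given values; others wet."""
    shape = (12, 1, 1)
    precip = np.full(shape, 1e4)
    temp = np.full(shape, 10.0)
    rh = np.full(shape, 0.5)
    wind = np.full(shape, 1.0)
    precip[active_month], temp[active_month] = p, t
    rh[active_month], wind[active_month] = r, u
    days = MONTH_DAYS.copy()
    days[active_month] = 30
    return ClimateStack(precip, temp, rh, wind, days=days)


class TestClimateErosivity:
    def test_wet_months_contribute_zero(self):
        c = climate_with(u=5.0, t=10.0, r=0.5, p=1e4)
        assert climate_erosivity(c).values[0, 0] == 0.0

    def test_hand_single_active_month(self):
        # ETP = 0.19*(30)^2*0.5 ~ 85.5; choose r so ETP=100: r = 1-100/171
        r = 1 - 100.0 / (0.19 * 900)
        c = climate_with(u=5.0, t=10.0, r=r, p=50.0)
        # (1/100) * 125 * 0.5 * 30 = 18.75
        assert climate_erosivity(c).values[0, 0] == pytest.approx(18.75)

    def test_additive_over_months(self):
        r = 1 - 100.0 / (0.19 * 900)
        c1 = climate_with(u=5.0, t=10.0, r=r, p=50.0, active_month=0)
        both = climate_with(u=5.0, t=10.0, r=r, p=50.0, active_month=0)
        both.precip_mm[3] = 50.0
        both.temp_c[3] = 10.0
        both.rel_humidity[3] = r
        both.wind_ms[3] = 5.0
        expected = climate_erosivity(c1).values[0, 0] * (1 + both.days[3] / 30)
        assert climate_erosivity(both).values[0, 0] == pytest.approx(expected)


class TestRoughnessAndSandFixation:
    def test_flat_terrain_roughness_one(self):
        assert surface_roughness(const(0.0)).values[0, 0] == 1.0

    def test_sixty_degrees_doubles(self):
        assert surface_roughness(const(np.pi / 3)).values[0, 0] == pytest.approx(2.0)

    def test_strictly_increasing(self):
        vals = [surface_roughness(const(t)).values[0, 0] for t in (0, 0.3, 0.6, 1.0)]
        assert vals == sorted(vals)

    def test_hand_product_2500(self):
        s = sand_fixation(const(500), const(0.4), const(10), const(1.25))
        assert s.values[0, 0] == pytest.approx(2500.0)

    def test_zero_factor_propagates(self):
        s = sand_fixation(const(0), const(0.4), const(10), const(1.25))
        assert np.all(s.values == 0)


class TestBiodiversity:
    def drivers(self):
        a = np.linspace(0, 1, 100).reshape(10, 10)
        b = np.linspace(1, 0, 100).reshape(10, 10)
        return DriverStack({"a": GridRaster(a), "b": GridRaster(b)})

    def test_envelope_membership_fractions(self):
        pts = [(4, c, 1) for c in range(2, 8)]  # envelope on middle values
        occ = SpeciesOccurrences(pts, {1: 1.0})
        suit = biodiversity_suitability(occ, self.drivers(), min_points=5)
        # occurrence cells lie inside both envelopes -> score 1
        assert suit.values[4, 4] == pytest.approx(1.0)
        # far corner lies outside both -> 0
        assert suit.values[0, 0] == 0.0
        assert np.all((suit.values >= 0) & (suit.values <= 1))

    def test_half_membership_single_species(self):
        drivers = DriverStack(
            {
                "a": GridRaster(np.tile(np.linspace(0, 1, 10), (10, 1))),
                "b": GridRaster(np.tile(np.linspace(0, 1, 10)[:, None], (1, 10))),
            }
        )
        pts = [(r, c, 1) for r in range(4, 7) for c in range(4, 7)]
        occ = SpeciesOccurrences(pts, {1: 1.0})
        suit = biodiversity_suitability(occ, drivers, min_points=5)
        # cell inside the row envelope but outside the column envelope
        assert suit.values[5, 0] == pytest.approx(0.5)

    def test_sparse_species_skipped_and_all_skipped_errors(self):
        occ = SpeciesOccurrences([(1, 1, 1)], {1: 1.0})
        with pytest.raises(ValueError):
            biodiversity_suitability(occ, self.drivers(), min_points=5)
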