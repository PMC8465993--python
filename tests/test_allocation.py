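import numpy as np
import pytest

from ecoclues.allocation import (
    AllocationError,
    AllocationParams,
    InfeasibleDemandError,
    allocate_year,
    simulate,
)
from ecoclues.grids import CLASS_CODES, GridRaster, LandUseMap, area_stats


def uniform_probs(shape, values=None):
    values = values or {c: 0.5 for c in CLASS_CODES}
    return {c: GridRaster(np.full(shape, v)) for c, v in values.items()}


def demand_from(map_):
    return {c: float(a) for c, a in area_stats(map_).items()}


class TestAllocateYear:
    def test_frozen_system_identity_one_iteration(self, random_map):
        params = AllocationParams(elasticity={c: 1.0 for c in CLASS_CODES})
        out, history = allocate_year(
            random_map, uniform_probs(random_map.shape), demand_from(random_map), params
        )
        assert np.array_equal(out.codes, random_map.codes)
        assert len(history) == 1

    def test_hand_1x2_case(self):
        # two cultivated cells; class-5 suitability much higher on the left;
        # demand one cell of each -> the left cell converts to artificial
        current = LandUseMap(np.array([[4, 4]]))
        probs = uniform_probs((1, 2), {c: 0.0 for c in CLASS_CODES})
        probs[5] = GridRaster(np.array([[0.9, 0.2]]))
        probs[4] = GridRaster(np.array([[0.5, 0.5]]))
        demand = {c: 0.0 for c in CLASS_CODES}
        demand[4], demand[5] = 1.0, 1.0
        params = AllocationParams(elasticity={c: 0.0 for c in CLASS_CODES})
        out, _ = allocate_year(current, probs, demand, params)
        assert out.codes.tolist() == [[5, 4]]

    def test_postconditions_on_random_instances(self):
        # demand conservation and convergence on randomized 50x50 instances
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            current = LandUseMap(rng.integers(1, 7, (50, 50)))
            probs = {c: GridRaster(rng.random((50, 50))) for c in CLASS_CODES}
            base = demand_from(current)
            # shift 60 km2 from the largest to the smallest class
            lo = min(base, key=base.get)
            hi = max(base, key=base.get)
            base[hi] -= 60.0
            base[lo] += 60.0
            params = AllocationParams(elasticity={c: 0.3 for c in CLASS_CODES})
            out, history = allocate_year(current, probs, base, params)
            tol = params.tolerance_frac * 2500.0
            final = demand_from(out)
            for c in CLASS_CODES:
                assert abs(final[c] - base[c]) <= tol
            assert area_stats(out).sum() == pytest.approx(2500.0)

    def test_elasticity_one_class_never_converted(self):
        rng = np.random.default_rng(7)
        current = LandUseMap(rng.integers(1, 7, (50, 50)))
        probs = {c: GridRaster(rng.random((50, 50))) for c in CLASS_CODES}
        demand = demand_from(current)
        demand[5] += 40.0
        demand[4] -= 20.0
        demand[1] -= 20.0
        elas = {c: 0.2 for c in CLASS_CODES}
        elas[3] = 1.0  # wetland strictly protected
        out, _ = allocate_year(current, probs, demand, AllocationParams(elasticity=elas))
        wet0 = current.codes == 3
        assert np.all(out.codes[wet0] == 3)

    def test_restricted_cells_unchanged(self):
        rng = np.random.default_rng(9)
        current = LandUseMap(rng.integers(1, 7, (30, 30)))
        restricted = np.zeros((30, 30), dtype=bool)
        restricted[:10] = True
        probs = {c: GridRaster(rng.random((30, 30))) for c in CLASS_CODES}
        demand = demand_from(current)
        demand[1] += 15.0
        demand[2] -= 15.0
        params = AllocationParams(
            elasticity={c: 0.0 for c in CLASS_CODES}, restricted_mask=restricted
        )
        out, _ = allocate_year(current, probs, demand, params)
        assert np.array_equal(out.codes[restricted], current.codes[restricted])

    def test_monotone_demand_response(self):
        rng = np.random.default_rng(21)
        current = LandUseMap(rng.integers(1, 7, (50, 50)))
        probs = {c: GridRaster(rng.random((50, 50))) for c in CLASS_CODES}
        params = AllocationParams(elasticity={c: 0.0 for c in CLASS_CODES})
        d1 = demand_from(current)
        out1, _ = allocate_year(current, probs, d1, params)
        d2 = dict(d1)
        d2[5] += 50.0
        d2[6] -= 50.0
        out2, _ = allocate_year(current, probs, d2, params)
        assert (out2.codes == 5).sum() >= (out1.codes == 5).sum()

    def test_conversion_rules_respected(self):
        rng = np.random.default_rng(5)
        current = LandUseMap(rng.integers(1, 7, (40, 40)))
        allowed = np.ones((6, 6), dtype=bool)
        allowed[4, :] = False  # artificial never converts away
        allowed[4, 4] = True
        probs = {c: GridRaster(rng.random((40, 40))) for c in CLASS_CODES}
        demand = demand_from(current)
        demand[1] += 30
        demand[2] -= 30
        params = AllocationParams(
            elasticity={c: 0.0 for c in CLASS_CODES}, conversion_allowed=allowed
        )
        out, _ = allocate_year(current, probs, demand, params)
        art0 = current.codes == 5
        assert np.all(out.codes[art0] == 5)

    def test_infeasible_demand_raises(self, random_map):
        demand = demand_from(random_map)
        # wetland locked by elasticity 1 but demanded to shrink far below its area
        elas = {c: 0.5 for c in CLASS_CODES}
        elas[3] = 1.0
        shrink = demand[3] * 0.8
        demand[3] -= shrink
        demand[4] += shrink
        with pytest.raises(InfeasibleDemandError):
            allocate_year(
                random_map, uniform_probs(random_map.shape), demand,
                AllocationParams(elasticity=elas),
            )

    def test_nonconvergence_carries_residuals(self, random_map):
        demand = demand_from(random_map)
        demand[1] += 100.0
        demand[2] -= 100.0
        params = AllocationParams(
            elasticity={c: 0.0 for c in CLASS_CODES}, max_iterations=1
        )
        with pytest.raises(AllocationError) as exc:
            allocate_year(random_map, uniform_probs(random_map.shape), demand, params)
        assert exc.value.residuals


class TestSimulate:
    def test_constant_demand_frozen_elasticity_identity(self, scene100):
        from ecoclues.demand import DemandSeries
        from ecoclues.suitability import fit_all_classes

        lu = scene100["landuse"]
        models = {c: m for c, m in fit_all_classes(lu, scene100["drivers"]).items()}
        areas = area_stats(lu).to_numpy()
        series = DemandSeries(list(range(2015, 2021)), np.tile(areas, (6, 1)))
        params = AllocationParams(elasticity={c: 1.0 for c in CLASS_CODES})
        out = simulate(lu, scene100["drivers"], models, series, params)
        for year, m in out.items():
            assert np.array_equal(m.codes, lu.codes), year

    def test_artificial_growth_lands_on_high_probability_cells(self, scene100):
        from ecoclues.demand import DemandSeries
        from ecoclues.suitability import fit_all_classes, probability_surface
        from scipy.stats import rankdata

        lu = scene100["landuse"]
        drivers = scene100["drivers"]
        models = fit_all_classes(lu, drivers)
        areas = area_stats(lu)
        target = areas.copy().astype(float)
        boost = 0.10 * target[5]
        target[5] += boost
        target[4] -= boost
        series = DemandSeries(
            [2015, 2025],
            np.vstack([areas.to_numpy(float), target.to_numpy(float)]),
        )
        elas = {1: 0.6, 2: 0.6, 3: 1.0, 4: 0.4, 5: 0.9, 6: 0.3}
        out = simulate(lu, drivers, models, series, AllocationParams(elasticity=elas))
        final = out[2025]
        new = (lu.codes != 5) & (final.codes == 5)
        assert new.sum() > 0
        p5 = probability_surface(models[5], drivers).values
        ranks = rankdata(p5.ravel()).reshape(p5.shape) / p5.size
        assert ranks[new].mean() > 0.8
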