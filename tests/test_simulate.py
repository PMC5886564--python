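"""Cellular-automata scenario simulator."""

import numpy as np
import pytest

from scenplan.errors import ConfigurationError
from scenplan.landcover import LandCoverGrid, default_registry
from scenplan.simulate import (
    FireParams,
    Scenario,
    TransitionModel,
    UrbanParams,
    build_scenario_set,
    default_base_model,
    simulate_scenario,
    step,
)
from scenplan.synthetic import ProtectedAreaMask

from tests.conftest import uniform_grid


def null_model(reg):
    return TransitionModel({}, UrbanParams(0.0, 0.0), None, reg)


def no_pas(shape):
    return ProtectedAreaMask(np.zeros(shape, dtype=bool))


class TestStep:
    def test_null_dynamics_identity(self, landscape):
        rng = np.random.default_rng(0)
        out = step(landscape, no_pas(landscape.shape), null_model(landscape.registry), rng)
        assert np.array_equal(out.classes, landscape.classes)

    def test_deterministic_expansion_fills_moore_neighbourhood(self, registry):
        herb, built = registry.code_of("herbaceous"), registry.code_of("built")
        arr = np.full((3, 3), herb, dtype=np.int64)
        arr[1, 1] = built
        grid = LandCoverGrid(arr, 1.0, registry)
        model = TransitionModel({}, UrbanParams(p_expand=1.0, p_seed=0.0), None, registry)
        out = step(grid, no_pas((3, 3)), model, np.random.default_rng(1))
        assert (out.classes == built).all()  # all 8 neighbours convert

    def test_one_step_conversion_is_binomial(self, registry):
        grid = uniform_grid(registry.code_of("herbaceous"), shape=(100, 100), registry=registry)
        p = 0.1
        model = TransitionModel(
            {(registry.code_of("herbaceous"), registry.code_of("sparse_shrubland")): p},
            UrbanParams(0.0, 0.0),
            None,
            registry,
        )
        out = step(grid, no_pas((100, 100)), model, np.random.default_rng(3))
        n = grid.classes.size
        k = (out.classes == registry.code_of("sparse_shrubland")).sum()
        sd = np.sqrt(n * p * (1 - p))
        assert abs(k - n * p) <= 3 * sd

    def test_protected_cells_never_urbanise(self, registry):
        herb, built = registry.code_of("herbaceous"), registry.code_of("built")
        arr = np.full((5, 5), herb, dtype=np.int64)
        arr[2, 2] = built
        grid = LandCoverGrid(arr, 1.0, registry)
        pa = ProtectedAreaMask(np.ones((5, 5), dtype=bool))
        model = TransitionModel({}, UrbanParams(1.0, 1.0, protected_exempt=True), None, registry)
        out = step(grid, pa, model, np.random.default_rng(0))
        assert np.array_equal(out.classes, arr)

    def test_agriculture_urbanises_but_never_succeeds(self, registry):
        crop, built = registry.code_of("cropland"), registry.code_of("built")
        arr = np.full((3, 3), crop, dtype=np.int64)
        arr[0, 0] = built
        grid = LandCoverGrid(arr, 1.0, registry)
        model = TransitionModel(
            {(registry.code_of("herbaceous"), registry.code_of("sparse_shrubland")): 1.0},
            UrbanParams(1.0, 0.0),
            None,
            registry,
        )
        out = step(grid, no_pas((3, 3)), model, np.random.default_rng(0))
        # built-adjacent cropland converts; the far corner stays cropland
        assert out.classes[1, 1] == built
        assert out.classes[2, 2] == crop

    def test_fire_resets_to_herbaceous(self, registry):
        wood = registry.code_of("dense_woodland")
        grid = uniform_grid(wood, shape=(10, 10), registry=registry)
        model = TransitionModel({}, UrbanParams(0.0, 0.0), FireParams(p_ignite=1.0), registry)
        out = step(grid, no_pas((10, 10)), model, np.random.default_rng(0))
        assert (out.classes == registry.code_of("herbaceous")).all()

    def test_invalid_transition_sum_rejected(self, registry):
        h = registry.code_of("herbaceous")
        model = TransitionModel(
            {(h, registry.code_of("sparse_shrubland")): 0.7,
             (h, registry.code_of("dense_shrubland")): 0.6},
            UrbanParams(0.0, 0.0),
            None,
            registry,
        )
        with pytest.raises(ConfigurationError, match="sum"):
            model.validate()


class TestScenarioSet:
    def test_full_factorial_of_12(self):
        pairs = build_scenario_set(master_seed=1)
        assert len(pairs) == 12
        triples = {(s.vegetation_regime, s.urban_policy, s.rate_level) for s, _ in pairs}
        assert len(triples) == 12

    def test_rate_multiplier_x8_on_urban_only(self):
        pairs = {s.scenario_id: m for s, m in build_scenario_set(master_seed=1)}
        low, high = pairs["S-U-L"], pairs["S-U-H"]
        assert high.urban.p_expand == pytest.approx(8 * low.urban.p_expand)
        assert high.urban.p_seed == pytest.approx(8 * low.urban.p_seed)
        assert high.veg_transitions == low.veg_transitions

    def test_regulated_policy_has_no_seeding(self):
        for s, m in build_scenario_set(master_seed=2):
            if s.urban_policy == "regulated":
                assert m.urban.p_seed == 0.0
            else:
                assert m.urban.p_seed > 0.0

    def test_multiplied_probability_above_one_fails_fast(self, registry):
        base = default_base_model(registry)
        base.urban = UrbanParams(p_expand=0.2, p_seed=0.0001)
        scen = Scenario("moderate", "regulated", "high")
        with pytest.raises(ConfigurationError, match="above 1"):
            base.resolve(scen)

    def test_invalid_scenario_fields(self):
        with pytest.raises(ConfigurationError):
            Scenario("mild", "regulated", "low")


class TestSimulateScenario:
    def test_zero_horizon_unchanged(self, landscape, pas):
        scen = Scenario("moderate", "regulated", "low", horizon_years=0, seed=1)
        model = default_base_model(landscape.registry).resolve(scen)
        out = simulate_scenario(landscape, pas, scen, model)
        assert np.array_equal(out.classes, landscape.classes)

    def test_built_is_absorbing(self, landscape, pas):
        built = landscape.registry.code_of("built")
        scen = Scenario("severe", "unregulated", "high", horizon_years=20, seed=5)
        model = default_base_model(landscape.registry).resolve(scen)
        final, snaps = simulate_scenario(landscape, pas, scen, model, return_snapshots=True)
        prev = (landscape.classes == built).sum()
        for year in sorted(snaps):
            cur = (snaps[year].classes == built).sum()
            assert cur >= prev
            prev = cur
        assert (final.classes == built).sum() >= prev

    def test_deterministic(self, landscape, pas):
        scen = Scenario("severe", "unregulated", "moderate", horizon_years=10, seed=9)
        model = default_base_model(landscape.registry).resolve(scen)
        a = simulate_scenario(landscape, pas, scen, model)
        b = simulate_scenario(landscape, pas, scen, model)
        assert np.array_equal(a.classes, b.classes)

    def test_classes_stay_in_registry(self, landscape, pas):
        scen = Scenario("severe", "unregulated", "high", horizon_years=15, seed=2)
        model = default_base_model(landscape.registry).resolve(scen)
        out = simulate_scenario(landscape, pas, scen, model)
        assert set(np.unique(out.classes)) <= {c.code for c in landscape.registry}


class TestScenarioContrasts:
    def test_built_area_monotone_in_rate(self, landscape, pas):
        """Expected final built area is non-decreasing in the rate multiplier."""
        built = landscape.registry.code_of("built")
        base = default_base_model(landscape.registry)
        wins = {"lm": 0, "mh": 0}
        reps = 20
        for r in range(reps):
            areas = {}
            for rate in ("low", "moderate", "high"):
                scen = Scenario("moderate", "unregulated", rate, horizon_years=30, seed=100 + r)
                out = simulate_scenario(landscape, pas, scen, base.resolve(scen))
                areas[rate] = (out.classes == built).sum()
            wins["lm"] += areas["low"] <= areas["moderate"]
            wins["mh"] += areas["moderate"] <= areas["high"]
        assert wins["lm"] == reps
        assert wins["mh"] == reps

    def test_severe_regime_less_woody_than_moderate(self, landscape, pas):
        woody = [
            landscape.registry.formation_by_rank(4).code,
            landscape.registry.formation_by_rank(5).code,
        ]
        base = default_base_model(landscape.registry)
        areas = {}
        for regime in ("moderate", "severe"):
            scen = Scenario(regime, "regulated", "low", horizon_years=40, seed=77)
            out = simulate_scenario(landscape, pas, scen, base.resolve(scen))
            areas[regime] = np.isin(out.classes, woody).sum()
        assert areas["severe"] < areas["moderate"]
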