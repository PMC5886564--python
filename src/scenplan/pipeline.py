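"""End-to-end synthetic study: generate, simulate, select, aggregate, evaluate.

One call to :func:`run_study` reproduces the full workflow on a synthetic
landscape: generate the land cover, species pool, protected areas and PU
grid; simulate the 12-scenario land-cover factorial; map per-scenario
habitat and set representation targets; run the annealer per scenario to
get selection frequencies; build the nine standard portfolios at a common
natural-area budget; and score every portfolio under every scenario.

Lock status follows each problem's own land-cover state: a scenario's
heavily urbanised PUs are unavailable in that scenario's selection run.
Portfolio construction (which PUs are locked in/out of the final reserve
sets) uses the present-day status, since the reserve system is established
today.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import PerformanceTable, covered_species, overlap_matrix, performance_summary
from .habitat import T0, HabitatMap, habitat_areas_by_scenario, suitable_habitat
from .landcover import LandCoverGrid
from .portfolio import TABLE1_SUBSETS, Portfolio, build_table1_portfolios
from .reserve import (
    AnnealSchedule,
    SelectionProblem,
    build_problem,
    calibrate_spf,
    lock_status,
    selection_frequency,
)
from .simulate import Scenario, TransitionModel, build_scenario_set, default_base_model, simulate_scenario
from .synthetic import (
    LandscapeConfig,
    ProtectedAreaMask,
    PUGrid,
    SpeciesHabitatModel,
    generate_landscape,
    generate_protected_areas,
    generate_species,
    make_pu_grid,
)
from .targets import RepresentationTarget, build_targets

__all__ = ["StudyConfig", "StudyResult", "run_study", "scenario_groups"]


@dataclass
class StudyConfig:
    """Desk-scale defaults for the synthetic study.

    A 64 x 64 raster of 1 km cells (4,096 km^2), 24 species on 8 km atlas
    blocks, 15% protected, 1 km^2 PUs, a 60-year horizon, and 100 annealing
    restarts of 20,000 iterations per selection problem. Species penalty
    factors are calibrated per problem (doubling from 1) before the
    frequency run.
    """

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    n_species: int = 24
    atlas_block: int = 8
    pa_fraction: float = 0.15
    pu_area: float = 1.0
    horizon: int = 60
    n_restarts: int = 100
    iterations: int = 20_000
    blm: float = 0.001
    freq_threshold: float = 0.9
    # SPF calibration (per selection problem, before the frequency run);
    # calibration rounds use shorter anneals than the frequency run
    calibrate_restarts: int = 10
    calibrate_rounds: int = 14
    calibrate_multiplier: float = 2.0
    calibrate_iterations: int = 5_000


@dataclass
class StudyResult:
    landscape: LandCoverGrid
    pas: ProtectedAreaMask
    pu_grid: PUGrid
    species: list[SpeciesHabitatModel]
    scenarios: list[tuple[Scenario, TransitionModel]]
    grids: dict[str, LandCoverGrid]
    habitat_areas: pd.DataFrame
    targets: dict[str, RepresentationTarget]
    status: dict[str, np.ndarray]
    problems: dict[str, SelectionProblem]
    frequencies: dict[str, pd.Series]
    portfolios: list[Portfolio]
    performance: PerformanceTable
    summary: pd.DataFrame
    overlap: pd.DataFrame

    def portfolio(self, name: str) -> Portfolio:
        for p in self.portfolios:
            if p.name == name:
                return p
        raise KeyError(name)

    def mean_covered(self) -> pd.Series:
        """Mean covered species per portfolio across the 12 scenarios."""
        return self.performance.counts.groupby("portfolio")["n_covered"].mean()


def scenario_groups(scenario_ids: list[str]) -> dict[str, list[str]]:
    """The standard scenario groupings (all, by regime, policy and rate)."""
    groups = {"all": list(scenario_ids)}
    for name, pred in TABLE1_SUBSETS.items():
        if pred is None or name == "all_scenarios":
            continue
        groups[name] = [s for s in scenario_ids if pred(s)]
    return groups


def run_study(master_seed: int, config: StudyConfig | None = None) -> StudyResult:
    """Run the complete scenario-robustness analysis on one synthetic replicate."""
    cfg = config or StudyConfig()
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4 + 13)]
    seed_land, seed_species, seed_pas, seed_scen = seeds[:4]
    select_seeds = seeds[4:]

    landscape = generate_landscape(cfg.landscape, seed_land)
    species = generate_species(cfg.n_species, landscape, cfg.atlas_block, seed_species)
    pas = generate_protected_areas(landscape, cfg.pa_fraction, seed_pas)
    pu_grid = make_pu_grid(landscape, cfg.pu_area)

    scenarios = build_scenario_set(
        default_base_model(landscape.registry), cfg.horizon, seed_scen
    )
    grids: dict[str, LandCoverGrid] = {T0: landscape}
    for scen, model in scenarios:
        grids[scen.scenario_id] = simulate_scenario(landscape, pas, scen, model)

    habitat_areas = habitat_areas_by_scenario(species, grids)
    targets = build_targets(habitat_areas)

    habitat_maps: dict[str, dict[str, HabitatMap]] = {
        sid: {
            sp.species_id: suitable_habitat(sp, grid, sp.range_mask, sid)
            for sp in species
        }
        for sid, grid in grids.items()
    }

    status: dict[str, np.ndarray] = {
        sid: lock_status(pu_grid, grid, pas) for sid, grid in grids.items()
    }

    schedule = AnnealSchedule(iterations=cfg.iterations)
    problems: dict[str, SelectionProblem] = {}
    frequencies: dict[str, pd.Series] = {}
    for i, sid in enumerate(grids):
        tgt = {
            s: (targets[s].target_area_km2 if sid == T0 else targets[s].achievable_area_km2[sid])
            for s in habitat_maps[sid]
        }
        prob = build_problem(
            pu_grid, habitat_maps[sid], tgt, status[sid], blm=cfg.blm, spf=1.0
        )
        spf = calibrate_spf(
            prob,
            n_restarts=cfg.calibrate_restarts,
            max_rounds=cfg.calibrate_rounds,
            multiplier=cfg.calibrate_multiplier,
            seed=select_seeds[i],
            schedule=AnnealSchedule(iterations=cfg.calibrate_iterations),
        )
        problems[sid] = prob.with_spf(np.array([spf[s] for s in prob.species_ids]))
        frequencies[sid] = selection_frequency(
            problems[sid], cfg.n_restarts, seed=select_seeds[i], schedule=schedule
        )

    scen_ids = [s.scenario_id for s, _ in scenarios]
    portfolios = build_table1_portfolios(
        {sid: frequencies[sid] for sid in scen_ids},
        frequencies[T0],
        landscape,
        pu_grid,
        status[T0],
        threshold=cfg.freq_threshold,
    )

    results = {}
    cell_area = landscape.cell_area
    for port in portfolios:
        for sid in scen_ids:
            achievable = {s: targets[s].achievable_area_km2[sid] for s in habitat_maps[sid]}
            results[(port.name, sid)] = covered_species(
                port, habitat_maps[sid], achievable, pu_grid, cell_area
            )
    performance = PerformanceTable.from_runs(results)
    summary = performance_summary(performance, scenario_groups(scen_ids))
    overlap = overlap_matrix(portfolios, pu_grid, mode="whole_portfolio")

    return StudyResult(
        landscape=landscape,
        pas=pas,
        pu_grid=pu_grid,
        species=species,
        scenarios=scenarios,
        grids=grids,
        habitat_areas=habitat_areas,
        targets=targets,
        status=status,
        problems=problems,
        frequencies=frequencies,
        portfolios=portfolios,
        performance=performance,
        summary=summary,
        overlap=overlap,
    )
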