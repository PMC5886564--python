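"""Simulated-annealing reserve selection: objective, oracle, frequencies, SPF."""

import numpy as np
import pytest

from scenplan.reserve import (
    AVAILABLE,
    LOCKED_IN,
    LOCKED_OUT,
    AnnealSchedule,
    Solution,
    anneal,
    brute_force_optimum,
    calibrate_spf,
    lock_status,
    objective,
    selection_frequency,
)
from scenplan.landcover import LandCoverGrid
from scenplan.synthetic import ProtectedAreaMask, make_pu_grid

from tests.conftest import make_problem, uniform_grid


def random_problem(seed, max_pu=13, max_sp=9):
    rng = np.random.default_rng(seed)
    n_pu = int(rng.integers(6, max_pu))
    n_sp = int(rng.integers(1, max_sp))
    ea, eb, el, seen = [], [], [], set()
    for _ in range(int(rng.integers(0, n_pu * 2))):
        a, b = rng.integers(0, n_pu, 2)
        if a == b or (min(a, b), max(a, b)) in seen:
            continue
        seen.add((min(a, b), max(a, b)))
        ea.append((min(a, b), max(a, b), float(rng.uniform(0.5, 2))))
    status = np.zeros(n_pu, np.int8)
    for j in range(n_pu):
        u = rng.random()
        if u < 0.1:
            status[j] = LOCKED_IN
        elif u < 0.2:
            status[j] = LOCKED_OUT
    amounts = rng.uniform(0, 5, (n_pu, n_sp)) * (rng.random((n_pu, n_sp)) < 0.6)
    return make_problem(
        n_pu,
        amounts,
        targets=rng.uniform(0, amounts.sum(0) * 0.8),
        spf=rng.uniform(1, 50, n_sp),
        cost=rng.uniform(0.5, 2, n_pu),
        status=status,
        edges=ea,
        outer=rng.uniform(0, 4, n_pu),
        blm=float(rng.choice([0.0, 0.001, 0.1, 1.0])),
    )


class TestObjective:
    def test_empty_selection_scores_total_spf(self):
        prob = make_problem(
            3, amounts=[[1.0], [2.0], [3.0]], targets=[5.0], spf=[7.0], blm=0.0
        )
        sol = Solution(frozenset(), 0.0, {}, {})
        assert objective(sol, prob) == pytest.approx(7.0)

    def test_full_selection_with_met_targets_scores_cost(self):
        prob = make_problem(
            3, amounts=[[3.0], [3.0], [3.0]], targets=[5.0], spf=[7.0],
            cost=[1.5, 2.0, 2.5], blm=0.0,
        )
        sol = Solution(frozenset({1, 2, 3}), 0.0, {}, {})
        assert objective(sol, prob) == pytest.approx(6.0)

    def test_corner_pu_boundary_on_2x2_lattice(self):
        # unit-square PUs in a 2x2 lattice; selecting one corner PU exposes
        # 2 internal edges + 2 study-area edges = boundary 4
        prob = make_problem(
            4,
            amounts=np.zeros((4, 0)),
            targets=[],
            spf=[],
            cost=[1.0, 1.0, 1.0, 1.0],
            edges=[(0, 1, 1.0), (0, 2, 1.0), (1, 3, 1.0), (2, 3, 1.0)],
            outer=[2.0, 2.0, 2.0, 2.0],
            blm=1.0,
        )
        sol = Solution(frozenset({1}), 0.0, {}, {})
        assert objective(sol, prob) == pytest.approx(1.0 + 1.0 * 4.0)

    def test_blm0_spf0_reduces_to_selected_cost(self):
        rng = np.random.default_rng(4)
        for s in range(20):
            prob = random_problem(s)
            prob.blm = 0.0
            prob.spf[:] = 0.0
            avail = prob.pu_ids[prob.status == AVAILABLE]
            pick = frozenset(
                int(p) for p in avail[rng.random(len(avail)) < 0.5]
            ) | frozenset(int(p) for p in prob.pu_ids[prob.status == LOCKED_IN])
            sol = Solution(pick, 0.0, {}, {})
            idx = prob.index_of()
            expected = sum(
                prob.cost[idx[p]] for p in pick if prob.status[idx[p]] == AVAILABLE
            )
            assert objective(sol, prob) == pytest.approx(expected)

    def test_lock_violations_raise(self):
        prob = make_problem(
            2, amounts=[[1.0], [1.0]], targets=[1.0], spf=[1.0],
            status=[LOCKED_IN, LOCKED_OUT],
        )
        with pytest.raises(ValueError, match="locked-in"):
            objective(Solution(frozenset(), 0.0, {}, {}), prob)
        with pytest.raises(ValueError, match="locked-out"):
            objective(Solution(frozenset({1, 2}), 0.0, {}, {}), prob)


class TestBruteForce:
    def test_no_available_pus_returns_locked_in_only(self):
        prob = make_problem(
            2, amounts=[[1.0], [1.0]], targets=[1.0], spf=[1.0],
            status=[LOCKED_IN, LOCKED_OUT],
        )
        sol = brute_force_optimum(prob)
        assert sol.selected == frozenset({1})

    def test_selects_single_sufficient_pu(self):
        prob = make_problem(
            3, amounts=[[10.0], [20.0], [70.0]], targets=[70.0], spf=[1000.0], blm=0.0
        )
        sol = brute_force_optimum(prob)
        assert sol.selected == frozenset({3})

    def test_tie_break_prefers_smaller_set(self):
        prob = make_problem(
            3, amounts=np.zeros((3, 1)), targets=[0.0], spf=[5.0],
            cost=[0.0, 0.0, 0.0], blm=0.0,
        )
        assert brute_force_optimum(prob).selected == frozenset()

    def test_refuses_large_problems(self):
        prob = make_problem(25, np.zeros((25, 1)), [0.0], [1.0])
        with pytest.raises(ValueError, match="enumeration limit"):
            brute_force_optimum(prob)


class TestAnneal:
    def test_selects_obviously_essential_pu(self):
        prob = make_problem(
            3, amounts=[[0.0], [9.0], [0.0]], targets=[9.0], spf=[1e6], blm=0.0
        )
        sol = anneal(prob, AnnealSchedule(iterations=2000), seed=0)
        assert 2 in sol.selected
        assert sol.shortfall["s1"] == 0.0

    def test_never_worse_than_trivial_solutions(self):
        for s in range(10):
            prob = random_problem(s)
            locked_in = frozenset(int(p) for p in prob.pu_ids[prob.status == LOCKED_IN])
            full = locked_in | frozenset(
                int(p) for p in prob.pu_ids[prob.status == AVAILABLE]
            )
            sol = anneal(prob, AnnealSchedule(iterations=5000), seed=s)
            assert sol.objective_value <= objective(Solution(locked_in, 0, {}, {}), prob) + 1e-9
            assert sol.objective_value <= objective(Solution(full, 0, {}, {}), prob) + 1e-9

    def test_deterministic_per_seed(self):
        prob = random_problem(3)
        a = anneal(prob, AnnealSchedule(iterations=3000), seed=5)
        b = anneal(prob, AnnealSchedule(iterations=3000), seed=5)
        assert a.selected == b.selected
        assert a.objective_value == b.objective_value

    def test_all_locked_problem(self):
        prob = make_problem(
            2, amounts=[[1.0], [1.0]], targets=[1.0], spf=[1.0],
            status=[LOCKED_IN, LOCKED_IN],
        )
        sol = anneal(prob, seed=1)
        assert sol.selected == frozenset({1, 2})


class TestSelectionFrequency:
    def test_locked_in_frequency_one_locked_out_zero(self):
        prob = make_problem(
            3, amounts=[[1.0], [1.0], [1.0]], targets=[0.5], spf=[10.0],
            status=[LOCKED_IN, AVAILABLE, LOCKED_OUT],
        )
        freq = selection_frequency(prob, 10, seed=2, schedule=AnnealSchedule(iterations=500))
        assert freq[1] == 1.0
        assert freq[3] == 0.0
        assert ((freq >= 0) & (freq <= 1)).all()

    def test_essential_pu_always_selected(self):
        prob = make_problem(
            5,
            amounts=[[0.0], [0.0], [8.0], [0.0], [0.0]],
            targets=[8.0],
            spf=[1e6],
            blm=0.0,
        )
        freq = selection_frequency(prob, 20, seed=3, schedule=AnnealSchedule(iterations=2000))
        assert freq[3] == 1.0

    def test_raising_spf_never_hurts_sole_holder(self):
        """Paired-seed monotonicity of the essential PU's selection frequency."""

        def freq_with_spf(spf):
            prob = make_problem(
                5,
                amounts=[[0.0], [0.0], [6.0], [0.0], [0.0]],
                targets=[6.0],
                spf=[spf],
                cost=[1.0, 1.0, 3.0, 1.0, 1.0],
                blm=0.0,
            )
            return selection_frequency(
                prob, 30, seed=11, schedule=AnnealSchedule(iterations=1000)
            )[3]

        assert freq_with_spf(100.0) >= freq_with_spf(1.0)


class TestCalibrateSpf:
    def test_sufficient_spf_returns_all_ones(self):
        prob = make_problem(
            2, amounts=[[10.0], [0.0]], targets=[5.0], spf=[1.0],
            cost=[0.001, 0.001], blm=0.0,
        )
        spf = calibrate_spf(prob, n_restarts=5, schedule=AnnealSchedule(iterations=500))
        assert spf == {"s1": 1.0}

    def test_expensive_sole_holder_drives_spf_up(self):
        prob = make_problem(
            5,
            amounts=[[10.0], [0.0], [0.0], [0.0], [0.0]],
            targets=[10.0],
            spf=[1.0],
            cost=[3.0, 0.1, 0.1, 0.1, 0.1],
            blm=0.0,
        )
        spf = calibrate_spf(
            prob, n_restarts=10, max_rounds=8, multiplier=2.0, seed=1,
            schedule=AnnealSchedule(iterations=1000),
        )
        v = spf["s1"]
        assert v > 1.0
        assert abs(np.log2(v) - round(np.log2(v))) < 1e-9  # power of the multiplier

    def test_nonconvergence_warns(self):
        # target can never be met: no PU holds the species
        prob = make_problem(
            2, amounts=np.zeros((2, 1)), targets=[5.0], spf=[1.0], blm=0.0
        )
        with pytest.warns(UserWarning, match="did not converge"):
            calibrate_spf(
                prob, n_restarts=3, max_rounds=2,
                schedule=AnnealSchedule(iterations=200),
            )


class TestLockStatus:
    def _setup(self, built_cells, pa_cells):
        """4x4 grid of 1 km cells, 2x2-cell PUs (4 PUs of 4 km^2)."""
        reg_grid = uniform_grid(1, shape=(4, 4), cell_size=1.0)
        arr = reg_grid.classes.copy()
        built = reg_grid.registry.code_of("built")
        for (i, j) in built_cells:
            arr[i, j] = built
        grid = LandCoverGrid(arr, 1.0, reg_grid.registry)
        mask = np.zeros((4, 4), bool)
        for (i, j) in pa_cells:
            mask[i, j] = True
        pu = make_pu_grid(grid, pu_area=4.0)
        return pu, grid, ProtectedAreaMask(mask)

    def test_mostly_built_locked_out(self):
        # PU 1 (top-left 2x2 block): 3/4 built, 1/4 protected
        pu, grid, pas = self._setup(
            built_cells=[(0, 0), (0, 1), (1, 0)], pa_cells=[(1, 1)]
        )
        status = lock_status(pu, grid, pas)
        assert status[0] == LOCKED_OUT

    def test_mostly_protected_locked_in_with_precedence(self):
        # PU 1: 3/4 protected AND 3/4 built -> protection wins
        cells = [(0, 0), (0, 1), (1, 0)]
        pu, grid, pas = self._setup(built_cells=cells, pa_cells=cells)
        status = lock_status(pu, grid, pas)
        assert status[0] == LOCKED_IN

    def test_exactly_half_built_stays_available(self):
        pu, grid, pas = self._setup(built_cells=[(0, 0), (0, 1)], pa_cells=[])
        status = lock_status(pu, grid, pas)
        assert status[0] == AVAILABLE
        assert (status[1:] == AVAILABLE).all()
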