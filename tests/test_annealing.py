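"""Annealing schedule primitives, move engine and run-level contracts."""

import itertools
import random

import numpy as np
import pytest
from scipy.stats import ttest_ind

from spinanneal.annealing import (
    AnnealingParams,
    AssignmentState,
    equilibrate_at_T,
    metropolis_accept,
    next_sample_size,
    next_temperature,
    run_annealing,
    specific_heat,
)
from spinanneal.energy import total_energy


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = random.Random(0)
        assert all(metropolis_accept(-5.0, t, rng) for t in (1e-3, 1.0, 1e3))

    def test_acceptance_frequency_follows_boltzmann(self):
        rng = random.Random(42)
        t = 100.0
        for target in (0.5, 0.25):
            delta = -t * np.log(target)
            n = 20000
            hits = sum(metropolis_accept(delta, t, rng) for _ in range(n))
            # 4-sigma binomial window
            sigma = (target * (1 - target) / n) ** 0.5
            assert abs(hits / n - target) < 4 * sigma

    def test_huge_uphill_never_accepted(self):
        rng = random.Random(1)
        assert not any(metropolis_accept(1e6, 1.0, rng) for _ in range(1000))


class TestSchedule:
    def test_specific_heat_hand_value(self):
        # sample {-100, -200} at T=10: variance 2500, Cv = 2500/100 = 25
        assert specific_heat([-100.0, -200.0], 10.0) == pytest.approx(25.0)

    def test_specific_heat_constant_sample_is_zero(self):
        assert specific_heat([-7.0] * 10, 5.0) == 0.0

    def test_specific_heat_quarter_on_doubled_temperature(self):
        sample = [-10.0, -30.0, -20.0]
        assert specific_heat(sample, 20.0) == pytest.approx(specific_heat(sample, 10.0) / 4)

    def test_cooling_step_from_specific_heat(self):
        assert next_temperature(100.0, 400.0) == pytest.approx(95.0)

    def test_cooling_step_capped_at_ten(self):
        assert next_temperature(100.0, 50.0) == pytest.approx(90.0)
        assert next_temperature(100.0, 0.0) == pytest.approx(90.0)

    def test_cooling_step_vanishes_at_large_cv(self):
        assert next_temperature(100.0, 1e12) == pytest.approx(100.0, abs=1e-6)

    def test_sample_size_floor(self):
        assert next_sample_size(100, 100.0) == 10000

    def test_sample_size_ceiling(self):
        assert next_sample_size(371, 10000.0) == 100000

    def test_sample_size_zero_specific_heat(self):
        assert next_sample_size(50, 0.0) == 10000

    def test_sample_size_intermediate_value(self):
        n, dedt = 200, 700.0  # raw value falls between floor and ceiling
        expected = n * dedt**1.5 / 300
        assert next_sample_size(n, dedt) == int(expected)


class TestEquilibration:
    def test_identical_samples_equilibrate(self, problem20, fast_params):
        state = AssignmentState(problem20, fast_params, seed=0)
        sample, successes, fails, stalled = equilibrate_at_T(state, 1000.0, 200)
        assert len(sample) == 200
        assert not stalled

    def test_t_statistic_matches_hand_computation(self):
        # pooled two-sample t on {1,2,3} vs {2,3,4}: t = -sqrt(3/2), p = 0.2879
        res = ttest_ind([1, 2, 3], [2, 3, 4], equal_var=True)
        assert res.statistic == pytest.approx(-1.224744871391589)
        assert res.pvalue == pytest.approx(0.28786413472669053, abs=1e-12)

    def test_distinguishable_means_not_equilibrated(self):
        from spinanneal.annealing import _samples_indistinguishable

        falling = list(range(100, 0, -1))
        flat = [50.0 + (i % 3) for i in range(100)]
        assert not _samples_indistinguishable(falling[:50], falling[50:], 0.5, False)
        assert _samples_indistinguishable(flat, flat, 0.5, False)


class TestMoves:
    def test_incremental_energy_matches_full_recompute(self, problem30, fast_params):
        """10^4 random moves at several temperatures keep |E_tot - oracle| tiny."""
        state = AssignmentState(problem30, fast_params, seed=7)
        for t in (1000.0, 100.0, 10.0):
            for _ in range(3500):
                state.step(t)
            assert state.E_tot == pytest.approx(total_energy(state), abs=1e-6)
            assert state.E_tot == pytest.approx(state.recompute_energy(), abs=1e-9)

    def test_placement_bookkeeping_consistent(self, problem30, fast_params):
        state = AssignmentState(problem30, fast_params, seed=3)
        for _ in range(5000):
            state.step(50.0)
        placed = {s for s in range(state.M) if state.pos_of[s] >= 0}
        assert placed == set(state.placed)
        assert set(state.cached) == set(range(state.M)) - placed
        occupied = {state.pos_of[s] for s in placed}
        assert occupied == {n for n in state.allowed if n not in state.empty}
        # every spin system is either placed at exactly one residue or cached
        assert len(occupied) == len(placed)

    def test_peak_conservation_through_crosspeak_moves(self, fast_params):
        from spinanneal import AssignmentProblem, generate_dataset, predictions_from_truth

        truth = generate_dataset(length=14, seed=9, noise=0, degenerate_pairs=2)
        preds = predictions_from_truth(truth)
        problem = AssignmentProblem.from_peaks(truth.all_peaks, truth.sequence, preds)
        state = AssignmentState(problem, fast_params, seed=5)
        assert state.exchangeable_pool  # the stress fixture creates overlap groups
        n_total = len(truth.all_peaks)
        for t in (500.0, 50.0):
            for _ in range(4000):
                state.step(t)
            held = sum(len(ss.peaks) for ss in state.spin_systems)
            assert held + len(state.crosspeak_cache) == n_total
        assert state.E_tot == pytest.approx(total_energy(state), abs=1e-6)


class TestRuns:
    def test_same_seed_reproduces_trajectory(self, problem20, fast_params):
        a = run_annealing(problem20, fast_params, seed=11)
        b = run_annealing(problem20, fast_params, seed=11)
        assert a.placement == b.placement
        assert a.E_tot == b.E_tot
        assert a.history == b.history

    def test_minimization_monotone_and_idempotent(self, problem20, fast_params):
        state = AssignmentState(problem20, fast_params, seed=2)
        e0 = state.E_tot
        state.local_minimize(100)
        e1 = state.E_tot
        assert e1 <= e0
        state.local_minimize(100)
        assert state.E_tot == pytest.approx(e1, abs=1e-9)

    def test_trivial_problem_reaches_global_minimum(self, fast_params):
        """3 residues with exact predictions: exhaustive enumeration agrees."""
        from spinanneal import (
            AssignmentProblem,
            ShiftPrediction,
            generate_dataset,
        )

        truth = generate_dataset(sequence="AKV", seed=21, noise=0)
        preds = [
            ShiftPrediction(n, res, value, 0.5)
            for n, per in truth.shifts.items()
            for res, value in per.items()
        ]
        problem = AssignmentProblem.from_peaks(truth.all_peaks, truth.sequence, preds)
        state = run_annealing(problem, fast_params, seed=1)
        assert state.E_tot == pytest.approx(_brute_force_minimum(problem), abs=1e-6)
        # the minimum is the true assignment
        systems = {ss.uid: ss for ss in state.spin_systems}
        for n, uid in state.placement.items():
            h, n15 = truth.reference[n]
            assert abs(systems[uid].amide_h - h) < 0.03

    def test_final_energy_not_above_initial(self, problem20, fast_params):
        initial = AssignmentState(problem20, fast_params, seed=13).E_tot
        final = run_annealing(problem20, fast_params, seed=13).E_tot
        assert final <= initial


def _brute_force_minimum(problem):
    """Exhaustive search over placements, cache subsets and type sets."""
    from spinanneal.energy import (
        chemical_shift_energy,
        posterior_matrix,
        adjacency_energy,
    )

    systems = [ss for g in problem.groups for ss in g.members]
    n_res = len(problem.sequence)
    params = problem.energy_params
    positions = [n for n in range(1, n_res + 1) if problem.sequence[n - 1] != "P"]

    ecs = {}
    for si, ss in enumerate(systems):
        pm = posterior_matrix(ss, problem.predictions, problem.sequence, params)
        for tsi in range(ss.n_type_sets):
            for n in positions:
                ecs[(si, tsi, n)] = chemical_shift_energy(
                    float(pm.posterior[tsi, n]), ss.n_type_sets, n_res, params
                )

    best = 0.0  # everything cached
    ts_choices = [range(ss.n_type_sets) for ss in systems]
    for k in range(1, min(len(systems), len(positions)) + 1):
        for subset in itertools.combinations(range(len(systems)), k):
            for pos_subset in itertools.combinations(positions, k):
                for perm in itertools.permutations(pos_subset):
                    for ts_combo in itertools.product(*[ts_choices[s] for s in subset]):
                        placed = dict(zip(perm, zip(subset, ts_combo)))
                        e = 0.0
                        for n, (si, tsi) in placed.items():
                            e += ecs[(si, tsi, n)]
                            nxt = placed.get(n + 1)
                            if nxt is not None:
                                e += adjacency_energy(
                                    systems[si].type_sets[tsi].mean_shifts,
                                    systems[nxt[0]].type_sets[nxt[1]].mean_shifts,
                                    params,
                                )
                        best = min(best, e)
    return best
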