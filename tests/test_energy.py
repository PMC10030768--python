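"""Adjacency energy, chi-square likelihood, posterior and energy composition."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from spinanneal.assembly import assemble_spin_systems
from spinanneal.energy import (
    EnergyParams,
    ShiftPredictionSet,
    adjacency_energy,
    adjacency_term,
    chemical_shift_energy,
    chi_square_statistic,
    likelihood,
    posterior_matrix,
    total_energy,
)
from spinanneal.io import CrossPeak, ShiftPrediction
from spinanneal.spectra import get_spectrum

PARAMS = EnergyParams()


def preds_from(entries, n):
    return ShiftPredictionSet(
        [ShiftPrediction(i, r, d, s) for i, r, d, s in entries], n
    )


class TestAdjacency:
    def test_perfect_match_scores_minus_fifty(self):
        assert adjacency_term(0.0, PARAMS) == pytest.approx(-50.0)

    def test_mismatch_limit_is_plus_fifty(self):
        assert adjacency_term(1e3, PARAMS) == pytest.approx(50.0, abs=1e-6)

    def test_zero_crossing_at_two_tenths_ppm(self):
        assert adjacency_term(0.2, PARAMS) == pytest.approx(0.0, abs=1e-9)

    def test_missing_resonance_contributes_zero(self):
        e = adjacency_energy({"CA": 55.0, "CO": 177.0}, {"CA-1": 55.0}, PARAMS)
        assert e == pytest.approx(-50.0)  # only the CA/CA-1 pair counts

    def test_three_perfect_matches(self):
        m = {"CA": 55.0, "CB": 30.0, "CO": 177.0}
        l = {"CA-1": 55.0, "CB-1": 30.0, "CO-1": 177.0}
        assert adjacency_energy(m, l, PARAMS) == pytest.approx(-150.0)

    def test_bounds_per_shared_resonance_count(self):
        m = {"CA": 55.0, "CB": 30.0}
        l = {"CA-1": 54.8, "CB-1": 31.0}
        e = adjacency_energy(m, l, PARAMS)
        k = 2
        assert k * (PARAMS.c0 + PARAMS.c1) <= e <= k * PARAMS.c1


class TestLikelihood:
    def test_zero_residuals_give_one(self):
        preds = preds_from([(1, "CA", 55.0, 1.0), (1, "CB", 30.0, 1.0)], 2)
        assert likelihood({"CA": 55.0, "CB": 30.0}, preds, 1) == pytest.approx(1.0)

    def test_chi2_two_degrees_closed_form(self):
        # X² = 2 with R = 2: survival probability is exp(-1)
        preds = preds_from([(1, "CA", 55.0, 1.0), (1, "CB", 30.0, 1.0)], 2)
        obs = {"CA": 56.0, "CB": 31.0}
        x2, r = chi_square_statistic(obs, preds, 1)
        assert (x2, r) == (pytest.approx(2.0), 2)
        assert likelihood(obs, preds, 1) == pytest.approx(math.exp(-1.0))

    def test_chi2_one_degree_matches_normal_tail(self):
        # X² = 1 with R = 1 equals the two-sided normal tail 2(1 - Φ(1))
        preds = preds_from([(1, "CA", 55.0, 0.5)], 1)
        p = likelihood({"CA": 55.5}, preds, 1)
        assert p == pytest.approx(2 * (1 - norm.cdf(1.0)), abs=1e-9)

    def test_prev_resonances_compared_to_predecessor(self):
        preds = preds_from([(1, "CA", 50.0, 1.0), (2, "CA", 60.0, 1.0)], 2)
        x2, r = chi_square_statistic({"CA-1": 50.0}, preds, 2)
        assert (x2, r) == (0.0, 1)
        # at n=1 there is no predecessor: excluded from R
        x2, r = chi_square_statistic({"CA-1": 50.0}, preds, 1)
        assert (x2, r) == (0.0, 0)

    def test_no_copresent_resonances_is_neutral(self):
        preds = preds_from([(1, "CA", 50.0, 1.0)], 1)
        assert likelihood({"CB": 30.0}, preds, 1) == 1.0

    def test_monotone_in_residual(self):
        preds = preds_from([(1, "CA", 55.0, 1.0)], 1)
        values = [likelihood({"CA": 55.0 + d}, preds, 1) for d in (0.0, 0.5, 1.0, 2.0)]
        assert values == sorted(values, reverse=True)


def _one_peak_system(h, n15, ca):
    groups = assemble_spin_systems(
        [CrossPeak("p1", get_spectrum("HNCA"), (h, n15, ca))]
    )
    return groups[0].members[0]


class TestPosterior:
    def test_prior_masks_prolines(self):
        ss = _one_peak_system(8.2, 119.0, 56.0)
        preds = preds_from(
            [(1, "CA", 55.0, 1.0), (3, "CA", 45.0, 1.0)], 3
        )
        pm = posterior_matrix(ss, preds, "APG", PARAMS)
        assert pm.C == 2 * len(ss.type_sets)
        assert np.all(pm.prior[:, 2] == 0.0)
        assert pm.prior.sum() == pytest.approx(1.0)

    def test_uniform_likelihood_returns_prior(self):
        ss = _one_peak_system(8.2, 119.0, 56.0)
        # no carbon predictions at all: every likelihood is 1
        preds = preds_from([], 3)
        pm = posterior_matrix(ss, preds, "AAA", PARAMS)
        assert np.allclose(pm.posterior, pm.prior)

    def test_posterior_concentrates_on_matching_position(self):
        ss = _one_peak_system(8.2, 119.0, 56.0)
        preds = preds_from(
            [(1, "CA", 56.0, 0.1), (2, "CA", 30.0, 0.1), (3, "CA", 70.0, 0.1)], 3
        )
        pm = posterior_matrix(ss, preds, "AAA", PARAMS)
        best = np.unravel_index(np.argmax(pm.posterior), pm.posterior.shape)
        assert best[1] == 1
        assert pm.posterior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_posterior_normalizes(self, problem30):
        for g in problem30.groups:
            for ss in g.members:
                pm = posterior_matrix(ss, problem30.predictions, problem30.sequence, PARAMS)
                assert pm.posterior.sum() == pytest.approx(1.0, abs=1e-9)


class TestChemicalShiftEnergy:
    def test_certain_assignment_scores_e_min(self):
        assert chemical_shift_energy(1.0, 2, 100, PARAMS) == pytest.approx(-50.0)

    def test_impossible_assignment_clamps_to_e_max(self):
        assert chemical_shift_energy(0.0, 2, 100, PARAMS) == 100.0
        assert chemical_shift_energy(1e-300, 2, 100, PARAMS) == 100.0

    def test_uninformative_probability_scores_zero(self):
        i_m, n = 4, 75
        assert chemical_shift_energy(1.0 / (i_m * n), i_m, n, PARAMS) == pytest.approx(0.0)

    def test_single_possible_assignment_degenerate(self):
        assert chemical_shift_energy(1.0, 1, 1, PARAMS) == PARAMS.e_cs_min

    @pytest.mark.parametrize("p", [0.0, 1e-12, 1e-3, 0.2, 0.5, 0.9, 1.0])
    def test_bounds(self, p):
        e = chemical_shift_energy(p, 3, 60, PARAMS)
        assert PARAMS.e_cs_min - 1e-9 <= e <= PARAMS.e_cs_max + 1e-9


class TestTotalEnergy:
    def test_all_cached_is_zero(self, problem20):
        from spinanneal.annealing import AssignmentState

        state = AssignmentState(problem20, seed=0, initialize=False)
        assert total_energy(state) == 0.0
        assert state.recompute_energy() == 0.0

    def test_single_placed_system_has_no_adjacency(self, problem20):
        from spinanneal.annealing import AssignmentState

        state = AssignmentState(problem20, seed=0, initialize=False)
        ss = state.spin_systems[0]
        state._place(0, 3, 0)
        pm = posterior_matrix(ss, problem20.predictions, problem20.sequence, PARAMS)
        expected = chemical_shift_energy(
            float(pm.posterior[0, 3]), ss.n_type_sets, state.N, PARAMS
        )
        assert total_energy(state) == pytest.approx(expected)
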