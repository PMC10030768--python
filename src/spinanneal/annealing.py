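"""Metropolis simulated annealing over assignment states.

The search state maps spin systems to residue positions (or to a cache).
Moves relocate, swap or cache spin systems, flip their resonance type set in
place, or (with small probability) exchange individual crosspeaks between
amide-degenerate spin systems.  Temperature starts at 1000 and is lowered
along a specific-heat-guided schedule: at each temperature the system is
equilibrated (consecutive energy samples compared by a two-sample t-test),
the specific heat d⟨E⟩/dT is estimated from the energy variance, and the next
temperature is chosen to target a fixed mean-energy drop, with the step
capped at 10 units.  Annealing ends when the temperature falls below 1, when
T·Cv drops below 200, or when swaps almost never succeed; a greedy local
minimization pass then refines the final state.

Energy bookkeeping is incremental: every move touches only the affected
residues, and :func:`spinanneal.energy.total_energy` recomputes the total
from scratch as an independent check.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass

import numpy as np
from scipy.stats import ttest_ind

from .assembly import SpinSystemGroup, assemble_spin_systems
from .energy import (
    DEFAULT_ENERGY_PARAMS,
    EnergyParams,
    ShiftPredictionSet,
    chemical_shift_energy_row,
    possible_mask,
    posterior_matrix,
)
from .spectra import DEFAULT_TOLERANCES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnealingParams:
    """Schedule and move-set constants of the annealing engine."""

    t0: float = 1000.0
    delta_e_target: float = -2000.0  # targeted mean-energy drop per cooling step
    max_t_step: float = 10.0
    p_equil: float = 0.5  # t-test p-value above which the system is equilibrated
    crosspeak_move_prob: float = 0.01
    sample_divisor: float = 300.0
    sample_exponent: float = 1.5
    sample_floor: int = 10000
    sample_ceiling: int = 100000
    t_min: float = 1.0
    t_cv_min: float = 200.0
    # the T·Cv criterion estimates the residual energy above the ground state,
    # which is only meaningful once the system is cold; checking it near T0
    # would stop small problems before any annealing happens
    t_cv_check_below: float = 100.0
    fail_ratio: float = 10000.0
    n_minimize: int = 100
    welch: bool = False  # pooled-variance Student's t by default
    use_crosspeak_cache: bool = False
    max_fails_per_sample: int = 5_000_000  # numeric safety valve

    def __post_init__(self):
        if self.delta_e_target >= 0:
            raise ValueError("delta_e_target must be negative")
        for name in ("t0", "max_t_step", "p_equil", "sample_floor", "t_min", "t_cv_min", "fail_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_ANNEALING_PARAMS = AnnealingParams()


# ---------------------------------------------------------------------------
# schedule primitives


def metropolis_accept(delta_e: float, t: float, rng: random.Random) -> bool:
    """Accept a proposed move: always for ΔE ≤ 0, else with prob exp(−ΔE/T)."""
    if delta_e <= 0:
        return True
    x = delta_e / t
    if x > 700.0:  # exp underflow
        return False
    return rng.random() <= math.exp(-x)


def specific_heat(sample, t: float) -> float:
    """d⟨E⟩/dT estimate (⟨E²⟩ − ⟨E⟩²)/T² with population moments."""
    arr = np.asarray(sample, dtype=float)
    return float((arr * arr).mean() - arr.mean() ** 2) / (t * t)


def next_temperature(t: float, cv: float, params: AnnealingParams = DEFAULT_ANNEALING_PARAMS) -> float:
    """Cooling step targeting the configured mean-energy drop, capped at 10."""
    if cv > 0:
        drop = -params.delta_e_target / cv
    else:
        drop = params.max_t_step
    return t - min(drop, params.max_t_step)


def next_sample_size(n_residues: int, dedt: float, params: AnnealingParams = DEFAULT_ANNEALING_PARAMS) -> int:
    """Equilibration sample size scaled by specific heat and protein size."""
    raw = n_residues * dedt ** params.sample_exponent / params.sample_divisor
    return int(min(max(raw, params.sample_floor), params.sample_ceiling))


# ---------------------------------------------------------------------------
# the assignment problem


class AssignmentProblem:
    """Immutable inputs of one assignment run."""

    def __init__(
        self,
        sequence: str,
        groups: list[SpinSystemGroup],
        predictions,
        energy_params: EnergyParams = DEFAULT_ENERGY_PARAMS,
        tolerances: dict[str, float] | None = None,
    ):
        self.sequence = sequence
        self.groups = groups
        self.energy_params = energy_params
        self.tolerances = {**DEFAULT_TOLERANCES, **(tolerances or {})}
        if isinstance(predictions, ShiftPredictionSet):
            self.predictions = predictions
        else:
            self.predictions = ShiftPredictionSet(predictions, len(sequence))

    @classmethod
    def from_peaks(
        cls,
        peaks,
        sequence: str,
        predictions,
        energy_params: EnergyParams = DEFAULT_ENERGY_PARAMS,
        tolerances: dict[str, float] | None = None,
        cache_low_intensity: bool = False,
    ) -> "AssignmentProblem":
        tol = {**DEFAULT_TOLERANCES, **(tolerances or {})}
        groups = assemble_spin_systems(peaks, tol, cache_low_intensity)
        return cls(sequence, groups, predictions, energy_params, tol)

    @property
    def n_peaks(self) -> int:
        return sum(len(ss.peaks) for g in self.groups for ss in g.members)


# ---------------------------------------------------------------------------
# the mutable annealing state


class AssignmentState:
    """Mutable residue ↔ spin-system mapping with incremental energy."""

    def __init__(
        self,
        problem: AssignmentProblem,
        anneal_params: AnnealingParams = DEFAULT_ANNEALING_PARAMS,
        seed: int = 0,
        initialize: bool = True,
    ):
        self.problem = problem
        self.anneal_params = anneal_params
        self.energy_params = problem.energy_params
        self.sequence = problem.sequence
        self.predictions = problem.predictions
        self.tolerances = problem.tolerances
        self.N = len(problem.sequence)
        self.seed = seed
        self.rng = random.Random(seed)
        self.history: list[dict] = []

        # per-run copies so crosspeak exchanges cannot leak between runs
        self.groups = [g.clone() for g in problem.groups]
        self.spin_systems = [ss for g in self.groups for ss in g.members]
        self.M = len(self.spin_systems)
        self._ss_index = {id(ss): i for i, ss in enumerate(self.spin_systems)}

        self.pos_of = [-1] * self.M  # residue or -1 (cached)
        self.ts_of = [0] * self.M  # active type-set index
        self.occ_flat = [-1] * (self.N + 2)  # flat (ss, ts) id per residue
        self.occ_ss = [-1] * (self.N + 2)

        self.allowed = [n for n in range(1, self.N + 1) if self.sequence[n - 1] != "P"]
        self.check_mask = problem.energy_params.glycine_rule

        # crosspeak exchange machinery
        self.crosspeak_cache: list = []
        self._index_peaks()

        self._row_cache: dict = {}  # (s, version, tsi) -> (ecs row, adj vecs, mask)
        self._ts_cache: dict = {}  # peak membership -> enumerated type sets
        self._build_tables()

        # bookkeeping lists with O(1) removal
        self.empty: list[int] = []
        self._empty_idx = [-1] * (self.N + 2)
        self.placed: list[int] = []
        self._placed_idx = [-1] * self.M
        self.cached: list[int] = []
        self._cached_idx = [-1] * self.M
        for n in self.allowed:
            self._ladd(self.empty, self._empty_idx, n)
        for s in range(self.M):
            self._ladd(self.cached, self._cached_idx, s)

        self.E_tot = 0.0
        if initialize:
            self.random_init()

    # -- bookkeeping helpers ------------------------------------------------
    @staticmethod
    def _ladd(lst, idx, x):
        idx[x] = len(lst)
        lst.append(x)

    @staticmethod
    def _lremove(lst, idx, x):
        i = idx[x]
        last = lst[-1]
        lst[i] = last
        idx[last] = i
        lst.pop()
        idx[x] = -1

    def _index_peaks(self):
        self.peak_owner: dict[int, object] = {}
        self.group_of_peak: dict[int, SpinSystemGroup] = {}
        pool = []
        for g in self.groups:
            for ss in g.members:
                for p in ss.peaks:
                    self.peak_owner[id(p)] = ss
                    self.group_of_peak[id(p)] = g
            pool.extend(g.exchangeable_peaks)
        if self.anneal_params.use_crosspeak_cache:
            seen = {id(p) for p in pool}
            for g in self.groups:
                for ss in g.members:
                    for p in ss.peaks:
                        if p.cache_eligible and id(p) not in seen:
                            pool.append(p)
                            seen.add(id(p))
        self.exchangeable_pool = pool

    # -- energy tables ------------------------------------------------------
    def _flat_rows(self, s: int, tsi: int):
        """Cached (ecs row, adjacency shift vectors, placement mask) per flat."""
        ss = self.spin_systems[s]
        key = (s, ss.version, tsi)
        hit = self._row_cache.get(key)
        if hit is not None:
            return hit
        params = self.energy_params
        pm = posterior_matrix(ss, self.predictions, self.sequence, params)
        row = chemical_shift_energy_row(pm.posterior[tsi], ss.n_type_sets, self.N, params).tolist()
        msh = ss.type_sets[tsi].mean_shifts
        cur = [msh.get("CA", math.nan), msh.get("CB", math.nan), msh.get("CO", math.nan)]
        prv = [msh.get("CA-1", math.nan), msh.get("CB-1", math.nan), msh.get("CO-1", math.nan)]
        mask = (
            possible_mask(ss, self.sequence, True)[tsi].tolist() if self.check_mask else None
        )
        if len(self._row_cache) > 20000:
            self._row_cache.clear()
        out = (row, cur, prv, mask)
        self._row_cache[key] = out
        return out

    def _build_tables(self):
        """Flat (spin system, type set) tables for O(1) energy lookups."""
        flats: list[tuple[int, int]] = []
        self.flat_base = []
        for s, ss in enumerate(self.spin_systems):
            self.flat_base.append(len(flats))
            for i in range(ss.n_type_sets):
                flats.append((s, i))
        self.flats = flats
        self.i_counts = [ss.n_type_sets for ss in self.spin_systems]
        self.ecs = []
        self.mask = []
        cur = np.empty((len(flats), 3))
        prv = np.empty((len(flats), 3))
        for a, (s, i) in enumerate(flats):
            row, c, p, m = self._flat_rows(s, i)
            self.ecs.append(row)
            self.mask.append(m)
            cur[a] = c
            prv[a] = p
        self._cur = cur
        self._prv = prv
        self._rebuild_adj()

    def _rebuild_adj(self):
        params = self.energy_params
        d = self._cur[:, None, :] - self._prv[None, :, :]
        missing = np.isnan(d)
        d[missing] = 0.0
        d *= 1.0 / params.sigma_k
        d *= d
        term = np.exp(-0.5 * d)
        term *= params.c0
        term += params.c1
        term[missing] = 0.0
        self.adj = term.sum(axis=2).tolist()

    def _adj_vec(self, cur_row, prv_all):
        """One adjacency row/column against all flats."""
        params = self.energy_params
        d = cur_row - prv_all
        missing = np.isnan(d)
        d[missing] = 0.0
        d *= 1.0 / params.sigma_k
        d *= d
        term = np.exp(-0.5 * d)
        term *= params.c0
        term += params.c1
        term[missing] = 0.0
        return term.sum(axis=1)

    def _update_ss_tables(self, s: int):
        """Refresh one spin system's rows in place (type-set count unchanged)."""
        base = self.flat_base[s]
        k = len(self.flats)
        adj = self.adj
        for i in range(self.spin_systems[s].n_type_sets):
            a = base + i
            row, c, p, m = self._flat_rows(s, i)
            self.ecs[a] = row
            self.mask[a] = m
            self._cur[a] = c
            self._prv[a] = p
            adj[a] = self._adj_vec(self._cur[a][None, :], self._prv).tolist()
            col = self._adj_vec(self._cur, self._prv[a][None, :]).tolist()
            for b in range(k):
                adj[b][a] = col[b]

    def _rebuild_occ(self):
        self.occ_flat = [-1] * (self.N + 2)
        self.occ_ss = [-1] * (self.N + 2)
        for s in range(self.M):
            n = self.pos_of[s]
            if n >= 0:
                self.occ_flat[n] = self.flat_base[s] + self.ts_of[s]
                self.occ_ss[n] = s

    # -- placement primitives ----------------------------------------------
    def _place(self, s: int, n: int, tsi: int):
        self.occ_flat[n] = self.flat_base[s] + tsi
        self.occ_ss[n] = s
        self.pos_of[s] = n
        self.ts_of[s] = tsi

    def _clear(self, n: int):
        s = self.occ_ss[n]
        self.occ_flat[n] = -1
        self.occ_ss[n] = -1
        self.pos_of[s] = -1

    def _e_at(self, n: int) -> float:
        a = self.occ_flat[n]
        if a < 0:
            return 0.0
        e = self.ecs[a][n]
        b = self.occ_flat[n + 1]
        if b >= 0:
            e += self.adj[a][b]
        return e

    def _e_local(self, positions) -> float:
        total = 0.0
        n_res = self.N
        for n in positions:
            if 1 <= n <= n_res:
                total += self._e_at(n)
        return total

    def recompute_energy(self) -> float:
        """Sum of per-residue energies from the fast tables."""
        return self._e_local(range(1, self.N + 1))

    def iter_placements(self):
        """Yield (residue, (spin system, active type-set index)) pairs."""
        for s in range(self.M):
            n = self.pos_of[s]
            if n >= 0:
                yield n, (self.spin_systems[s], self.ts_of[s])

    @property
    def placement(self) -> dict[int, str]:
        """residue -> spin-system uid for placed systems."""
        return {n: ss.uid for n, (ss, _) in self.iter_placements()}

    def random_init(self):
        """Random placement at T0; excess spin systems go to the cache."""
        rng = self.rng
        order = list(range(self.M))
        rng.shuffle(order)
        positions = rng.sample(self.allowed, min(self.M, len(self.allowed)))
        for s, n in zip(order, positions):
            tsi = rng.randrange(self.spin_systems[s].n_type_sets)
            if self.check_mask and not self.mask[self.flat_base[s] + tsi][n]:
                choices = [
                    i
                    for i in range(self.spin_systems[s].n_type_sets)
                    if self.mask[self.flat_base[s] + i][n]
                ]
                if not choices:
                    continue  # stays cached
                tsi = choices[rng.randrange(len(choices))]
            self._place(s, n, tsi)
            self._lremove(self.empty, self._empty_idx, n)
            self._lremove(self.cached, self._cached_idx, s)
            self._ladd(self.placed, self._placed_idx, s)
        self.E_tot = self.recompute_energy()

    # -- single Metropolis step --------------------------------------------
    def step(self, t: float) -> int:
        """Propose and possibly apply one move; returns 1 on success."""
        if self.exchangeable_pool and self.rng.random() < self.anneal_params.crosspeak_move_prob:
            return self._crosspeak_step(t)
        return self._spin_step(t)

    def _spin_step(self, t: float) -> int:
        # hot path: local bindings, inlined energy and Metropolis evaluation
        rng_random = self.rng.random
        occ = self.occ_flat
        ecs = self.ecs
        adj = self.adj
        empty = self.empty
        placed = self.placed
        n_res = self.N
        exp = math.exp

        pos_of = self.pos_of
        s = int(rng_random() * self.M)
        n1 = pos_of[s]
        i_counts = self.i_counts
        i_s = i_counts[s]
        base = self.flat_base[s]

        if n1 >= 0:
            n_kinds = 1 + (1 if empty else 0) + (1 if len(placed) >= 2 else 0) + (1 if i_s > 1 else 0)
            draw = int(rng_random() * n_kinds)
            kind = 2  # cache always legal
            if empty:
                if draw == 0:
                    kind = 0
                draw -= 1
            if len(placed) >= 2:
                if draw == 0:
                    kind = 1
                draw -= 1
            if i_s > 1 and draw == 0:
                kind = 3
        else:
            has_place = 1 if empty else 0
            has_swap = 1 if placed else 0
            n_kinds = has_place + has_swap
            if n_kinds == 0:
                return 0
            draw = int(rng_random() * n_kinds)
            kind = 4 if (has_place and draw == 0) else 5

        if kind == 0:  # relocate to an empty position
            n2 = empty[int(rng_random() * len(empty))]
            tsi2 = int(rng_random() * i_s)
            flat2 = base + tsi2
            if self.check_mask and not self.mask[flat2][n2]:
                return 0
            old_flat = occ[n1]
            pos = {n1 - 1, n1, n2 - 1, n2}
            before = 0.0
            for n in pos:
                if 1 <= n <= n_res:
                    a = occ[n]
                    if a >= 0:
                        before += ecs[a][n]
                        b = occ[n + 1]
                        if b >= 0:
                            before += adj[a][b]
            occ[n1] = -1
            occ[n2] = flat2
            after = 0.0
            for n in pos:
                if 1 <= n <= n_res:
                    a = occ[n]
                    if a >= 0:
                        after += ecs[a][n]
                        b = occ[n + 1]
                        if b >= 0:
                            after += adj[a][b]
            d_e = after - before
            if d_e <= 0 or (d_e < 700.0 * t and rng_random() <= exp(-d_e / t)):
                self.occ_ss[n2] = s
                self.occ_ss[n1] = -1
                self.pos_of[s] = n2
                self.ts_of[s] = tsi2
                self.E_tot += d_e
                self._lremove(empty, self._empty_idx, n2)
                self._ladd(empty, self._empty_idx, n1)
                return 1
            occ[n1] = old_flat
            occ[n2] = -1
            return 0

        if kind == 1:  # swap two placed systems
            l = placed[int(rng_random() * len(placed))]
            while l == s:
                l = placed[int(rng_random() * len(placed))]
            n2 = self.pos_of[l]
            i_l = i_counts[l]
            tsi_s = int(rng_random() * i_s)
            tsi_l = int(rng_random() * i_l)
            flat_s = base + tsi_s
            flat_l = self.flat_base[l] + tsi_l
            if self.check_mask and (not self.mask[flat_s][n2] or not self.mask[flat_l][n1]):
                return 0
            old_s_flat = occ[n1]
            old_l_flat = occ[n2]
            pos = {n1 - 1, n1, n2 - 1, n2}
            before = 0.0
            for n in pos:
                if 1 <= n <= n_res:
                    a = occ[n]
                    if a >= 0:
                        before += ecs[a][n]
                        b = occ[n + 1]
                        if b >= 0:
                            before += adj[a][b]
            occ[n1] = flat_l
            occ[n2] = flat_s
            after = 0.0
            for n in pos:
                if 1 <= n <= n_res:
                    a = occ[n]
                    if a >= 0:
                        after += ecs[a][n]
                        b = occ[n + 1]
                        if b >= 0:
                            after += adj[a][b]
            d_e = after - before
            if d_e <= 0 or (d_e < 700.0 * t and rng_random() <= exp(-d_e / t)):
                self.occ_ss[n1] = l
                self.occ_ss[n2] = s
                self.pos_of[s] = n2
                self.pos_of[l] = n1
                self.ts_of[s] = tsi_s
                self.ts_of[l] = tsi_l
                self.E_tot += d_e
                return 1
            occ[n1] = old_s_flat
            occ[n2] = old_l_flat
            return 0

        if kind == 2:  # move to the spin-system cache
            old_flat = occ[n1]
            before = ecs[old_flat][n1]
            b = occ[n1 + 1]
            if b >= 0:
                before += adj[old_flat][b]
            p = occ[n1 - 1]
            if p >= 0:
                before += adj[p][old_flat]
            d_e = -before
            if d_e <= 0 or (d_e < 700.0 * t and rng_random() <= exp(-d_e / t)):
                occ[n1] = -1
                self.occ_ss[n1] = -1
                self.pos_of[s] = -1
                self.E_tot += d_e
                self._ladd(empty, self._empty_idx, n1)
                self._lremove(placed, self._placed_idx, s)
                self._ladd(self.cached, self._cached_idx, s)
                return 1
            return 0

        if kind == 3:  # type-set change in place
            old_tsi = self.ts_of[s]
            tsi2 = int(rng_random() * (i_s - 1))
            if tsi2 >= old_tsi:
                tsi2 += 1
            flat2 = base + tsi2
            if self.check_mask and not self.mask[flat2][n1]:
                return 0
            old_flat = occ[n1]
            before = ecs[old_flat][n1]
            after = ecs[flat2][n1]
            b = occ[n1 + 1]
            if b >= 0:
                before += adj[old_flat][b]
                after += adj[flat2][b]
            p = occ[n1 - 1]
            if p >= 0:
                before += adj[p][old_flat]
                after += adj[p][flat2]
            d_e = after - before
            if d_e <= 0 or (d_e < 700.0 * t and rng_random() <= exp(-d_e / t)):
                occ[n1] = flat2
                self.ts_of[s] = tsi2
                self.E_tot += d_e
                return 1
            return 0

        if kind == 4:  # place from the cache
            n2 = empty[int(rng_random() * len(empty))]
            tsi = int(rng_random() * i_s)
            flat2 = base + tsi
            if self.check_mask and not self.mask[flat2][n2]:
                return 0
            after = ecs[flat2][n2]
            b = occ[n2 + 1]
            if b >= 0:
                after += adj[flat2][b]
            p = occ[n2 - 1]
            if p >= 0:
                after += adj[p][flat2]
            d_e = after
            if d_e <= 0 or (d_e < 700.0 * t and rng_random() <= exp(-d_e / t)):
                occ[n2] = flat2
                self.occ_ss[n2] = s
                self.pos_of[s] = n2
                self.ts_of[s] = tsi
                self.E_tot += d_e
                self._lremove(empty, self._empty_idx, n2)
                self._lremove(self.cached, self._cached_idx, s)
                self._ladd(placed, self._placed_idx, s)
                return 1
            return 0

        # kind == 5: cached s replaces placed l, which is cached in turn
        l = placed[int(rng_random() * len(placed))]
        n2 = self.pos_of[l]
        tsi = int(rng_random() * i_s)
        flat2 = base + tsi
        if self.check_mask and not self.mask[flat2][n2]:
            return 0
        old_flat = occ[n2]
        before = ecs[old_flat][n2]
        after = ecs[flat2][n2]
        b = occ[n2 + 1]
        if b >= 0:
            before += adj[old_flat][b]
            after += adj[flat2][b]
        p = occ[n2 - 1]
        if p >= 0:
            before += adj[p][old_flat]
            after += adj[p][flat2]
        d_e = after - before
        if d_e <= 0 or (d_e < 700.0 * t and rng_random() <= exp(-d_e / t)):
            occ[n2] = flat2
            self.occ_ss[n2] = s
            self.pos_of[s] = n2
            self.ts_of[s] = tsi
            self.pos_of[l] = -1
            self.E_tot += d_e
            self._lremove(self.cached, self._cached_idx, s)
            self._ladd(placed, self._placed_idx, s)
            self._lremove(placed, self._placed_idx, l)
            self._ladd(self.cached, self._cached_idx, l)
            return 1
        return 0

    # -- crosspeak moves ----------------------------------------------------
    def _affected_positions(self, systems) -> set[int]:
        pos = set()
        for ss in systems:
            n = self.pos_of[self._ss_index[id(ss)]]
            if n >= 0:
                pos.add(n)
                pos.add(n - 1)
        return pos

    def _crosspeak_step(self, t: float) -> int:
        rng = self.rng
        pool = self.exchangeable_pool
        p = pool[rng.randrange(len(pool))]
        owner = self.peak_owner.get(id(p))
        group = self.group_of_peak[id(p)]
        use_cache = self.anneal_params.use_crosspeak_cache

        ops = []
        others = partners = None
        if owner is None:
            ops.append("uncache")
        else:
            others = [ss for ss in group.members if ss is not owner]
            if others and len(owner.peaks) > 1:
                ops.append("move")
            partners = [
                q
                for q in group.exchangeable_peaks
                if self.peak_owner.get(id(q)) not in (None, owner)
            ]
            if partners:
                ops.append("swap")
            if use_cache and p.cache_eligible and len(owner.peaks) > 1:
                ops.append("cache")
        if not ops:
            return 0
        op = ops[rng.randrange(len(ops))]

        if op == "move":
            target = others[rng.randrange(len(others))]
        elif op == "swap":
            target = partners[rng.randrange(len(partners))]
        elif op == "cache":
            target = None
        else:  # uncache: offer to a random group member
            target = group.members[rng.randrange(len(group.members))]
        return self._crosspeak_attempt(p, op, target, t=t)

    def _crosspeak_attempt(self, p, op, target, t=None, greedy=False) -> int:
        """Move/swap/cache one crosspeak; clash-rejected outright.

        ``greedy`` accepts only energy decreases (local minimization); else
        the Metropolis criterion at temperature ``t`` applies.
        """
        rng = self.rng
        owner = self.peak_owner.get(id(p))
        tol = self.tolerances

        if op == "move":
            affected = [owner, target]
        elif op == "swap":
            q = target
            q_owner = self.peak_owner[id(q)]
            affected = [owner, q_owner]
        elif op == "cache":
            affected = [owner]
        else:  # uncache
            affected = [target]

        def membership_change():
            if op == "move":
                owner.peaks.remove(p)
                target.peaks.append(p)
                self.peak_owner[id(p)] = target
            elif op == "swap":
                owner.peaks.remove(p)
                q_owner.peaks.remove(q)
                owner.peaks.append(q)
                q_owner.peaks.append(p)
                self.peak_owner[id(p)] = q_owner
                self.peak_owner[id(q)] = owner
            elif op == "cache":
                owner.peaks.remove(p)
                self.crosspeak_cache.append(p)
                self.peak_owner[id(p)] = None
            else:
                self.crosspeak_cache.remove(p)
                target.peaks.append(p)
                self.peak_owner[id(p)] = target

        def membership_revert():
            if op == "move":
                target.peaks.remove(p)
                owner.peaks.append(p)
                self.peak_owner[id(p)] = owner
            elif op == "swap":
                owner.peaks.remove(q)
                q_owner.peaks.remove(p)
                owner.peaks.append(p)
                q_owner.peaks.append(q)
                self.peak_owner[id(p)] = owner
                self.peak_owner[id(q)] = q_owner
            elif op == "cache":
                self.crosspeak_cache.remove(p)
                owner.peaks.append(p)
                self.peak_owner[id(p)] = owner
            else:
                target.peaks.remove(p)
                self.crosspeak_cache.append(p)
                self.peak_owner[id(p)] = None

        positions = self._affected_positions(affected)
        before = self._e_local(positions)
        saved = [
            (
                ss,
                ss.type_sets,
                ss.version,
                ss._pcache,
                self.ts_of[self._ss_index[id(ss)]],
            )
            for ss in affected
        ]

        membership_change()
        new_type_sets = []
        for ss in affected:
            ts = self._enumerate_cached(ss)
            if not ts:  # clash (or emptied spin system): rejected outright
                membership_revert()
                return 0
            new_type_sets.append(ts)

        structural = False
        for ss, ts in zip(affected, new_type_sets):
            if len(ts) != ss.n_type_sets:
                structural = True
            ss.touch()
            ss.type_sets = ts
            self.ts_of[self._ss_index[id(ss)]] = rng.randrange(len(ts))

        # ΔE evaluated locally on the tentative spin systems; the global
        # tables are only touched when the move is accepted
        d_e = self._e_local_tentative(positions, affected) - before

        accept = (d_e < -1e-12) if greedy else metropolis_accept(d_e, t, rng)
        if accept:
            self.E_tot += d_e
            if structural:
                self._build_tables()
                self._rebuild_occ()
            else:
                for ss in affected:
                    s_idx = self._ss_index[id(ss)]
                    self._update_ss_tables(s_idx)
                    n = self.pos_of[s_idx]
                    if n >= 0:
                        self.occ_flat[n] = self.flat_base[s_idx] + self.ts_of[s_idx]
            return 1

        membership_revert()
        for ss, type_sets, version, pcache, tsi in saved:
            ss.type_sets = type_sets
            ss.version = version
            ss._pcache = pcache
            self.ts_of[self._ss_index[id(ss)]] = tsi
        return 0

    def _enumerate_cached(self, ss):
        """Type-set enumeration memoized on peak membership."""
        from .assembly import enumerate_type_sets

        if not ss.peaks:
            return []
        key = tuple(sorted(p.id for p in ss.peaks))
        hit = self._ts_cache.get(key)
        if hit is None:
            hit = enumerate_type_sets(ss.peaks, self.tolerances)
            if len(self._ts_cache) > 20000:
                self._ts_cache.clear()
            self._ts_cache[key] = hit
        return list(hit)

    def _e_local_tentative(self, positions, affected) -> float:
        """Local energy with ``affected`` spin systems' fresh type sets,
        evaluated without touching the flat tables."""
        from .energy import adjacency_energy, chemical_shift_energy

        params = self.energy_params
        affected_idx = {self._ss_index[id(ss)] for ss in affected}
        n_res = self.N

        def shifts_of(s):
            ss = self.spin_systems[s]
            return ss.type_sets[self.ts_of[s]].mean_shifts

        total = 0.0
        for n in positions:
            if not 1 <= n <= n_res:
                continue
            s = self.occ_ss[n]
            if s < 0:
                continue
            if s in affected_idx:
                ss = self.spin_systems[s]
                tsi = self.ts_of[s]
                pm = posterior_matrix(ss, self.predictions, self.sequence, params)
                total += chemical_shift_energy(
                    float(pm.posterior[tsi, n]), ss.n_type_sets, n_res, params
                )
            else:
                total += self.ecs[self.occ_flat[n]][n]
            s2 = self.occ_ss[n + 1]
            if s2 >= 0:
                if s in affected_idx or s2 in affected_idx:
                    total += adjacency_energy(shifts_of(s), shifts_of(s2), params)
                else:
                    total += self.adj[self.occ_flat[n]][self.occ_flat[n + 1]]
        return total

    # -- sampling and equilibration ------------------------------------------
    def collect_sample(self, t: float, size: int):
        """Energies after ``size`` successful swaps at temperature t.

        Returns (sample, successes, fails, stalled); ``stalled`` is set when
        the fail/success ratio blows past the termination threshold mid-sample.
        """
        params = self.anneal_params
        sample: list[float] = []
        successes = 0
        fails = 0
        step = self.step
        append = sample.append
        while successes < size:
            if step(t):
                successes += 1
                append(self.E_tot)
            else:
                fails += 1
                if fails > params.fail_ratio * (successes or 1) or fails > params.max_fails_per_sample:
                    return sample, successes, fails, True
        return sample, successes, fails, False

    # -- local minimization ---------------------------------------------------
    def local_minimize(self, n_iter: int | None = None):
        """Greedy sweeps: every spin-system/peak placement and swap is tried,
        only energy decreases accepted; stops early at a fixed point."""
        n_iter = n_iter if n_iter is not None else self.anneal_params.n_minimize
        for _ in range(n_iter):
            improved = self._minimize_sweep()
            if not improved:
                break

    def _minimize_sweep(self) -> bool:
        improved = False
        eps = -1e-12
        for s in range(self.M):
            i_s = self.spin_systems[s].n_type_sets
            base = self.flat_base[s]
            n1 = self.pos_of[s]

            if n1 >= 0 and i_s > 1:  # type-set flips in place
                for tsi2 in range(i_s):
                    cur = self.ts_of[s]
                    if tsi2 == cur:
                        continue
                    if self.check_mask and not self.mask[base + tsi2][n1]:
                        continue
                    pos = {n1 - 1, n1}
                    before = self._e_local(pos)
                    self.occ_flat[n1] = base + tsi2
                    self.ts_of[s] = tsi2
                    d_e = self._e_local(pos) - before
                    if d_e < eps:
                        self.E_tot += d_e
                        improved = True
                    else:
                        self.occ_flat[n1] = base + cur
                        self.ts_of[s] = cur

            # moves to every empty position
            for n2 in sorted(self.empty):
                n1 = self.pos_of[s]
                for tsi2 in range(i_s):
                    if self.check_mask and not self.mask[base + tsi2][n2]:
                        continue
                    if n1 >= 0:
                        old_tsi = self.ts_of[s]
                        pos = {n1 - 1, n1, n2 - 1, n2}
                        before = self._e_local(pos)
                        self._clear(n1)
                        self._place(s, n2, tsi2)
                        d_e = self._e_local(pos) - before
                        if d_e < eps:
                            self.E_tot += d_e
                            self._lremove(self.empty, self._empty_idx, n2)
                            self._ladd(self.empty, self._empty_idx, n1)
                            improved = True
                            break
                        self._clear(n2)
                        self._place(s, n1, old_tsi)
                    else:
                        pos = {n2 - 1, n2}
                        before = self._e_local(pos)
                        self._place(s, n2, tsi2)
                        d_e = self._e_local(pos) - before
                        if d_e < eps:
                            self.E_tot += d_e
                            self._lremove(self.empty, self._empty_idx, n2)
                            self._lremove(self.cached, self._cached_idx, s)
                            self._ladd(self.placed, self._placed_idx, s)
                            improved = True
                            break
                        self._clear(n2)

            # swaps with every placed system
            for l in sorted(self.placed):
                if l == s:
                    continue
                n1 = self.pos_of[s]
                n2 = self.pos_of[l]
                if n2 < 0:
                    continue
                i_l = self.spin_systems[l].n_type_sets
                done = False
                for tsi_s in range(i_s):
                    for tsi_l in range(i_l):
                        if n1 >= 0:
                            if self.check_mask and (
                                not self.mask[base + tsi_s][n2]
                                or not self.mask[self.flat_base[l] + tsi_l][n1]
                            ):
                                continue
                            old_s, old_l = self.ts_of[s], self.ts_of[l]
                            pos = {n1 - 1, n1, n2 - 1, n2}
                            before = self._e_local(pos)
                            self._clear(n1)
                            self._clear(n2)
                            self._place(s, n2, tsi_s)
                            self._place(l, n1, tsi_l)
                            d_e = self._e_local(pos) - before
                            if d_e < eps:
                                self.E_tot += d_e
                                improved = True
                                done = True
                                break
                            self._clear(n1)
                            self._clear(n2)
                            self._place(s, n1, old_s)
                            self._place(l, n2, old_l)
                        else:
                            if self.check_mask and not self.mask[base + tsi_s][n2]:
                                continue
                            old_l = self.ts_of[l]
                            pos = {n2 - 1, n2}
                            before = self._e_local(pos)
                            self._clear(n2)
                            self._place(s, n2, tsi_s)
                            d_e = self._e_local(pos) - before
                            if d_e < eps:
                                self.E_tot += d_e
                                self._lremove(self.cached, self._cached_idx, s)
                                self._ladd(self.placed, self._placed_idx, s)
                                self._lremove(self.placed, self._placed_idx, l)
                                self._ladd(self.cached, self._cached_idx, l)
                                improved = True
                                done = True
                                break
                            self._clear(n2)
                            self._place(l, n2, old_l)
                    if done:
                        break

            # caching
            n1 = self.pos_of[s]
            if n1 >= 0:
                old_tsi = self.ts_of[s]
                pos = {n1 - 1, n1}
                before = self._e_local(pos)
                self._clear(n1)
                d_e = self._e_local(pos) - before
                if d_e < eps:
                    self.E_tot += d_e
                    self._ladd(self.empty, self._empty_idx, n1)
                    self._lremove(self.placed, self._placed_idx, s)
                    self._ladd(self.cached, self._cached_idx, s)
                    improved = True
                else:
                    self._place(s, n1, old_tsi)

        # crosspeak sweeps
        for p in list(self.exchangeable_pool):
            owner = self.peak_owner.get(id(p))
            group = self.group_of_peak[id(p)]
            if owner is None:
                for target in group.members:
                    if self._crosspeak_attempt(p, "uncache", target, greedy=True):
                        improved = True
                        break
                continue
            if len(owner.peaks) > 1:
                for target in group.members:
                    if target is owner:
                        continue
                    if self._crosspeak_attempt(p, "move", target, greedy=True):
                        improved = True
                        break
            for q in group.exchangeable_peaks:
                if self.peak_owner.get(id(q)) in (None, self.peak_owner.get(id(p))):
                    continue
                if self._crosspeak_attempt(p, "swap", q, greedy=True):
                    improved = True
            if (
                self.anneal_params.use_crosspeak_cache
                and p.cache_eligible
                and self.peak_owner.get(id(p)) is not None
                and len(self.peak_owner[id(p)].peaks) > 1
            ):
                if self._crosspeak_attempt(p, "cache", None, greedy=True):
                    improved = True
        return improved


# ---------------------------------------------------------------------------
# equilibration and the annealing loop


def equilibrate_at_T(
    state: AssignmentState,
    t: float,
    size: int,
    p_equil: float = 0.5,
    welch: bool = False,
):
    """Sample until consecutive disjoint energy samples are indistinguishable.

    Repeatedly collects ``size`` post-swap energies and declares equilibrium
    when a two-tailed two-sample t-test between the two most recent samples
    has p > ``p_equil``.  Returns (final sample, successes, fails, stalled);
    a sampling round with essentially no successful swaps is treated as
    equilibrated (stalled) and feeds the termination ratio check.
    """
    prev = None
    while True:
        sample, successes, fails, stalled = state.collect_sample(t, size)
        if stalled:
            return sample, successes, fails, True
        if prev is not None and _samples_indistinguishable(prev, sample, p_equil, welch):
            return sample, successes, fails, False
        prev = sample


def _samples_indistinguishable(a, b, p_equil, welch) -> bool:
    arr_a = np.asarray(a)
    arr_b = np.asarray(b)
    if arr_a.var() == 0.0 and arr_b.var() == 0.0:
        return bool(arr_a.mean() == arr_b.mean())
    p = ttest_ind(arr_a, arr_b, equal_var=not welch).pvalue
    return bool(p > p_equil)


def run_annealing(
    problem: AssignmentProblem,
    params: AnnealingParams = DEFAULT_ANNEALING_PARAMS,
    seed: int = 0,
) -> AssignmentState:
    """One full annealing run: cool, terminate, locally minimize.

    Deterministic for a fixed seed.
    """
    state = AssignmentState(problem, anneal_params=params, seed=seed)
    t = params.t0
    size = params.sample_floor
    while True:
        sample, successes, fails, stalled = equilibrate_at_T(
            state, t, size, params.p_equil, params.welch
        )
        cv = specific_heat(sample, t) if len(sample) >= 2 else 0.0
        ratio = fails / (successes or 1)
        state.history.append(
            {
                "T": t,
                "mean_E": float(np.mean(sample)) if sample else state.E_tot,
                "Cv": cv,
                "S": size,
                "fail_ratio": ratio,
            }
        )
        if stalled or ratio > params.fail_ratio:
            break
        t = next_temperature(t, cv, params)
        if t < params.t_min:
            break
        if t < params.t_cv_check_below and t * cv < params.t_cv_min:
            break
        size = next_sample_size(state.N, cv, params)
    state.local_minimize(params.n_minimize)
    logger.info(
        "annealing seed=%d finished: %d temperatures, E=%.1f",
        seed,
        len(state.history),
        state.E_tot,
    )
    return state
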