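"""Pseudo-energy model scoring spin-system placements on the sequence.

Two terms drive the annealing search.  The *adjacency energy* rewards
agreement between a spin system's Cα/Cβ/CO shifts and the Cα(i-1)/Cβ(i-1)/
CO(i-1) shifts of the spin system placed at the following residue: each
matching resonance contributes an inverted Gaussian
``c0 * exp(-1/2 (Δδ/σ_k)^2) + c1`` with defaults c0 = −100, c1 = +50, giving
−50 at Δδ = 0, a zero crossing at Δδ = 0.2 ppm, and +50 in the mismatch
limit.  The *chemical-shift energy* converts the Bayesian posterior
probability of the placement — prior uniform over possible (residue,
type-set) combinations, likelihood the chi-square survival probability of the
standardized observed-vs-predicted shift residuals — into an energy on
[−50, +100].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .assembly import SpinSystem
from .io import ShiftPrediction
from .spectra import RESONANCES, base_resonance, is_prev

logger = logging.getLogger(__name__)

#: Adjacency width giving a zero crossing at |Δδ| = 0.2 ppm with c0=-100, c1=+50.
DEFAULT_SIGMA_K = 0.2 / math.sqrt(2.0 * math.log(2.0))

ADJACENCY_RESONANCES = ("CA", "CB", "CO")


@dataclass(frozen=True)
class EnergyParams:
    """Tunable constants of the pseudo-energy (arbitrary energy units)."""

    c0: float = -100.0  # adjacency depth
    c1: float = 50.0  # adjacency offset
    sigma_k: float = DEFAULT_SIGMA_K  # adjacency width (ppm), all nuclei k
    e_cs_min: float = -50.0
    e_cs_max: float = 100.0
    glycine_rule: bool = False  # also forbid CB-bearing type sets at glycine

    def __post_init__(self):
        if not (self.c0 < 0 < self.c1 and abs(self.c0) > self.c1):
            raise ValueError("require c0 < 0 < c1 and |c0| > c1")
        if not (self.e_cs_min < 0 < self.e_cs_max):
            raise ValueError("require e_cs_min < 0 < e_cs_max")


DEFAULT_ENERGY_PARAMS = EnergyParams()


# ---------------------------------------------------------------------------
# predictions container


class ShiftPredictionSet:
    """Vectorized per-residue predicted shifts: arrays indexed 1..N."""

    def __init__(self, predictions: list[ShiftPrediction], n_residues: int):
        self.n_residues = n_residues
        self.delta = {r: np.full(n_residues + 1, np.nan) for r in RESONANCES}
        self.sigma = {r: np.full(n_residues + 1, np.nan) for r in RESONANCES}
        for p in predictions:
            if not 1 <= p.residue_index <= n_residues:
                raise IndexError(f"prediction residue {p.residue_index} out of range")
            self.delta[p.resonance][p.residue_index] = p.delta_pred
            self.sigma[p.resonance][p.residue_index] = p.sigma
        # predecessor-shifted views: entry n holds the prediction for n-1
        self.delta_prev = {r: _shift_back(a) for r, a in self.delta.items()}
        self.sigma_prev = {r: _shift_back(a) for r, a in self.sigma.items()}

    def at(self, n: int) -> dict[str, tuple[float, float]]:
        out = {}
        for r in RESONANCES:
            d = self.delta[r][n]
            if np.isfinite(d):
                out[r] = (float(d), float(self.sigma[r][n]))
        return out


def _shift_back(a: np.ndarray) -> np.ndarray:
    out = np.full_like(a, np.nan)
    out[1:] = a[:-1]
    return out


# ---------------------------------------------------------------------------
# adjacency energy


def adjacency_term(delta: float, params: EnergyParams = DEFAULT_ENERGY_PARAMS) -> float:
    """One resonance's adjacency contribution at shift difference ``delta``."""
    return params.c0 * math.exp(-0.5 * (delta / params.sigma_k) ** 2) + params.c1


def adjacency_energy(
    shifts_m: dict[str, float],
    shifts_l: dict[str, float],
    params: EnergyParams = DEFAULT_ENERGY_PARAMS,
) -> float:
    """Adjacency energy of spin system m at residue n vs l at residue n+1.

    Sums one inverted-Gaussian term per resonance k in {CA, CB, CO} comparing
    m's k(i) mean shift with l's k(i-1) mean shift; a term with either shift
    missing contributes exactly 0.
    """
    e = 0.0
    for k in ADJACENCY_RESONANCES:
        dm = shifts_m.get(k)
        dl = shifts_l.get(k + "-1")
        if dm is None or dl is None:
            continue
        e += params.c0 * math.exp(-0.5 * ((dm - dl) / params.sigma_k) ** 2) + params.c1
    return e


# ---------------------------------------------------------------------------
# likelihood


def chi_square_statistic(
    obs: dict[str, float], preds: ShiftPredictionSet, n: int
) -> tuple[float, int]:
    """Standardized residual sum X² and degrees of freedom R at residue n.

    Observed (i-1) resonances are compared against the predictions of residue
    n-1; resonances without a co-present prediction are excluded from R.
    """
    x2 = 0.0
    r = 0
    for label, value in obs.items():
        base = base_resonance(label)
        if is_prev(label):
            d = preds.delta_prev[base][n]
            s = preds.sigma_prev[base][n]
        else:
            d = preds.delta[base][n]
            s = preds.sigma[base][n]
        if np.isnan(d):
            continue
        x2 += ((value - d) / s) ** 2
        r += 1
    return x2, r


def likelihood(obs: dict[str, float], preds: ShiftPredictionSet, n: int) -> float:
    """P(observed shifts | placement at n): chi-square survival probability."""
    x2, r = chi_square_statistic(obs, preds, n)
    if r == 0:
        logger.debug("no co-present resonances at residue %d; likelihood 1", n)
        return 1.0
    return float(chi2.sf(x2, r))


def _likelihood_row(
    mean_shifts: dict[str, float], preds: ShiftPredictionSet
) -> np.ndarray:
    """Vectorized likelihood over all residues for one type set."""
    n = preds.n_residues
    x2 = np.zeros(n + 1)
    r = np.zeros(n + 1, dtype=int)
    for label, value in mean_shifts.items():
        base = base_resonance(label)
        if is_prev(label):
            d, s = preds.delta_prev[base], preds.sigma_prev[base]
        else:
            d, s = preds.delta[base], preds.sigma[base]
        mask = np.isfinite(d)
        x2[mask] += ((value - d[mask]) / s[mask]) ** 2
        r[mask] += 1
    out = np.ones(n + 1)
    has = r > 0
    out[has] = chi2.sf(x2[has], r[has])
    out[0] = 0.0
    return out


# ---------------------------------------------------------------------------
# posterior


@dataclass
class PosteriorMatrix:
    """Bayesian assignment probabilities for one spin system.

    Arrays have shape (I, N+1) and are indexed [type set, residue]; column 0
    is unused padding so residue indices stay 1-based.  ``C`` counts the
    possible (residue, type set) combinations.
    """

    prior: np.ndarray
    likelihood: np.ndarray
    marginal: float
    posterior: np.ndarray
    C: int


def possible_mask(
    ss: SpinSystem, sequence: str, glycine_rule: bool = False
) -> np.ndarray:
    """Boolean (I, N+1) mask of chemically possible placements.

    An amide-bearing type set cannot sit at a proline; with the optional
    glycine rule, a CB-bearing type set cannot sit at glycine (nor a
    CB(i-1)-bearing one immediately after glycine).
    """
    n_res = len(sequence)
    mask = np.zeros((len(ss.type_sets), n_res + 1), dtype=bool)
    mask[:, 1:] = True
    for i, ts in enumerate(ss.type_sets):
        labels = {lab for cand in ts.labels for lab in cand}
        if "H" in labels or "N" in labels:
            for n, aa in enumerate(sequence, start=1):
                if aa == "P":
                    mask[i, n] = False
        if glycine_rule:
            for n, aa in enumerate(sequence, start=1):
                if aa == "G" and ("CB" in labels):
                    mask[i, n] = False
                if n > 1 and sequence[n - 2] == "G" and ("CB-1" in labels):
                    mask[i, n] = False
    return mask


def posterior_matrix(
    ss: SpinSystem,
    preds: ShiftPredictionSet,
    sequence: str,
    params: EnergyParams = DEFAULT_ENERGY_PARAMS,
) -> PosteriorMatrix:
    """Prior, likelihood, marginal and posterior over (residue, type set).

    The prior is 0 at impossible combinations and uniform 1/C elsewhere; the
    posterior follows Bayes' rule with the chi-square likelihood.  The result
    is cached on the spin system and invalidated when its peak membership
    changes.
    """
    key = (id(preds), ss.version, params.glycine_rule)
    if ss._pcache is not None and ss._pcache[0] == key:
        return ss._pcache[1]

    if not ss.type_sets:
        raise ValueError(f"spin system {ss.uid} has no resonance type sets")
    mask = possible_mask(ss, sequence, params.glycine_rule)
    c = int(mask.sum())
    if c == 0:
        raise ValueError(f"spin system {ss.uid} is placeable nowhere (C = 0)")
    prior = np.where(mask, 1.0 / c, 0.0)
    like = np.vstack([_likelihood_row(ts.mean_shifts, preds) for ts in ss.type_sets])
    marginal = float((like * prior).sum())
    if marginal > 0:
        post = like * prior / marginal
    else:
        post = np.zeros_like(prior)
    pm = PosteriorMatrix(prior, like, marginal, post, c)
    ss._pcache = (key, pm)
    return pm


# ---------------------------------------------------------------------------
# chemical-shift energy


def chemical_shift_energy(
    p: float, i_m: int, n_res: int, params: EnergyParams = DEFAULT_ENERGY_PARAMS
) -> float:
    """Energy of a placement with posterior probability ``p``.

    ``(e_cs_min / log(I_m N)) * log(p I_m N)``, clamped from above at
    ``e_cs_max``; p = 1 gives e_cs_min, p = 0 maps to the clamp.
    """
    total = i_m * n_res
    if total <= 1:  # single possible assignment
        return params.e_cs_min
    if p <= 0.0:
        return params.e_cs_max
    e = params.e_cs_min / math.log(total) * math.log(p * total)
    return min(e, params.e_cs_max)


def chemical_shift_energy_row(
    posterior_row: np.ndarray, i_m: int, n_res: int, params: EnergyParams
) -> np.ndarray:
    """Vectorized chemical-shift energy over a posterior row."""
    total = i_m * n_res
    out = np.full(posterior_row.shape, params.e_cs_max)
    if total <= 1:
        out[:] = params.e_cs_min
        return out
    pos = posterior_row > 0
    coef = params.e_cs_min / math.log(total)
    out[pos] = np.minimum(coef * np.log(posterior_row[pos] * total), params.e_cs_max)
    return out


# ---------------------------------------------------------------------------
# total energy (full recomputation; the incremental bookkeeping oracle)


def total_energy(state) -> float:
    """Recompute the state's total energy from scratch.

    Sums adjacency plus chemical-shift energy over placed spin systems using
    the module's scalar routines; cached spin systems contribute exactly 0.
    Serves as the independent check of the annealer's incremental ΔE
    bookkeeping.
    """
    params = state.energy_params
    preds = state.predictions
    seq = state.sequence
    n_res = len(seq)
    occupants = dict(state.iter_placements())
    e_tot = 0.0
    for n, (ss, tsi) in occupants.items():
        pm = posterior_matrix(ss, preds, seq, params)
        p = float(pm.posterior[tsi, n])
        e_tot += chemical_shift_energy(p, ss.n_type_sets, n_res, params)
        nxt = occupants.get(n + 1)
        if nxt is not None:
            e_tot += adjacency_energy(
                ss.type_sets[tsi].mean_shifts, nxt[0].type_sets[nxt[1]].mean_shifts, params
            )
    return e_tot
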