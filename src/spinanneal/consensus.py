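"""Ensemble consensus, curation and scoring of assignment runs.

The annealing search is repeated from independent random starts (20 by
default); a residue keeps a spin system only when a strict majority of runs
agree.  Tentative consensus assignments are then curated: an assignment
survives if it has at least two connectivities with adjacent spin systems,
one connectivity plus a posterior probability of at least 3/N, or a
posterior above 50%.  Scoring against a reference labels each non-proline
residue matched, missing or mismatched by amide-group identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .annealing import AnnealingParams, AssignmentProblem, AssignmentState, run_annealing
from .energy import posterior_matrix

logger = logging.getLogger(__name__)


@dataclass
class ResidueRecord:
    """Consensus outcome for one residue position."""

    residue: int
    aa: str
    spin_system: str | None = None
    vote_fraction: float = 0.0
    posterior: float = 0.0
    connectivities: int = 0
    status: str = "unassigned"
    mean_shifts: dict[str, float] | None = None


@dataclass
class ConsensusResult:
    sequence: str
    n_runs: int
    records: list[ResidueRecord] = field(default_factory=list)
    curated: bool = False

    @property
    def assignment_map(self) -> dict[int, str]:
        return {
            r.residue: r.spin_system
            for r in self.records
            if r.status == "assigned" and r.spin_system is not None
        }

    def record(self, n: int) -> ResidueRecord:
        return self.records[n - 1]


@dataclass
class AssignmentScore:
    """Matched/mismatched/missing fractions over scorable residues."""

    matched: float
    mismatched: float
    missing: float
    n_scored: int
    labels: dict[int, str] = field(default_factory=dict)


def run_ensemble(
    problem: AssignmentProblem,
    n_runs: int = 20,
    params: AnnealingParams | None = None,
    base_seed: int = 0,
) -> list[AssignmentState]:
    """Independent annealing runs seeded base_seed, base_seed+1, ..."""
    params = params or AnnealingParams()
    return [run_annealing(problem, params, seed=base_seed + i) for i in range(n_runs)]


def build_consensus(runs: list[AssignmentState]) -> ConsensusResult:
    """Majority-vote consensus over an ensemble of annealing runs.

    A residue is tentatively assigned the spin system placed there in a
    strict majority (>50%) of runs.  The consensus posterior, type set and
    mean shifts are taken from the majority run with the smallest seed, which
    makes the result independent of run completion order.
    """
    if not runs:
        raise ValueError("consensus requires at least one run")
    sequence = runs[0].sequence
    n_runs = len(runs)
    n_res = len(sequence)
    result = ConsensusResult(sequence, n_runs)

    placements = [run.placement for run in runs]
    for n in range(1, n_res + 1):
        rec = ResidueRecord(n, sequence[n - 1])
        votes: dict[str, int] = {}
        for pl in placements:
            uid = pl.get(n)
            if uid is not None:
                votes[uid] = votes.get(uid, 0) + 1
        if votes:
            uid, count = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
            if count * 2 > n_runs:  # strict majority
                rep = min(
                    (run for run, pl in zip(runs, placements) if pl.get(n) == uid),
                    key=lambda run: run.seed,
                )
                s_idx = next(
                    i for i, ss in enumerate(rep.spin_systems) if ss.uid == uid
                )
                ss = rep.spin_systems[s_idx]
                tsi = rep.ts_of[s_idx]
                pm = posterior_matrix(ss, rep.predictions, sequence, rep.energy_params)
                rec.spin_system = uid
                rec.vote_fraction = count / n_runs
                rec.posterior = float(pm.posterior[tsi, n])
                rec.mean_shifts = dict(ss.type_sets[tsi].mean_shifts)
                rec.status = "assigned"
        result.records.append(rec)

    _count_connectivities(result, runs[0].tolerances)
    return result


def _count_connectivities(result: ConsensusResult, tolerances: dict[str, float]) -> None:
    """Connectivity = a matching resonance pair between adjacent spin systems."""
    tol_c = tolerances["C"]
    recs = result.records
    matches = [0] * (len(recs) + 2)
    for n in range(1, len(recs)):
        a, b = recs[n - 1], recs[n]  # residues n and n+1
        if a.mean_shifts is None or b.mean_shifts is None:
            continue
        count = 0
        for k in ("CA", "CB", "CO"):
            dm = a.mean_shifts.get(k)
            dl = b.mean_shifts.get(k + "-1")
            if dm is not None and dl is not None and abs(dm - dl) <= tol_c:
                count += 1
        matches[n] = count
    for n, rec in enumerate(recs, start=1):
        rec.connectivities = matches[n] + matches[n - 1]


def curate(
    consensus: ConsensusResult,
    n_residues: int | None = None,
    tol: float | None = None,
) -> ConsensusResult:
    """Rule-based curation of the tentative consensus assignments.

    Keeps an assignment iff (1) it has >= 2 connectivities with adjacent
    consensus spin systems, (2) >= 1 connectivity and posterior >= 3/N, or
    (3) posterior > 0.5.  Curation only removes assignments.
    """
    n_res = n_residues or len(consensus.sequence)
    out = ConsensusResult(consensus.sequence, consensus.n_runs, curated=True)
    for rec in consensus.records:
        new = ResidueRecord(**vars(rec))
        if rec.status == "assigned":
            keep = (
                rec.connectivities >= 2
                or (rec.connectivities >= 1 and rec.posterior >= 3.0 / n_res)
                or rec.posterior > 0.5
            )
            if not keep:
                new.status = "unassigned"
        out.records.append(new)
    n_dropped = sum(
        1
        for a, b in zip(consensus.records, out.records)
        if a.status == "assigned" and b.status == "unassigned"
    )
    if n_dropped:
        logger.info("curation removed %d tentative assignments", n_dropped)
    return out


def score_against_reference(
    result: ConsensusResult,
    reference: dict[int, tuple[float, float] | None],
    tolerances: dict[str, float] | None = None,
) -> AssignmentScore:
    """Label each residue matched/missing/mismatched against a reference.

    ``reference`` maps residue index to the amide (H, N) shifts of the
    reference assignment (None where the reference is unassigned).  Amide
    identity is shift-based: the result's consensus amide must fall within
    the H/N matching tolerances of the reference amide.  Prolines are not
    scored.
    """
    tol = tolerances or {"H": 0.03, "N": 0.3}
    seq = result.sequence
    if reference and max(reference) > len(seq):
        raise ValueError("reference refers to residues beyond the sequence")
    labels: dict[int, str] = {}
    counts = {"matched": 0, "mismatched": 0, "missing": 0}
    n_scored = 0
    for rec in result.records:
        if seq[rec.residue - 1] == "P":
            continue
        n_scored += 1
        ref = reference.get(rec.residue)
        assigned = rec.status == "assigned" and rec.mean_shifts is not None
        if not assigned:
            label = "matched" if ref is None else "missing"
        elif ref is None:
            label = "mismatched"
        else:
            h = rec.mean_shifts.get("H")
            n15 = rec.mean_shifts.get("N")
            same = (
                h is not None
                and n15 is not None
                and abs(h - ref[0]) <= tol["H"]
                and abs(n15 - ref[1]) <= tol["N"]
            )
            label = "matched" if same else "mismatched"
        labels[rec.residue] = label
        counts[label] += 1
    if n_scored == 0:
        raise ValueError("no scorable residues")
    return AssignmentScore(
        matched=counts["matched"] / n_scored,
        mismatched=counts["mismatched"] / n_scored,
        missing=counts["missing"] / n_scored,
        n_scored=n_scored,
        labels=labels,
    )
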