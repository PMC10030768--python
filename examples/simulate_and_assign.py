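"""Generate a synthetic triple-resonance dataset and assign it end to end.

Simulates a 20-residue protein with the full seven-experiment set at the
default measurement noise, assembles spin systems, runs a small annealing
ensemble, and scores the curated consensus against the generating truth.
"""

from spinanneal import (
    AnnealingParams,
    AssignmentProblem,
    build_consensus,
    curate,
    generate_dataset,
    predictions_from_truth,
    run_ensemble,
    score_against_reference,
)

truth = generate_dataset(length=20, seed=3)
print(f"sequence ({len(truth.sequence)} aa): {truth.sequence}")
print(f"emitted crosspeaks: {len(truth.all_peaks)} over {len(truth.peak_lists)} spectra")

preds = predictions_from_truth(truth)  # residue-type means with SD errors
problem = AssignmentProblem.from_peaks(truth.all_peaks, truth.sequence, preds)
n_systems = sum(len(g.members) for g in problem.groups)
print(f"assembled spin systems: {n_systems}")

params = AnnealingParams(sample_floor=600, sample_ceiling=6000)
runs = run_ensemble(problem, n_runs=5, params=params, base_seed=1)
print(f"annealed {len(runs)} independent runs; final energies:",
      [round(r.E_tot, 1) for r in runs])

result = curate(build_consensus(runs))
assigned = sum(1 for r in result.records if r.status == "assigned")
print(f"curated consensus: {assigned}/{len(result.records)} residues assigned")

score = score_against_reference(result, truth.reference)
print(
    f"vs truth: matched {score.matched:.2f}, mismatched {score.mismatched:.2f}, "
    f"missing {score.missing:.2f} over {score.n_scored} scorable residues"
)
print("matched counts both recovered assignments and correctly-empty positions;")
print("mismatched is the error rate the curation rules are designed to suppress.")
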