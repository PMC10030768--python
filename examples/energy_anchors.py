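"""Evaluate the pseudo-energy terms at their characteristic points.

Builds a one-peak spin system, scores it against three candidate residue
positions, and prints the adjacency and chemical-shift energy anchors that
parameterize the annealing search.
"""

from spinanneal import (
    CrossPeak,
    EnergyParams,
    assemble_spin_systems,
    chemical_shift_energy,
    get_spectrum,
    posterior_matrix,
)
from spinanneal.energy import ShiftPredictionSet, adjacency_term
from spinanneal.io import ShiftPrediction

params = EnergyParams()

print("Adjacency energy per matching resonance (c0=-100, c1=+50):")
for delta in (0.0, 0.1, 0.2, 0.5, 2.0):
    print(f"  |d-delta| = {delta:4.1f} ppm  ->  {adjacency_term(delta, params):8.2f}")
print("A perfect connectivity contributes -50; a clear mismatch +50;")
print("the term crosses zero at 0.2 ppm.\n")

print("Chemical-shift energy vs posterior probability (I_m=2, N=100):")
for p in (1.0, 0.5, 1.0 / 200, 1e-6, 0.0):
    print(f"  p = {p:8.2e}  ->  {chemical_shift_energy(p, 2, 100, params):8.2f}")
print("Certainty scores -50 (one perfect connectivity); impossibility +100.\n")

# one HNCA peak whose carbon matches the prediction at residue 2 of "AKV"
peak = CrossPeak("demo", get_spectrum("HNCA"), (8.2, 119.0, 56.9))
ss = assemble_spin_systems([peak])[0].members[0]
preds = ShiftPredictionSet(
    [
        ShiftPrediction(1, "H", 8.9, 0.2),
        ShiftPrediction(2, "H", 8.2, 0.2),
        ShiftPrediction(3, "H", 7.4, 0.2),
        ShiftPrediction(1, "N", 112.0, 1.5),
        ShiftPrediction(2, "N", 119.2, 1.5),
        ShiftPrediction(3, "N", 126.0, 1.5),
        ShiftPrediction(1, "CA", 53.1, 0.8),
        ShiftPrediction(2, "CA", 56.9, 0.8),
        ShiftPrediction(3, "CA", 62.5, 0.8),
    ],
    3,
)
pm = posterior_matrix(ss, preds, "AKV", params)
print("Posterior of the demo spin system over residues 1-3 (per type set):")
for i in range(len(ss.type_sets)):
    row = " ".join(f"{pm.posterior[i, n]:6.3f}" for n in (1, 2, 3))
    print(f"  type set {i}: {row}")
print("Residue 2, whose predicted amide and CA shifts all match, absorbs")
print(f"most of the probability; posteriors sum to {pm.posterior.sum():.6f}.")
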