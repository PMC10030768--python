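# spinanneal

Automated assignment of protein backbone triple-resonance NMR crosspeaks to
residues, by Bayesian-scored simulated annealing.

Backbone resonance assignment maps each observed amide-rooted spin system —
the crosspeaks sharing one H–N pair across HSQC, HNCO, HN(CA)CO, HNCA,
HN(CO)CA, HNCACB and CBCA(CO)NH spectra — onto a residue of the protein
sequence. `spinanneal` automates this for globular and disordered proteins
alike: it assembles raw Sparky-style peak lists into spin systems, scores
every candidate placement with a Bayesian posterior over predicted chemical
shifts, chains spin systems through Cα/Cβ/CO sequential connectivities, and
searches the assignment space with Metropolis simulated annealing under a
specific-heat-guided cooling schedule. An ensemble of independent runs is
reduced to a strict-majority consensus and curated with conservative
acceptance rules, so the final table contains very few wrong assignments even
when much of the data is missing or artifactual.

## The model

Each state places spin systems at residue positions (unplaced systems sit in
a cache at zero energy). The total energy is `E_tot = Σ_m (E_m^adj + E_m^cs)`.

**Adjacency energy.** For spin system *m* at residue *n* and spin system *l*
at *n*+1,

    E^adj = Σ_k [ c0 · exp(−½ ((δ_k(i)^m − δ_k(i−1)^l)/σ_k)²) + c1 ],

summed over k ∈ {Cα, Cβ, CO}; c0 = −100, c1 = +50, and σ_k is set so each
term crosses zero at a shift difference of 0.2 ppm. A perfect connectivity
contributes −50, a clear mismatch +50, and a missing resonance exactly 0.

**Chemical-shift energy.** For spin system *m* with I^m resonance type sets
on a sequence of N residues, the posterior that placement (n, i) is correct
follows Bayes' rule: a uniform prior 1/C over the C chemically possible
(residue, type set) combinations (amide-bearing type sets cannot sit on
proline), and a likelihood CCDF_χ²R(X²) where

    X² = Σ_r ((δ_obs,r − δ_pred,r)/σ_r)²

runs over the R resonances shared between observation and prediction —
(i−1) resonances are compared to the predictions of residue n−1. The energy
is `E^cs = (E_min/log(I^m N)) · log(p · I^m N)` clamped above at
E_max = +100, so certainty (p = 1) scores −50 and impossibility +100.

**Search.** Metropolis annealing from T = 1000 proposes spin-system
relocations, swaps, caching and type-set flips (and, with probability 0.01,
crosspeak exchanges between amide-degenerate spin systems). Equilibration at
each temperature is declared when consecutive energy samples pass a
two-sample t-test (p > 0.5); the specific heat `d⟨E⟩/dT = var(E)/T²` then
sets the next temperature through a target mean-energy drop of −2000, with
steps capped at 10 units. After termination a greedy minimization sweeps
every placement and exchange 100 times. Twenty runs vote; a residue keeps
its majority spin system if it has ≥2 connectivities, or 1 connectivity and
posterior ≥ 3/N, or posterior > 0.5.

Predicted shifts can come from a structure-based predictor table (errors
0.45/2.4/0.8/0.95/0.9 ppm for H/N/Cα/Cβ/CO), a random-coil table for
disordered proteins (0.16/1.0/0.42/0.37/0.43 ppm), or packaged per-residue
statistics (mean ± SD).

A fully ground-truthed synthetic data generator (`spinanneal.simulate`)
emulates the seven experiments with realistic measurement noise
(0.003/0.04/0.04 ppm for ¹H/¹⁵N/¹³C), per-peak-type depletion, whole
spin-system deletion (random or contiguous five-residue stretches) and
artifact contamination, so the entire pipeline is testable offline.

## Worked example

`examples/simulate_and_assign.py` simulates a 20-residue protein, assigns it
from scratch, and scores the result against the generating truth:

```
sequence (20 aa): IWVFNYSWDYASKVIHSVVS
emitted crosspeaks: 252 over 7 spectra
assembled spin systems: 20
annealed 5 independent runs; final energies: [-3386.4, -3386.4, -3386.4, -3386.4, -3386.4]
curated consensus: 20/20 residues assigned
vs truth: matched 1.00, mismatched 0.00, missing 0.00 over 20 scorable residues
```

All five runs reach the same energy minimum, the consensus assigns every
residue, and every assignment agrees with the truth (matched 1.00). The
companion scripts `examples/energy_anchors.py` (energy-term anchor values and
a posterior matrix) and `examples/depletion_experiment.py` (40% spin-system
deletion: mismatched stays 0.00 while deleted residues turn up as missing)
show the other capabilities.

A thin CLI wraps the same library calls:

```bash
spinanneal simulate --length 60 --seed 1 --out-dir data/
spinanneal assign config.yaml       # peak lists + FASTA + predictions -> table
spinanneal score result.tsv reference.tsv --sequence data/sequence.fasta
```

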