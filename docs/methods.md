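# Methods

This note records the scientific model implemented by `spinanneal`, the
parameter choices that matter, what the synthetic data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Spin-system assembly

All seven supported experiments are rooted at a backbone amide, so the amide
¹H and ¹⁵N dimensions are the two resonances of unambiguous type used for
matching. Assembly seeds a spin system with the first unconsumed crosspeak
(input order — fixed for reproducibility), then repeatedly adds any
remaining peak whose amide shifts fall within tolerance of the growing
system's running amide means (defaults 0.03 ppm ¹H, 0.3 ppm ¹⁵N) provided at
least one internally consistent resonance type labeling survives the
addition. A peak whose amide matches but whose carbon clashes with every
established resonance spawns a sibling spin system in the same overlap
group; remaining peaks are offered to all siblings. Carbon-bearing peaks of
multi-member groups are marked exchangeable and may migrate between siblings
during annealing.

Resonance type sets are enumerated by depth-first search over each peak's
candidate type tuples, pruning any branch in which a label's shift departs
from the label's running mean by more than the nucleus tolerance (0.3 ppm
for carbon by default). This subsumes the incremental "eliminate a candidate
that violates an established resonance" rule and guarantees the enumeration
is exhaustive and duplicate-free. Mean shifts per label are arithmetic means
over all contributing peak dimensions and are recomputed whenever peak
membership changes.

## Energy model

Defaults: c0 = −100, c1 = +50, E_min^cs = −50, E_max^cs = +100. The
adjacency width σ_k = 0.2/√(2 ln 2) ≈ 0.16986 ppm follows from requiring the
per-resonance term to cross zero at a 0.2 ppm shift difference; the same
width is used for Cα, Cβ and CO. The Gaussian exponent is negative — the
published anchor values (−50 at Δδ = 0, → +50 as Δδ → ∞) admit no other
sign. Amide H/N do not enter the adjacency sum.

The likelihood of a placement is the survival function of a χ² variable
with R degrees of freedom (scipy's `chi2.sf`), where R counts the
resonances present in both the observation and the prediction; a spin
system's (i−1) resonances are compared against residue n−1, so at n = 1
they simply drop out of R. A placement with no co-present resonances gets
likelihood 1 (R = 0) — it is uninformative rather than impossible. Prior
impossibility covers amide-bearing type sets at prolines; an analogous rule
for Cβ-bearing type sets at glycine exists behind the `glycine_rule` flag
(off by default, since only the proline case is chemically unconditional
once real data enter: sparse spin systems can lack a Cβ peak for many
reasons).

The log base in the chemical-shift energy cancels between numerator and
denominator; natural log is used. p = 0 (and any p small enough to exceed
the clamp) maps to E_max^cs. The degenerate case I^m·N = 1 returns
E_min^cs.

## Annealing engine

T0 = 1000; target mean-energy drop −2000 per cooling step; temperature
steps capped at 10 units; equilibration sample floor 10000 and ceiling
100000 with the sample size N·(d⟨E⟩/dT)^1.5/300 in between; termination at
T < 1, at a fail/success swap ratio above 10000 during the last sample, or
when T·Cv < 200. Equilibration compares the two most recent disjoint
samples of post-swap energies with a pooled-variance Student's t-test
(Welch available behind a flag) and declares equilibrium at p > 0.5; two
samples with zero variance and equal means are treated as p = 1. Specific
heat uses population (divide-by-n) moments; at sample sizes ≥ 10⁴ the
distinction from n−1 is negligible.

One deliberate refinement: the T·Cv criterion estimates the residual energy
separating the current ensemble from the ground state, which is meaningful
only once the system is cold. Near T0 a small problem's energy variance can
already satisfy T·Cv < 200 and would terminate the run before any annealing
occurred, so the criterion is checked only below a gate temperature
(default 100, `t_cv_check_below`). For desk-scale problems (a handful of
residues) the 200-unit threshold itself exceeds the total energy scale —
one connectivity is only 50 units — and should be lowered via `t_cv_min`;
the 6-residue global-minimum test uses 20.

Move mix: with probability 0.01 a crosspeak move (migration to a sibling,
swap within the overlap group, or caching of a low-intensity peak when the
crosspeak cache is enabled), otherwise a spin-system move chosen uniformly
among the legal kinds (relocate to an empty non-proline position, swap with
another placed system, move to the cache, or change type set in place; a
cached system may be placed or may displace a placed one). Every placement
draws a random type set. A crosspeak move that would clash — or would leave
its source spin system empty — is rejected outright; an accepted one
re-enumerates the affected systems' type sets, recomputes their mean shifts
and posteriors, and picks new random type sets.

Energy bookkeeping is incremental: each move evaluates only the affected
residues and their left neighbors, maintaining `E_tot` exactly (the test
suite checks agreement with a from-scratch recomputation to 10⁻⁶ after
thousands of random moves). Post-annealing, a greedy pass proposes every
spin-system placement/swap/type-set change and every crosspeak exchange,
accepting only energy decreases; the pass repeats up to 100 times but stops
at a fixed point, where it is idempotent.

Determinism: one seeded `random.Random` stream per run; ensemble run *i*
uses seed base+*i*. Identical seeds give identical trajectories.

## Consensus, curation and scoring

A residue keeps the spin system assigned there in a strict majority (>50%)
of the ensemble's runs (default 20 runs); an exact tie is unassigned. The
consensus record's posterior, type set and mean shifts come from the
majority run with the smallest seed, which makes the consensus independent
of run completion order. Curation accepts a tentative assignment with ≥2
connectivities to adjacent consensus spin systems, or 1 connectivity plus
posterior ≥ 3/N, or posterior > 0.5; a connectivity is a Cα/Cβ/CO pair
matching within the carbon assembly tolerance (0.3 ppm, user-overridable —
no number is prescribed for this step, so the assembly tolerance is
reused). Curation only removes assignments.

Scoring against a reference is amide-identity-based: a residue matches when
the consensus amide H/N shifts fall within the matching tolerances of the
reference amide (or both are unassigned); it is missing when only the
reference assigns it, and mismatched when the result assigns something the
reference does not confirm. Prolines are not scored.

## Synthetic data

True shifts are drawn per residue from packaged per-amino-acid reference
statistics (mean, SD per backbone resonance); the predictions handed to the
solver in `residue_stats` mode are those same means with the SDs as errors,
so the Bayesian model's assumptions hold exactly and parameter recovery is
a fair test. About 32% of true shifts fall outside one SD of their
prediction by construction — the test suite checks this analytic
expectation. Crosspeak positions add Gaussian noise of 0.003/0.04/0.04 ppm
(¹H/¹⁵N/¹³C); intensities are positive random values around 1 (no physics —
relaxation and linewidth are out of scope). Prolines emit no amide-rooted
peaks, glycines no Cβ, and residue 1 no (i−1) peaks.

Degradation covers per-peak-type Bernoulli retention (peaks classified Cα,
Cβ or CO by their generating label), whole-spin-system deletion at a given
retained fraction — uniformly at random or as disjoint runs of five
consecutive residues — and artifact injection: artifacts are added until
the requested fraction of all carbon-bearing crosspeaks is artifactual,
each drawn from the residue-type Gaussians of a random compatible residue
and given its list's maximum intensity so the crosspeak cache cannot remove
it. An option forces residue pairs to share amide shifts within tolerance,
stressing the overlap-group and crosspeak-exchange machinery.

What the generator does **not** emulate: inter-spectrum referencing drift,
peak-position bias from overlap, intensity–distance relationships,
side-chain (NH₂) spin systems, and realistic (correlated) prediction errors
from structure-based predictors. Passing the synthetic suites therefore
demonstrates the correctness of the machinery and its robustness to
missing/ambiguous/artifactual data under the model's own assumptions, not
performance on any particular experimental dataset.

## Problem sizes used in the test suite

The protein-scale defaults (sample floor 10000, 20-run ensembles) are kept
as package defaults. The test suite runs the same algorithms at reduced sizes
chosen to exercise every code path on one CPU in minutes: ensembles of 5–10
runs with sample floor 600 and ceiling 6000 for the 60-residue recovery and
depletion suites, floor 300 for small fixtures, and a 6-residue problem for
exhaustive-search comparison. These are problem-size choices, not separate
tuning: quality criteria (≥95% matched, 0% mismatched on complete data;
≤3% mismatch under 40% spin-system deletion; ≥18/20 runs at the enumerated
minimum) are met at these sizes.

## Known limitations

* Assembly is greedy in input order; pathological orderings of heavily
  degenerate data could partition peaks differently (the annealer's
  crosspeak exchange corrects most such splits, but only within overlap
  groups).
* The crosspeak cache admits only peaks in the lowest 5% of intensity and
  is off by default.
* Type-set enumeration is exponential in the number of mutually ambiguous
  peaks of a spin system; real paired experiments keep this tiny, but
  adversarial synthetic input could blow it up.
* Runs execute sequentially; the ensemble is a pure fold over run results,
  so callers may parallelize runs themselves if desired.
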