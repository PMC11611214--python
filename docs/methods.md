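# Methods

This note documents the model behind `transmix`, the defaults it ships
with and why, the numerical conventions, and what the simulation study
does and does not demonstrate.

## The assortativity model

Consider `G ≥ 2` groups with census sizes `N_a` and fractions
`f_a = N_a / Σ_g N_g` (each strictly inside (0, 1)). The mixing model has
one parameter per group: the person-to-person transmission rate from an
infector in group `a` is `ψ` toward any individual of another group and
`γ_a ψ` toward individuals of its own group. `γ_a` is therefore the
multiplicative excess of within-group transmission; the baseline rate `ψ`
cancels from every quantity the package computes and is never represented.
In a fully susceptible population the expected share of a group-`a`
infector's secondary cases landing in group `b` is

    π_{b←a} = f_b / D_a        (b ≠ a),      π_{a←a} = γ_a f_a / D_a,
    D_a = (1 − f_a) + γ_a f_a

which is column `a` of the mixing matrix (`expected_mixing_matrix`);
columns sum to one identically. Inverting the diagonal relation gives the
estimator `γ̂ = π̂(1−f)/(f(1−π̂))` with `π̂ = τ_{a←a}/τ_{·←a}` read off the
transmission chain, and results are reported on the rescaled
`δ = (γ−1)/(γ+1) ∈ [−1, 1]` (δ = 1 for infinite γ). Infinite γ is a
first-class value: it is carried as `float('inf')` with explicit branches
(δ = 1; unit mixing column), never produced by overflow.

Uncertainty: `τ_{a←a} | τ_{·←a}` is treated as binomial, a Clopper–Pearson
(exact beta-quantile) interval is computed on `π`, and both endpoints are
mapped through `δ(π) = (π − f)/(π + f(1 − 2π))`. The map's derivative
`2f(1−f)/(π + f − 2πf)² > 0`, so endpoint transformation is
order-preserving and the interval is exact on the δ scale too. Boundary
conventions: `π̂ = 0` gives lower bound 0 (δ = −1), `π̂ = 1` gives upper
bound 1 (δ = +1); the point estimate then sits on the interval boundary.
A group that emitted no transmissions yields an explicit `no_emissions`
status object — batch evaluation excludes such replicates from every
denominator and reports their count, rather than aborting.

The model assumes a group's outward mixing is uniform across all other
groups (exactly representative with two groups, a simplification with
more) and that group sizes are known; the estimate is sensitive to both.

## Counting rules

`τ` counts are read from infector→infectee pairs. Imported cases (no
recorded infector) never appear on the infectee side but emit like any
case. Within a time window, a pair contributes only when **both** the
infector's and the infectee's symptom onsets fall on or before the window
end — the emitting case must itself be observable at analysis time. This
both-onsets rule is a package decision; the reasonable alternative
(infectee onset only) differs negligibly in practice because infectors
almost always show symptoms before their infectees.

## Analysis windows and peaks

The peak day `T` of a group is the earliest day attaining the maximal
symptom-onset incidence at or after the group's first case (earliest-day
tie-break). The analysis window runs from the first case to
`first + round(ε·(T − first))`, rounding half up to integer days. `ε` is
interpreted on the time axis *relative to the group's first case* so that
it scales the group's pre-peak duration; multiplying an absolute calendar
day would make the window depend on when the group's outbreak happened to
start. `ε = 1` analyses exactly up to the peak. Peak asynchronicity is the
sample standard deviation (n−1) of per-group peak days, defined when at
least two groups have cases.

## The outbreak simulator

A discrete-time branching process over the `G` groups. Individual `j` of
group `a`, infected on day `s`, exerts on day `t` a force of infection
toward the whole of group `b` of `w(t−s)·R0_a·π_{b←a}`, where `w` is the
generation-time pmf on integer lags (zero mass at lag 0) and `R0_a` the
group's basic reproduction number. Group totals `λ_b(t)` give each
susceptible the infection probability `p_b(t) = 1 − exp(−λ_b(t)/N_b)`; the
day's new case count is `X_b(t+1) ~ Binomial(S_b(t), p_b(t))`, new cases
are allocated at random among susceptibles, infection confers permanent
immunity, and each new case's infector is drawn with probability
proportional to the individual FOI contributions toward its group. Summed
over all days and targets, an infector's expected emission in a fully
susceptible population is exactly `R0_a`; the suite verifies first-
generation offspring calibrate to `R0` within Monte-Carlo error, and that
realised within-group fractions match `π_{a←a}` far from saturation.

Onset dates are infection day plus an independent draw from the incubation
pmf; onsets drive only analysis windows, never dynamics. One seeded
generator drives each simulation with a fixed draw order (per-group
binomials in group order, then infector attribution in case order, then
incubation draws), so a scenario plus a seed reproduces a byte-identical
tree. The daily loop exits once no infector can still transmit, which for
nosocomial population sizes ends outbreaks long before the default
365-day horizon.

Generation-time and incubation distributions default to gammas discretised
onto integer days (CDF increments over (k−½, k+½], day-0 cell from 0,
tail truncated at 1e−9 and renormalised; generation time additionally
zeroes lag 0 and renormalises — a case cannot transmit on its infection
day). Defaults: generation time mean 5 d, sd 2 d; incubation mean 4 d,
sd 2 d — representative of respiratory viruses that drive nosocomial
outbreaks (coronaviruses, influenza, RSV). These are emulation choices,
configurable per scenario, not estimates of any particular pathogen.

## Scenario ensembles

The default nosocomial ensemble samples, per scenario: number of groups
uniform on {2,3,4}; total population uniform on [50, 500] split by a flat
Dirichlet with a floor of 2 per group (largest-remainder apportionment);
per-group δ uniform on [−1, 1] with a 20% point mass at exactly 0 (so
specificity — the no-effect case — is measurable); per-group R0 uniform on
[1, 4]; 1–5 total imports allocated uniformly across groups at day 0. All
ranges are exposed in the ensemble spec; nothing is hidden. Scenario `i`,
replicate `j` draws its seed deterministically from
`SeedSequence((base_seed, i, j))`, so any single run can be re-executed in
isolation and a study is exactly reproducible from its spec and base seed
(the written manifest records the spec, per-scenario parameters and
seeds; re-running `transmix evaluate` on the same spec and seed reproduces
the report byte-for-byte).

## Performance metrics

Per scenario × group × ε × α cell, across replicates: bias
`mean(δ_true − δ̂)` (positive = assortativity underestimated); coverage =
fraction of valid replicates whose CI contains `δ_true` (target 1−α, with
Clopper–Pearson conservatively above); sensitivity = fraction whose CI
excludes 0, computed only where `δ_true ≠ 0`; specificity = fraction whose
CI contains 0, only where `δ_true = 0` exactly (hence the ensemble's point
mass). Default α grid: {0.05, 0.1, 0.25, 0.5}. Replicates with undefined
estimates are excluded and counted; a cell with no valid replicate is
flagged, never dropped silently.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the study at 200 scenarios
× 50 replicates (plus a 100 × 100 termination ensemble), which one CPU
completes in a few minutes while leaving the metric means stable to well
under the tolerances asserted; the calibration checks use 10,000
single-index replicates and two-group populations of 2×20,000 analysed
over a short early window (first ~3 generations) as the far-from-
saturation regime.

## Known limitations and honest failure modes

* **Saturation bias at the peak is real and size-dependent.** Analysing up
  to the group's peak keeps bias small for small outbreaks, where CI width
  dominates. In large populations the same analysis is no longer safe: at
  the onset peak of an SIR-like epidemic roughly `1 − 1/R0` plus one
  incubation period's worth of the group is already infected, the observed
  within-group fraction is dragged toward the depleted group's deficit,
  and with thousands of observed pairs the CI becomes far narrower than
  this distortion — point estimates land ~0.07–0.10 below |δ_true| = 0.5
  and coverage collapses. The suite contains an end-to-end check of this
  regime (two groups of 5,000) that documents the effect; interpret
  at-peak estimates from large, substantially depleted populations with
  caution, or analyse an earlier window.
* Transmission chains are taken as known. Reconstruction uncertainty can
  be propagated crudely via `estimate_delta_over_trees` (mean of per-tree
  estimates with an across-tree percentile spread; count-summing variant
  behind a flag), but no posterior re-weighting is attempted.
* The simulator has no waning immunity, no time-varying R0, no
  interventions, and the generator emulates plausible nosocomial
  conditions rather than replicating any published scenario set; passing
  tests show the estimator behaves as designed under this model, not that
  any particular real outbreak satisfies the model's assumptions.
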