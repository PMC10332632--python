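# Methods

## The model

Colorectal carcinogenesis through the three major driver genes is modelled
as a continuous-time multitype branching process with five hits: activation
of the oncogene KRAS (one hit) and biallelic inactivation of the tumour
suppressors APC and TP53 (two ordered hits each).  A pool of `N` normal
stem cells feeds the first premalignant compartment at rate `muN` per cell
per year; a stage-`i` premalignant cell (carrying `i` of the five hits)
divides symmetrically at rate `alpha_i`, dies at `beta_i`, and produces one
stage-`i+1` daughter by asymmetric division at rate `mu_i` without leaving
its own stage.  The fifth hit creates a persistent malignant cell that
never dies; clinical detection follows the first such cell after a fixed
lag `Tlag`.

### Hit orderings

There are 5!/(2!·2!) = 30 legal orderings of the five hits (each tumour
suppressor's first allele must precede its second).  `fivehit.pathways`
enumerates them, groups them into six gene orders (by the position of each
gene's completing hit) and into five growth-rate cases.  The case of an
ordering is determined by where growth-relevant completions fall; because
two orderings can share the same numerical net-growth vector yet belong to
different printed cases, classification tracks the full completed-
alteration set after each hit (TP53 loss included, although it changes no
rate) and compares consecutive stages.  The eleven orderings that fit
registry incidence (gene orders KRAS→APC→TP53, APC→TP53→KRAS,
APC→KRAS→TP53, split 4/3/4) are shipped as a curated constant together
with their published rate estimates (`fivehit.fitted`): selecting them
requires the registry extract itself, which is not redistributable.
Several of the 30 orderings share identical rate assignments (heterozygous
hits change nothing), so the 30 pathways collapse to fewer distinct model
parameterisations.

### Stage rates

Colonic stem cells divide every five days, i.e. 365/5 = 73 times per year.
Growth advantages are additive over completed driver alterations: KRAS
activation raises the division rate by 0.07/y, APC inactivation lowers the
death rate by 0.2/y, and nothing else (heterozygous hits, TP53 loss) moves
either, giving net growth 0 / 0.07 / 0.2 / 0.27 per year for the four
possible regimes.  The death rate of no-advantage stages is set equal to
the division rate so their net growth is exactly zero.

## Hazard solutions

### Approximate (clone-expectation) hazard

The expected compartment sizes satisfy the linear cascade
`dE[P_i]/dt = lam_i E[P_i] + mu_{i-1} E[P_{i-1}]` with source `muN·N`, and
the approximate hazard is `h(t) = mu4·E[P4(t−Tlag)]`.  The cascade is
solved two ways: by the matrix exponential of the augmented linear system
(exact for any rates, including repeated or zero net growth — which covers
every one of the 30 pathways), and, when all four net growth rates are
distinct and nonzero (pairwise gaps and magnitudes above 1e-6/y), by the
Laplace-residue closed form.  The two paths agree to ~1e-12 relative where
both apply, and the test suite asserts that agreement.

### Exact (generating-function) hazard

Let `Phi_i(t)` be the joint PGF of the process started from one stage-`i`
cell, evaluated at the point that marks "no malignant cell yet" (all
premalignant arguments 1, malignant argument 0).  The Kolmogorov backward
equations close the chain from the top:

    dPhi_i/dt = alpha_i Phi_i² − (alpha_i + beta_i + mu_i) Phi_i
                + mu_i Phi_i Phi_{i+1} + beta_i,       Phi_5 ≡ 0,

with `Phi_i(0) = 1`.  The middle coefficient is `−(alpha+beta+mu)`: this is
the form under which `Phi ≡ 1` is stationary when nothing can change state
and under which a single-stage submodel reduces to `Phi_4 = exp(−mu4·t)`;
both properties are asserted in tests, and the full solution is validated
against the stochastic simulator.  Survival takes the filtered-Poisson
form `S(t) = exp{muN·N ∫0^{t−Tlag}(Phi_1 − 1) ds}`, whence

    h(t) = muN · N · (1 − Phi_1(t − Tlag)).

The system is integrated by fixed-step fourth-order Runge-Kutta, step 0.01
years by default; halving the step changes `Phi_1` at t = 100 by less than
1e-8, and the integrator raises if any `Phi` leaves [0, 1] by more than
1e-6 (values inside the tolerance band are clipped).  At the biological
division rates (~73/y) the step gives `alpha·h ≈ 0.73`, well inside the
RK4 stability region.

### When the approximation fails

The clone-expectation hazard counts mean clone sizes, while the exact
solution accounts for the probability that each clone ever transforms.
Once `mu4·e^{lam4·t}/lam4` is of order one, the per-clone transformation
probability saturates and the approximation overshoots — by a factor ~3 at
the comparison settings (`N = 1e7`, all `mu = 1e-5`, net growth
0.10/0.15/0.20/0.25, division rate 0.5/y) across ages 30–80, growing
monotonically with the division rate (ratios ~3.7, 4.5, 9.4, 17 at
division rates 0.5, 1, 10, 50/y at age 80).  The two solutions never agree
to within a few percent at late ages in this regime; only the qualitative
ordering and the monotone trend are stable properties, and those are what
the tests assert.

## Stochastic oracle

`fivehit.gillespie` simulates the identical process exactly (event-driven,
one channel per reaction).  Whole-lifetime simulation at biological rates
(`N = 1e8`, rates ~73/y) is infeasible event-by-event, so oracle
comparisons run down-scaled: `N = 1e3` with `muN` inflated to keep the
influx `N·muN` of order unity, stage mutation rates at 9e-3/y, division
rates 0.35–0.5/y, horizon ~32 years — chosen so the cumulative risk is
~0.2 and a replicate needs a few thousand events.  The comparison itself is
parameter-free: the empirical survival and first-hit-time CDF from 1e4
replicates must match the generating-function solution within three
binomial standard errors and the 1% Kolmogorov–Smirnov band.  Agreement is
also asserted across three net-growth patterns spanning the growth cases.

## Synthetic incidence data

`fivehit.synthetic.generate` evaluates the exact hazard at integer ages
0–84 (registries top-code at 85+), converts to a rate per 100,000
person-years, divides by the configured triple-driver fraction (default
0.15) so the series resembles a total-registry curve of which the model
describes a subset, and optionally replaces each age's rate by a Poisson
draw given person-years at risk (default 1e5 per age; the observation
model is the package's choice).  The generator reproduces exactly the
statistical structure the fitter assumes — same solver, same age grid.
What passing recovery tests on such data shows is therefore internal
consistency of the pipeline, not robustness to model misspecification,
cohort effects, sex or period structure, or registry reporting artefacts,
none of which are emulated.

## Rate estimation

The fitted vector is `Theta = (v, mu1..mu4)` with `v = N·muN`; stage
growth/death rates follow from the pathway, `N = 1e8` and `Tlag = 5` y are
fixed.  Priors: `log10 v` uniform on (−2, 2); each `mu_i` uniform on
(0, 1e-2).  The discrepancy is the RMS distance between log10 incidence
curves over the positive data ages past the lag, and the posterior is the
prior tilted by a Gaussian kernel `exp(−d²/2ε²)` — the smoothed
"simulated likelihood".

The sampler exploits two structural facts.  First, `v` scales the hazard
exactly (`h = v·(1 − Phi_1(mu))`), so the best `v` for any `mu` has a
closed form (profile optimum) and `v`-proposals are centred there.
Second, near its minimum the squared profiled distance is approximately
quadratic in `log mu`, so the kernel posterior is locally Gaussian with
covariance `ε²H⁻¹`.  The evaluation budget (`n_particles × n_rounds`
model solves; 2500 at the defaults) is spent as: one uniform prior round;
three annealed elite-resampling rounds (full-covariance perturbations
scaled by each parent's distance, small-step polish moves around the
incumbent best, and permutation moves of the stage rates — the cascade is
near-exchangeable in the `mu_i` when stages share a net growth rate, so
the distance surface has near-twin modes that permutations jump between);
one refinement round and one final round drawn from a Student-t (df 5)
proposal.  At fine tolerances the t-proposal comes from the local
quadratic (Laplace) fit in log-rate space, exponentially tilted toward the
uniform-`mu` prior; at coarse tolerances (ε ≥ 0.02, e.g. noisy data),
where the quadratic expansion is invalid, its moments are estimated
directly from the kernel-and-prior-weighted archive of all evaluated
points.  Final draws carry importance weights prior × kernel / proposal,
truncated at mean·√n to bound outlier influence.

The bandwidth adapts as `ε = max(0.005, 0.75·d_best)` so noisy data are
not over-resolved; 0.005 is the smallest value at which the final round
sustains an effective sample size near 100 at the default budget.  A fit
attempt is accepted when the effective sample size reaches the configured
gate (default 50) and enough final draws fall within twice the bandwidth;
a failed gate triggers a deterministic restart with a re-derived seed (the
whole fit remains reproducible under its seed), and if no attempt ever
reaches the tolerance the fit raises.  Summaries are weighted quantiles
(median, 2.5%, 97.5%) with midpoint plotting positions.

### What is and is not identifiable

On noise-free self-generated data the KRAS-first fit concentrates around
the truth: all four stage rates land inside their published 95% intervals
for the majority of seeds, and the initiating rate `v/N` is recovered
within ±5% for most seeds (±13% worst-case over 26 seeds at the default
budget).  Its seed-to-seed scatter of a few percent is the resolution
limit of the scaled-down budget and should be kept in mind when comparing
against intervals narrower than that.  Two structural degeneracies are
worth knowing.  When consecutive stages share a net growth rate the
expected cascade is symmetric under swapping the corresponding mutation
rates, so the posterior has near-twin modes; the sampler's permutation
moves find the dominant one, and summaries describe that mode.  When the
first stage has zero net growth (APC- or TP53-first orderings),
`E[P1] = v·t` and the curve constrains essentially only the product
`v·mu1`: the product is recovered to a few percent while `v` and `mu1`
separately can trade off over several-fold.  Fits for such pathways should
be read accordingly.

## Problem sizes and defaults

| quantity | default | note |
| --- | --- | --- |
| RK4 step | 0.01 y | halving changes Phi1 by <1e-8 |
| closed-form guard | 1e-6 /y | min pairwise gap and magnitude of net growth |
| ABC budget | 500 × 5 | particles × rounds = model evaluations |
| kernel bandwidth floor | 0.005 | RMS log10 units |
| ESS gate / summary floor | 50 | triggers restart / summary error |
| oracle replicates | 1e4 | down-scaled parameter set, horizon 32 y |
| ages | 0–84 | integer years, registry top-coding |
| person-years per age | 1e5 | Poisson observation model |
| triple-driver fraction | 0.15 | share of cases the model describes |

## Known limitations

- No mechanistic distinction between point mutation and loss of
  heterozygosity for the tumour-suppressor allele hits.
- No age-, sex- or calendar-period-dependent rates; no competing
  mortality; detection is a fixed five-year lag rather than a distribution.
- The stochastic simulator is event-driven only; no tau-leaping, so
  biological-scale parameter sets are out of its reach.
- Posterior intervals from the scaled-down ABC budget are approximate;
  they are kernel-smoothed and truncated-weight estimates, not exact
  posterior quantiles.
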