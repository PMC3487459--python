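# Methods

## The model

We study adaptation of a bacterial population on a multilocus fitness
landscape with limited peak accessibility. A genotype is a binary string
over `L` biallelic loci (allele `0` deleterious, `1` beneficial), encoded
internally as the integer whose bit `l` holds the allele at locus `l`;
strings are printed most-significant-bit first, so `"1111"` is the global
peak. The basal landscape is smooth and single-peaked: a genotype carrying
`k` deleterious alleles has Malthusian fitness `m(k) = 1 − s·k^ε`. The peak
has fitness 1 by construction; `s > 0` is the fitness reduction per
deleterious allele; `ε > 0` bends the schedule (`ε = 1` additive; `ε < 1`
places intermediates below the chord between the extremes — positive
magnitude epistasis in the convention used throughout this package;
`ε > 1` negative). Construction fails loudly whenever `s·L^ε > 1` would
produce negative fitness.

A *fitness topography* designates a subset of the `2^L − 2` intermediate
genotypes as low-fitness genotypes (LFGs), overlaid with `m = 0` exactly.
An LFG is not inviable — Malthusian fitness 0 just means far less fit than
its neighbors — but it creates sign epistasis and can block mutational
paths. Because relabeling loci maps landscapes onto dynamically identical
landscapes, topographies are grouped into orbit classes under the
symmetric group acting on locus positions; screens integrate one
representative per class and copy its statistics to the other members.

## Deterministic dynamics

Frequencies evolve by mutation (per-locus rate `μ`, forward = backward),
selection on Malthusian fitness differences, and transformation:
single-allele replacement at one locus per event, drawing the incoming
allele from a free-DNA pool whose allele frequencies mirror the
population. `r` is the *total* per-genome uptake rate; each locus is
replaced at `r/L` (`rate_convention="per_locus"` applies `r` per locus
instead). Under the total-rate convention the two-locus critical
recombination rate equals the fitness difference between the extreme
genotypes independently of `L`-scaling ambiguity, which is why it is the
default.

Integration uses `scipy.integrate.solve_ivp` with LSODA, `rtol = 1e-10`,
`atol = 1e-14`. Fixation (peak frequency crossing 0.99) and
mean-fitness-threshold crossings are located by the solver's event
machinery, not post-hoc interpolation. Output states are clipped at 0 and
renormalized only when the simplex drift exceeds 1e-8 (each intervention
is logged). The linkage-disequilibrium null check — `D(t)` identically 0
on the additive no-LFG landscape — is run at `rtol = 1e-12` because the
1e-9 bound it asserts sits below the discretization error of the default
tolerance; T_fix values agree to at least five digits across both
settings.

Non-fixation is a first-class result (`FixationResult.fixed = False` with
the censoring time), never an exception: above a critical recombination
rate a valley landscape's unadapted state is stable, which is a finding,
not an error. The critical rate itself is computed two independent ways:
bisection on the sign of the leading eigenvalue of the numerically
differentiated Jacobian of the mutation-free dynamics at the unadapted
fixed point, and bisection on the long-time outcome of an invasion
experiment seeding the peak genotype at frequency 1e-5 (the inoculum
introduces an O(0.2·δ) bias in the located threshold, far below the 1e-4
agreement the tests require).

## Stochastic dynamics

The finite-population model is a Moran-type continuous-time chain over
genotype compartments with four independent event families: birth at
`B·f_i·n_i` with Fisherean fitness `f_i = e^{m_i}`, density-dependent
death at `B·(N/N0)·n_i`, mutation to each Hamming neighbor at `μ·n_i`, and
transformation to `flip(i, l)` at `(r/L)·n_i·A_l/N`, where `A_l` counts
individuals carrying the incoming allele. The density-dependent death term
is the simplest closure that regulates `N` around the carrying capacity
`N0` while keeping independent +1/−1 state changes; it lives behind a
single rate-function seam so alternative closures can be swapped.

The simulator core (numba-compiled) is a hybrid of Gillespie's exact SSA
and tau-leaping. Any event channel touching a compartment smaller than
`tau_leap_threshold` (default 100) fires exactly; the remaining channels
advance by Poisson leaps over a step chosen so no compartment's expected
total flux exceeds `leap_eps = 0.03` of its size (floored at one event).
Leap draws that would drive a count negative are re-drawn over a halved
step. Setting the threshold to infinity recovers pure SSA, which is the
correctness reference: the tau-leap path must be statistically
indistinguishable from it (two-sample Kolmogorov–Smirnov at α = 0.01 in
the tests), and the pure SSA itself reproduces the Moran fixation
probability `(1 − 1/w)/(1 − w^{-N})` within binomial error when the
resident sits at its demographic equilibrium. That equilibrium caveat
matters: the resident's stationary population size is `e^{m}·N0`, so the
closed-form comparison is run with a resident at `m = 0` (`L = 2`,
`s = 0.5`); starting a fitter resident at `N0` means an expanding
population and a genuinely higher fixation probability.

Replicate seeds derive from one master seed via
`numpy.random.SeedSequence`, with separate child streams per arm
(with/without recombination), so any replicate is independently
reproducible. The censoring horizon defaults to 50× the deterministic
fixation time of the same landscape without recombination. Censored,
extinct and peak-lost replicates are reported separately and never enter
mean fixation times.

### Mean-field limit

The exact `N → ∞` limit of this simulator has selection term
`B·(f_i − f̄)·x_i` — Fisherean differences — while the deterministic model
under study uses Malthusian differences `(m_i − m̄)·x_i`. With peak
fitness pinned at `m = 1` the two differ by a smoothly varying time-warp
factor `≈ e^{m̄}`, so finite-size convergence is validated against the
true mean-field ODE, available as
`DynamicsParams(selection_scale="fisherean")`. On a two-locus landscape
(`s = 0.1`, `μ = 1e-3`, `r = 0.05`, 20 replicates) the sup-norm deviation
of the mean peak-frequency trajectory falls monotonically,
roughly 0.4 → 0.1 → 0.02 over `N0 = 1e3, 1e4, 1e5`.

## Screening and statistics

Deterministic screens cover every topography up to a given LFG count
(enumeration order: by count, then lexicographic over sorted genotype
indices, making screens reproducible and resumable); stochastic screens
use seeded uniform samples of topographies at fixed LFG counts. Box
statistics per LFG count use inclusive linear-interpolation quantiles with
1.5×IQR whiskers. Rank concordance between parameter sets reports
least-squares R², slope and Spearman's rho over shared topographies.

Physiological epistasis is estimated by regressing fitness against the
number of deleterious mutations, `m(k) = 1 − b·k^ε̂`, by nonlinear least
squares multi-started over `ε̂ ∈ {0.25, 0.5, 1, 2, 4}`. Two conventions
are supported. With both `(b, ε̂)` free the fit recovers `(s, ε)` exactly
on LFG-free landscapes, but on LFG landscapes scale and exponent trade
off, so the exponent alone does not carry the curvature sign. With the
scale pinned to the basal `s` (`fix_b = s`, the convention used by the
screening CLI and the acceptance script) the exponent is a pure curvature
measure: any LFG drags intermediate fitness below the basal schedule and
forces `ε̂ > 1`, matching the observation that all six-LFG landscapes show
positive epistasis. Under that measure `ε̂` explains only ~16% of the
variance in T_fix across the 3003 six-LFG landscapes (R² < 0.25, our
operationalization of "no useful predictive power"): one-dimensional
epistasis summaries do not predict the recombination effect.

## Standard parameters and problem sizes

Inferred defaults, declared once in `RunConfig` and echoed into every
manifest: `L = 4`, `s = 0.05`, `ε = 1.0`, `μ = 1e-5`, `r = 0.05`,
deterministic fixation threshold 0.99, stochastic threshold 0.95 (the two
thresholds follow the respective model conventions), `B = 1`, `n_reps = 50`
per arm, `N0 = 1e4`. The deterministic screen shipped with the acceptance
script covers all LFG counts 0–6 (6476 topographies, 401 orbit classes);
the stochastic screen uses 10 sampled three-LFG topographies at
`N0 = 1e4` with 10 replicates per arm, sizes at which the full pipeline
completes in about a minute while every qualitative contrast (monotone
deceleration with LFG count, Fisher–Muller sign flip, rank preservation)
is already stable across seeds.

## What the tests do and do not show

All inputs are generated by the package itself — landscapes are exact
mathematical objects, not data — so there is no measurement noise to
emulate; the synthetic element is the choice of topography and parameters.
The test suite demonstrates the model's internal consistency (conservation
laws, symmetry equivariance, independent oracles for enumeration, Euler
cross-checks, eigenvalue-vs-invasion agreement, SSA-vs-closed-form and
SSA-vs-tau-leap agreement) and the robustness of the headline qualitative
results at desk-scale problem sizes. It does not establish anything about
empirical bacterial fitness landscapes: real landscapes need not decompose
into a smooth basal gradient plus fitness-zero obstacles, transformation
imports tracts rather than single alleles, and competence regulation is
outside the model.

## Known limitations

* Heterogeneous per-locus selection coefficients, NK/Rough-Mount-Fuji
  generators and diploid genetics are out of scope.
* The hybrid simulator's leap-step redraw on negativity introduces a
  formally unquantified (empirically undetectable at α = 0.01) bias;
  pure-SSA mode is always available as the exact reference.
* The all-topography screen is exhaustive only through the LFG counts
  requested; beyond ~10 LFGs at `L = 4` the enumeration is complete but
  per-topography integration cost dominates.
* Fixation-time ratios are undefined (NaN, flagged) when either arm fails
  to fix within the horizon; screens record such rows as censored rather
  than dropping them.
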