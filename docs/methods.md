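# Methods

## Scope and model class

`kincal` calibrates deterministic kinetic models of biochemical
networks to replicated time-course measurements, assesses which
parameters the data actually constrain (profile-likelihood
identifiability), and compares alternative network topologies by
information criteria.  The motivating application is transcriptional
response data — e.g. Smad7/Ski induction in fibroblasts stimulated
with TGF-β — measured by qPCR in arbitrary units, but nothing in the
toolkit is specific to that system.

A model is a single-compartment reaction network: species with initial
amounts (optionally fixed, for inputs such as a constant stimulus),
kinetic parameters, and reactions with algebraic rate laws over
`+ - * / ** exp`.  The induced ODE system is `dx/dt = N v(x, θ)` with
stoichiometric matrix `N`.  Events, assignment rules, delays and
stochastic simulation are out of scope.  Time is in hours; the single
unit-size compartment makes amounts and concentrations interchangeable.

## Observation model and weighting

Measurements in arbitrary units are linked to model units by the
observation function `X_obs(t) = X(t) / X_SF` with a per-observable
scale factor `X_SF > 0` (default 100).  Empirical baselines can be
propagated into the model with `X(t0) = mean(X_obs at t0) · X_SF`.

The objective is the weighted residual sum of squares over every
replicate data point:

    RSS(θ) = Σ_{t,o,r} ((y_{t,o,r} − X_o(t;θ)/X_SF,o) / σ_{t,o})²

with `σ_{t,o}` the sample standard deviation (ddof = 1) of the
replicates at that time and observable.  Residuals are computed per
replicate rather than against replicate means so that the data-point
count `n` entering the information criteria equals the number of
measurements.  Standard deviations are floored (default: 5% of the
observable's grand mean) so coinciding replicates cannot produce
infinite weights; missing values are skipped, never imputed.  With
weighting disabled, `σ ≡ 1`.

qPCR cycle-threshold plates are normalized by the 2^−ΔΔCt method:
per sample, ΔCt = Ct(target) − mean(Ct of reference genes) — the
arithmetic reference mean is equivalent to normalizing linear
expression to the reference genes' geometric mean — then ΔΔCt is taken
against the mean ΔCt of the calibrator samples and exponentiated base 2.
The calibrator defaults to all t = 0 samples, matching the
fold-change-from-baseline presentation of such data; amplification-
efficiency correction and plate effects are not modelled.

## Numerics

Simulation uses `scipy.integrate.solve_ivp` with LSODA (stiff-capable,
adaptive) at rtol 1e-8 / atol 1e-10.  Inside the objective these
tolerances are configurable (`FitProblem(sim_rtol=, sim_atol=)`);
loosening to 1e-6/1e-9 — as the bundled experiments do — speeds up
global search several-fold at the cost of ~1e-6 relative noise on RSS.
Trajectories exceeding ~1e12 in magnitude abort immediately as
diverged; any integration failure maps to an infinite objective value
(with a logged warning) so stochastic search continues.  Rate laws are
compiled once per model structure to plain Python functions, making an
objective evaluation on the bundled fixtures ~1–2 ms.

## Optimization

Parameter bounds default to 1e-7..1e4 — eleven decades — so all search
runs in log10 space; linear-space search over such a box is hopeless.

* **Global**: a real-coded genetic algorithm (default population 300,
  500 generations) with tournament selection of size 2, uniform
  crossover (p = 0.5), per-gene Gaussian mutation (p = 1/d, σ = 0.2
  decades) and elitism of one.  These internals are this package's own
  choices, validated by the convergence benchmarks; starts are drawn
  log-uniformly within bounds.
* **Local ("chaser")**: Hooke & Jeeves pattern search — exploratory
  ± step moves per coordinate, pattern extrapolation along successful
  directions, step halving on failure — terminating when the step
  falls below the tolerance or the iteration limit is reached
  (defaults: 1e-10 / 1000 when refining archive candidates, 1e-6 / 50
  inside profile re-optimizations; initial step 0.2 decades).

Repeat estimations run `n` independent optimizations with per-run seeds
`base + i`, so the archive is a deterministic function of the base seed
and independent of the worker-pool size (a thread pool caps concurrent
evaluations; cluster schedulers are out of scope).  Archives are ranked
by RSS (ties broken by run id) and can be truncated by fraction, count
or RSS cutoff before plotting — sub-optimal sets otherwise distort
distributions and correlations.

## Identifiability

A profile likelihood fixes one parameter on a log10 grid (default 20
points per direction over ±3 orders of magnitude, intersected with the
bounds) and re-optimizes all remaining parameters at each point with
the pattern search, warm-started from the neighbouring point's solution
sweeping outward from the best value — warm starts keep profiles smooth
and cheap.  The curve is compared with a likelihood-ratio threshold:

* `chi2_pointwise` (default): best RSS + Q_χ²,1(α), valid when the RSS
  is weighted by the true error scales; α defaults to 0.95.
* `f_based`: best RSS · (1 + Q_F,1,n−p(α)/(n−p)), which does not assume
  the weights are exact error scales.

Classification: a curve whose total RSS variation is below a relative
flatness tolerance (1e-3) is *structurally* non-identifiable — flagged
"suspected", because a scan can only sample the space — with infinite
confidence bounds.  Otherwise threshold crossings are located on a
monotone cubic spline (PCHIP) of RSS against log10(value); crossings on
both sides make the parameter *identifiable* with the crossings as
confidence bounds, anything else is *practically* non-identifiable with
only the crossed side bounded.  Re-optimized trajectories of the other
parameters along the scan (co-parameter traces) expose compensatory
relationships — a product coupling appears as a slope −1 line in
log-log space — which is the information model reduction needs;
automated reduction itself is not attempted.  Profiles are only
meaningful from (near-)optimal starts, so the intended workflow is
global search → chase → profile, optionally from several top sets with
discordant classifications flagged.

## Model selection

RSS-based Gaussian forms are used (the weighted RSS standing in for
−2 log L up to a constant):

    AIC  = n ln(RSS/n) + 2k
    AICc = AIC + 2k(k+1)/(n−k−1)
    BIC  = n ln(RSS/n) + k ln(n)

`n` counts non-missing replicate data points; `k` counts only the free
(estimated) parameters.  Computing criteria from the sd-weighted RSS
assumes the replicate standard deviations are the true error scales —
a documented caveat, shared by any weighted-RSS criterion.  Models
violating `n > k + 1` are flagged and excluded from AICc ranking.
`multi_model_fit` calibrates every candidate against the same data with
disjoint seed streams (`base + model_index · n_runs`).

## Synthetic data generator

`kincal.synthetic.generate_data` emulates the study design of the
motivating experiment: observables sampled at 0, 1, 2, 4, 8, 12 h with
6 biological replicates; the simulated truth mapped into arbitrary
units by scale factors (default 100); optional derived protein
observables equal to 100× the mRNA signal lagged by 30 min (the t = 0
level is held before the lag has elapsed); optional inverse-ΔΔCt
synthesis of a raw Ct plate (Ct = mean reference Ct − log2 expression,
plus optional per-sample loading shifts and Ct noise).  Measurement
noise defaults to Gaussian with cv = 0.1 of the signal, clipped at
zero (the alternative is multiplicative lognormal, or none); noise on
the derived protein profiles is optional because real derived data
would inherit the mRNA measurement noise.

What the generator does *not* emulate: amplification-efficiency
variation, plate effects, outliers, non-constant replicate structure,
or the absolute magnitudes of any particular real data set.  Passing
tests therefore demonstrate correctness of the machinery under the
stated noise model, not robustness to the full messiness of real qPCR
data.

### Fixture models

All fixture parameter values were drawn once and committed as
constants so tests are stable.

* **Regulatory motifs** (idealized selection problem): negative
  feedback (output X induced by the stimulus, repressed by its target
  F), positive feedback, and a coherent feed-forward motif, sharing
  species names so one observation map fits all three.  Under a step
  stimulus the negative-feedback output overshoots and declines; the
  alternatives respond monotonically, which is what lets AICc recover
  the generating topology from noisy data.  The coherent (rather than
  incoherent) feed-forward variant was chosen deliberately: an
  incoherent loop can mimic adaptation and would make the selection
  problem ill-posed at this scale.
* **Smad7/Ski demo variants**: a driver species D induces Smad7 and
  Ski; Ski inhibits Smad7 transcription via a saturating term with
  `km` and `I50` parameters; Smad7 degrades D catalytically
  (variant 1), is consumed doing so (variant 2), or additionally Ski
  decays by second-order mass action (variant 3).  These are reduced
  toy analogues of the published TGF-β model variants, not
  reconstructions of them.
* **Identifiability oracles**: a one-parameter exponential decay
  (identifiable), a decay whose rate is the product k1·k2 (structural
  non-identifiability by construction), and exponential saturation
  `X' = k(Xmax − X)` observed only on the first 4% of its timescale,
  where the signal ≈ `Xmax·k·t` makes `k` practically
  non-identifiable; observed into the plateau both parameters become
  identifiable.

## Problem sizes in the bundled experiments

The validation experiments (`kincal.experiments`, also driven by
`scripts/acceptance.py`) run at reduced sizes chosen to keep each run
in seconds-to-minutes on one core: GA population 16–20 over 15–25
generations, 2–20 repeat runs, 8 profile points per direction, and 20
seeded repetitions of the three-motif selection experiment.  The
full-scale demonstration protocol (population 300 × 500 generations ×
300 runs) is carried, unchanged, in the bundled
`examples/demo_config.yaml` for use through the CLI.

## Known limitations

* Profile likelihood is a local method; classifications depend on the
  starting optimum (mitigated, not solved, by profiling several top
  sets).
* The flatness test cannot distinguish a truly flat profile from one
  flat only over the scanned span.
* The χ² threshold is pointwise (df = 1); simultaneous confidence
  regions would need the df = p variant, which is not implemented.
* The GA is a pragmatic global searcher, not a convergence-guaranteed
  one; multi-start plus chasing is the intended safeguard, and the
  likelihood-ranks plot the diagnostic for unconverged ensembles.
* SBML support is export-only (L3V1); models are authored in the
  bundled text format.
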