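# Methods

This note documents the models implemented in `synsites`, the defaults
of the synthetic-data generator, the numerical choices inside the
fitters and simulators, and the limits of what the synthetic tests can
show about real recordings.

## Silent-synapse failure analysis

A unitary connection is modelled as `n` synapses (default range 3–5)
releasing independently with probability `p` per stimulus (default
range 0.3–0.5). A fraction `s` of the synapses is AMPAR-silent:
non-responding at −60 mV, responding at +40 mV. A −60 mV sweep fails
when zero non-silent synapses release; a +40 mV sweep fails when zero
synapses release. The estimator `1 − ln(F₋₆₀)/ln(F₊₄₀)` then recovers
`m/n` where `m = n − round(n·s)` is the non-silent count.

Choices and caveats:

* **Discrete silent synapses.** The number of silent synapses per
  connection is `round(n·s)` — synapses are integral, so a connection
  cannot be 37% silent site-by-site. An alternative formulation scales
  the −60 mV release probability by `1 − s` at every synapse; it is
  available as `simulate_sweeps(..., mode="scaled-p")`. The two differ:
  the discrete model makes the estimator exactly unbiased at the rate
  level, while the rate-scaled variant carries an upward bias of up to
  ~0.06 at `s = 0.5, p = 0.4`. The discrete model is the default
  because it matches the physical picture of whole synapses lacking
  AMPARs.
* **Undefined estimates.** When a failure count is 0 or equals the
  sweep count the logarithms degenerate; the estimate is reported as
  NaN, counted, and excluded from population means — never clipped or
  imputed. With 50 sweeps and `p > 0.5` such runs are common, which is
  why release probabilities above 0.5 are outside the default range.
* **Population draws.** Per-neuron silent fractions are truncated
  normal (clip-resample to [0, 1]); only mean ± SD is specified for an
  age group. Defaults: 0.5 ± 0.15 for the P16-like group and
  0.2 ± 0.15 for the P30-like group. 50 sweeps per potential (the
  experimental protocol records 30–50).
* The estimate may be negative by sampling noise and is bounded above
  by 1; both properties are asserted, not corrected.

## Two-gamma mixture fitting

Amplitudes are fitted by maximum likelihood: first a single gamma, then
the two-component mixture initialised from it (both components at the
single-fit shape/scale, weight 0.5, scales perturbed ±25% to break the
symmetric stationary point; a second deterministic start from
moment fits of a median split guards against local optima, and the
higher-likelihood solution is kept).

* **Optimizer.** Expectation-maximisation with responsibilities; the
  shape M-step solves `ln α − ψ(α) = ln(w̄x) − w̄(ln x)` by safeguarded
  Brent iteration, the scale M-step is `β = w̄x / α`. Convergence:
  relative log-likelihood change < 1e−8 or 500 iterations, followed by
  an L-BFGS-B polish of the full likelihood.
* **Shape box.** α ∈ (0, 40]. The bound exists because nearly
  symmetric, low-variance samples push the gamma shape toward infinity;
  fits at the bound are flagged (`bound_active`).
* **Labelling.** The component with the larger *shape* is `comp1` and
  κ is its weight (ties broken by the larger scale). Note that in the
  default parameter regime (means 16.8 pA and 10.0 pA) the
  *smaller-mean* component has the larger shape, so cross-condition
  comparisons of "the weight of the big-quantal population" must match
  components by mean; the pipeline reports
  `kappa_large_mean_component` for exactly this purpose.
* **Constrained refit.** For a drug condition from the same cell the
  shapes are frozen at the baseline estimates and only κ, β₁, β₂ are
  fitted. Component *identity* across conditions is carried by the
  warm start: pass the baseline scales as `beta*_init`, otherwise
  near-symmetric shape pairs can converge with roles swapped.
* **LRT.** df = 3 (the mixture adds κ and one shape/scale pair). The
  null distribution of a mixture LRT is not exactly χ²(3) because κ
  sits on a boundary under the null; p-values approaching 0 are read
  as strong evidence, not as a calibrated size-α test.
* **Truncation.** Real detection censors events below 5 pA. Fitting
  uses only events above the floor but the likelihood is *not*
  truncated at it — with the default mixture less than ~2% of mass
  lies below 5 pA, so the bias is small, but fits to distributions
  with substantial sub-threshold mass will be distorted. This is a
  deliberate simplification.

## Scaling decomposition

Detected frequency at threshold `t` counts events with amplitude ≥ t
(events exactly at threshold count as detected). The scaling bound
multiplies each drug-condition event by the scalar 0.7 — kept exactly
as specified even though 1/1.4 ≈ 0.714 — and counts originally
detected events whose downscaled amplitude falls below `t`. Density
histograms default to 1-pA bins anchored at 0 (the mode is read from
the raw histogram, not a smoothed density); cumulative curves use 20
equal-count bins.

## Synthetic-data generator

The generator defines the study conditions for every test:

| parameter | default | rationale |
|---|---|---|
| (α₁, β₁) | (16, 1.05) | big-quantal population, mean 16.8 pA |
| (α₂, β₂) | (20, 0.5) | small-quantal population, mean 10.0 pA |
| κ | 0.45 (P16-like) / 0.30 (P30-like) | the big-quantal weight declines with age |
| event_rate | 3.5 Hz | detected rate ~2–3 Hz at an 8-pA threshold |
| duration | 300 s | ≥ 400 events per cell above the floor |
| detection_threshold | 5 pA | low-noise recording floor |
| TCM amplitude_scale | 1.4 | ~40% quantal-size increase |
| TCM unidle_rate_factor | 2.0 (P16) / 3.0 (P30) | frequency effect roughly doubles with age |
| trace kernel | rise 0.5 ms, decay 4 ms | typical AMPAR mEPSC kinetics |

Event trains are homogeneous Poisson — the standard null for
spontaneous vesicle fusion; no inter-event-interval structure is
claimed by the analyses, only rates. The drug effect is modelled as
independent amplitude and rate scaling with no interaction. Censored
events are flagged, never dropped, so ground truth stays available.

What the generator does **not** emulate: dendritic filtering and
rise-time variability, access-resistance artifacts, non-stationary
noise, amplitude–frequency correlations, or per-component rate changes
under the drug (unidling is a uniform rate factor). Passing tests
therefore validate the *computations*, not the biological fidelity of
any particular recording.

## Trace utilities

Events render as unit-peak biexponential kernels
`exp(−t/τ_d) − exp(−t/τ_r)` (normalised, sign-inverted, truncated at
12 decay constants, tail < 1e−5 of the area). The baseline for charge
transfer is a rolling 20th-percentile over 1-s windows joined by
linear interpolation — a transparent substitute for opaque
baseline-fitting tools, validated only on synthetic oracles. Charge is
∫(baseline − current) dt in pC; it is offset-invariant by
construction. Detection finds local minima below −threshold with a
minimum separation (default 5 ms); half-width uses linear
interpolation between samples, adequate at 10 kHz sampling.

## Spine simulation

Uniform model: per spine, 1–8 sites (uniform integer) all share one
assignment drawn at 5% silent / 20% unsilenced / 60% idled / 15%
unidled. The analytic fold of total effective sites after unidling is
(0.20+0.60+0.15)/(0.20+0.15) ≈ 2.71, and the expected baseline
nonresponder fraction is 65% (silent + idled); both are asserted
against the simulation within Monte-Carlo error. After the switch only
silent spines (5%) remain unresponsive.

Mixed model: per spine 1–2 silenceable sites, each silent with
p = 0.2; per silenceable site 1–3 idle-able sites on the same head.
Idling probability is conditional: 0.85 when an unsilenced site exists
on the spine, 0.50 otherwise. Only the *direction* of this conditioning
is specified by the biology (idling correlates with unsilencing); the
two values are the package's own calibration, chosen so the expected
fold lands mid-window: mean silenceable per spine 1.5 → 1.2 unsilenced;
mean idle-able per spine 3 with mean idling q̄ ≈ 0.81, giving
fold = 4.2 / (1.2 + 3(1−q̄)) ≈ 2.37. Both values are config-exposed.

Other choices: site counts are uniform integers over the stated ranges
(no other distribution is specified); unit responses are drawn with
replacement from the per-run seeded 50×50 Normal(−4, 1) pool; folds
are ratios of per-iteration *totals*, averaged over the 10 iterations
(per-spine ratios would divide by zero at nonresponders; an all-idled
iteration yields NaN, never ∞); the nonresponder criterion for
simulated uncaging is |response| ≤ 1.5 pA, alongside the exact
N_eff = 0 count. The multi-Gaussian quantal-peak fit uses Gaussian
mixtures for 1..k components selected by BIC.

## Pipeline and reproducibility

`run_study` derives every stage seed from the master seed via a
spawned `SeedSequence`, embeds the seed and a SHA-256 configuration
hash in all outputs, and reproduces the report bundle byte-identically
for a fixed configuration. Stage failures abort with the stage name
and config hash. Outputs are tables (CSV) and summaries (JSON) only.

Problem sizes throughout (300-s recordings, 2000-event fitting
benchmarks, 10⁴-sweep estimator checks, 1000×10 spine populations) are
desk-scale: the full suite and the study pipeline each run in well
under a minute of CPU, which keeps the statistical checks comfortably
powered without simulation overkill.

## Known limitations

* The untruncated mixture likelihood biases fits when sub-threshold
  mass is substantial (see above).
* The LRT is used for evidence, not calibrated inference, because of
  the boundary problem.
* The uniform-model expected baseline nonresponder fraction (65%) and
  fold (≈2.71) follow from the stated assignment probabilities; they
  are reported as-is rather than adjusted toward any target range.
* Component identity in constrained refits is a warm-start convention,
  not an identifiability guarantee; with nearly equal shapes the
  labelling can legitimately swap.
* The estimator population simulations assume release probability is
  identical across the synapses of a connection and across sweeps.
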