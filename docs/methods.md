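# Methods

## Scope

`eitrack` estimates time-varying excitation/inhibition balance from a
single EEG channel by assimilating the signal into a Jansen–Rit
neural-mass model with an adaptive, constrained ensemble Kalman filter.
This note records the model, the estimator, the design choices that were
genuinely open, and what the synthetic validation does and does not
establish.

## Forward model

The Jansen–Rit column lumps three populations (pyramidal cells,
excitatory and inhibitory interneurons) into six ODEs in the average
postsynaptic potentials; the observable is `y = v1 − v2`, which behaves
like a single EEG channel. Parameters and units:

| parameter | meaning | default | units |
|---|---|---|---|
| `A`, `B` | excitatory / inhibitory synaptic gain | 3.25, 22 | mV |
| `a`, `b` | inverse synaptic time constants (τ = 1/a) | 100, 50 | 1/s |
| `p` | background input pulse density | 220 | 1/s |
| `C1..C4` | connectivity counts | 135, 108, 33.75, 33.75 | – |

With `p` in roughly 120–320 the model sits on an alpha-band (~10 Hz)
limit cycle; `a`, `b` in 5–200 1/s span synaptic time constants of
5–200 ms and keep the output in the delta-to-beta range. These ranges
double as the filter's interval constraints. Integration is classical
RK4 at the sampling interval (`dt = 0.01` s for 100 Hz data), with
parameters held fixed within a step's four substage evaluations. A
guard (default `1e6`) converts numerical blow-up into a clean error.
At `dt = 0.01` the integrator is adequate for generating and filtering
EEG-like signals but not phase-accurate to 1e-3 over seconds (ten
samples per alpha cycle); its fourth-order convergence is verified in
the tests at finer steps.

## Synthetic-data generator

The benchmark scenario is 3000 samples (30 s at 100 Hz) in two
half-open segments with a simultaneous step at t = 15 s
(A: 3.25→4.25, B: 22→19, b: 50→52; a = 100 throughout). The input `p`
is redrawn once per output sample from N(220, 22) — 22 read as a
variance — and held through the RK4 substages; white observation noise
N(0, 1.3) is added to the clean output. The generator starts from the
zero state; an optional burn-in (default 0 s) first settles the model
on its limit cycle under the first segment's parameters, which matters
only for spectral and SNR summaries. No additional state noise is
injected: stochasticity enters through `p` and the observation noise
only, so the filter's `Q` is a modelling choice, not a generator
property.

What the generator emulates: a stationary alpha-band rhythm with an
abrupt, known E/I change and heavy white measurement noise (power SNR
< 5). What it does not emulate: 1/f background activity, artifacts,
drowsiness-related nonstationarity, volume conduction, or multi-channel
structure. Passing the synthetic checks therefore shows the estimator
is self-consistent under its own model class, not that real sleep EEG
satisfies that model.

## The filter

State: `x = [v0..v5, A, a, B, b, p]` (11-dimensional). Observation row
`H = [0, 1, −1, 0, …, 0]`; base observation covariance `R = 50` scaled
by a gamma-distributed precision factor `η ~ G(α, β)` with
`α0 = 1, β0 = 0.5`. State-noise covariance presets:
`diag([dt·10⁻²]×6, [10⁻³]×5)` for synthetic data and
`diag([dt]×6, [10⁻³]×5)` for real EEG.

Per sample:

1. **Predict** — every member's `v`-block is advanced one RK4 step
   using that member's own parameter block (parameters are a random
   walk); independent N(0, Q) perturbations are added; the predicted
   covariance is the ensemble covariance plus Q. Members that leave the
   finite/guard region are re-sampled from the surviving members'
   statistics (counted and reported).
2. **Update** — `α += 1/2`; with `⟨η⟩ = α/β` the effective observation
   covariance is `R/⟨η⟩`. A stochastic EnKF update with
   perturbed observations `w_i ~ N(0, R/⟨η⟩)` moves each member; the
   posterior covariance uses `P − K P_yy Kᵀ`. Then
   `β += (‖y − H x̂‖² + H P̂ Hᵀ) / (2R)` evaluated at the **posterior**
   mean and covariance. This is the exact variational update for the
   gamma factor (the expected squared residual under the current state
   posterior): its fixed point is the true noise variance whenever the
   ensemble spread is calibrated. Evaluating the same expression at the
   predicted state instead creates a positive feedback between the
   perturbed-observation spread and `β` and settles far above the true
   variance — we verified this empirically (≈6× inflation on the
   benchmark) and use the posterior form.
3. **Constrain** — components violating their interval are replaced by
   the covariance-weighted projection
   `x̂ = x − P Dᵀ (D P Dᵀ)⁻¹ (D x − d)`. Because `D` is a selection
   matrix, the projected value of an active component is exactly its
   bound, so the operation reduces to clamping those components; the
   implementation keeps the general formula with a clamping fallback if
   `D P Dᵀ` is singular. Both the stored estimate and (by default) each
   member are projected — member projection keeps every member's ODE
   integration inside the stable parameter regime.

Randomness: one root seed spawns three independent streams
(initialization, process noise, observation perturbations), so runs are
bit-reproducible and ensemble-size sweeps comparable.

### Initialization

`x0 = 0` for the `v`-block — which is also the generator's true initial
state — with unit prior variance. The printed-zero initial mean is
infeasible for every parameter, so the parameter block needs its own
prior: members are drawn around the canonical Jansen–Rit values
(3.25, 100, 22, 50, 220) with standard deviation one eighth of each
constraint interval, then projected into the feasible box. Rationale:
a weakly informative prior centred on the standard literature operating
point is what a practitioner fitting this model would choose; centring
at interval midpoints instead (b-midpoint 102.5 vs the physiological
~50) roughly doubles the startup transient in the noise-covariance
trace, and centring at zero piles essentially all members onto the
lower bounds. Both the centre (`theta0`) and `P0` are configurable.

### Noise-covariance reporting

`R/⟨η⟩` is recorded after each update; the recovered observation-noise
covariance is its time average over the final half of the run. Because
`α, β` accumulate without forgetting, this statistic keeps a `~1/t`
memory of the startup transient: on 30 s benchmark runs it settles
~10–15% above the true 1.3 even though the instantaneous equilibrium is
at 1.3 (the optional exponential forgetting factor, default off,
removes the memory at the cost of deviating from the plain accumulation
rule). An 80–120% band around the true value is the meaningful
calibration check at this record length.

## E/I indices

* `mE/I(t) = Â/(Â + B̂)` per sample; strictly in (0, 1), scale-invariant
  in the gains.
* Spectral baseline: Welch PSD (2-s Hann windows, 50% overlap), OLS of
  log10 power on log10 frequency over the closed 30–50 Hz band. The
  estimator is unbiased on 1/f^χ surrogates (χ = 1..3) but a single
  60-s realization carries ~0.15 slope noise; the band must lie within
  Nyquist, and a 100 Hz recording supports exactly 30–50 Hz — wider
  bands are refused rather than truncated, which is precisely why this
  baseline is uninformative for 100 Hz sleep data.

## Sleep pipeline

Band-pass 0.6–20 Hz, 6000-tap Hann-window FIR applied forward-backward
(exactly zero-phase; net response |B|², edge reflection padding, series
must exceed the 60 s kernel). Analysis window: 20 min of pre-onset wake
(clamped to the recording start, labelled Awake) through the end of the
first contiguous REM run; recordings with no REM, or with wake inside
the first NREM period, are flagged unusable. Stage vocabulary Awake /
S1 / S2 / S3/4 / REM (stages 3 and 4 merged; sleep-EDF annotation
strings mapped, movement/unknown epochs dropped). Per-sample mE/I is
averaged within each stage (no epoch-level intermediate).

Statistics: hand-implemented rank tests so an independent library can
serve as oracle — Kruskal–Wallis with tie correction and
`η²_H = (H − k + 1)/(n − k)`; Dunn z on pooled ranks with tie term,
two-tailed, Bonferroni over all pairs; pairwise effect size
`ϕ² = z²/(n_i + n_j)`. EMD-based artifact removal is exposed only as a
pluggable pass-through hook.

## Problem sizes and defaults

Desk-scale defaults: 3000-sample records; ensemble sweep over
{40, 100, 200} with 5 trials (the full design, sizes 40..500 step 20
with 50 trials, is a parameter away); 5 filter seeds for the
noise-recovery summary; 10 scenario seeds for the SNR summary. At
these sizes the complete validation runs in well under a minute on one
CPU.

## Known limitations

* Single channel, single column: no network coupling or volume
  conduction.
* `Q` is fixed; only the observation-noise scale adapts.
* MAE differences between 100 and 200 members sit at the
  observation-noise floor and are not resolvable with desk-scale trial
  counts; only the small-ensemble penalty (40 vs larger) is a robust
  ordering.
* The gamma posterior's transient memory biases the last-half noise
  covariance slightly upward on short records (see above).
* `A`/`B` constraint defaults ([1, 10] / [1, 50]) bracket the canonical
  values with headroom but are conventions, configurable per run.
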