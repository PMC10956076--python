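# eitrack

Model-based tracking of cortical **excitation/inhibition (E/I) balance**
from a single EEG channel, sample by sample.

Perceptual learning, sleep regulation and several psychiatric conditions
are tied to shifts in the balance between glutamatergic excitation and
GABAergic inhibition, but the established in-vivo measures (MRS,
TMS-EEG) need minutes per estimate. `eitrack` instead assimilates the
raw EEG into a Jansen–Rit neural-mass model and reads the E/I balance
off the model's synaptic gain parameters, giving a sub-second-scale
index from ordinary recordings. It is a library for computational
neuroscientists and EEG methods researchers, with a small CLI for batch
runs.

## The model and the estimator

The Jansen–Rit model couples pyramidal cells, excitatory interneurons
and inhibitory interneurons through six ODEs in the postsynaptic
potentials `v0..v5`:

```
v̇0 = v3        v̇3 = A a Sigm(v1 − v2) − 2a v3 − a² v0
v̇1 = v4        v̇4 = A a [p + C2 Sigm(C1 v0)] − 2a v4 − a² v1
v̇2 = v5        v̇5 = B b C4 Sigm(C3 v0) − 2b v5 − b² v2

Sigm(v) = 5 / (1 + exp{0.56 (6 − v)}),   y = v1 − v2  (the EEG-like output)
```

`A`/`B` are the excitatory/inhibitory synaptic gains, `a`/`b` the
inverse synaptic time constants, `p` the background input; `C1..C4` are
fixed connectivity counts (135, 108, 33.75, 33.75).

The estimator is a **variational-Bayesian noise-adaptive constrained
ensemble Kalman filter** over the augmented state
`x = [v0..v5, A, a, B, b, p]`:

* stochastic (perturbed-observation) EnKF with the parameters carried as
  a random walk through the RK4-integrated transition;
* observation noise `w ~ N(0, R/η)` with a gamma posterior
  `η ~ G(α, β)` updated variationally each sample, so the filter adapts
  to unknown and nonstationary noise power;
* interval constraints (`a, b ∈ [5, 200]`, `p ∈ [120, 320]`,
  `A ∈ [1, 10]`, `B ∈ [1, 50]`) enforced by covariance-weighted
  projection onto the bounds.

The per-sample E/I index is the **mE/I ratio**

```
mE/I(t) = Â(t) / (Â(t) + B̂(t))  ∈ (0, 1),
```

larger values meaning excitation-dominant dynamics. The package also
implements the prior spectral baseline (slope of the log-log PSD in
30–50 Hz) for comparison, and a sleep-stage statistics pipeline
(band-pass FIR preprocessing, hypnogram-aligned stage averaging,
Kruskal–Wallis + Dunn tests with effect sizes).

## Worked example

Track a known E/I shift in synthetic EEG
(`examples/02_track_ei_balance.py`):

```python
from eitrack import FilterConfig, make_step_scenario, mei_series, run_filter, simulate

record = simulate(make_step_scenario(seed=1))        # 30 s at 100 Hz, gains step at 15 s
result = run_filter(record.noisy_eeg, FilterConfig.simulation(n_ens=200, seed=1))
mei = mei_series(result)
```

which prints

```
one-step prediction MAE: 1.066
recovered noise covariance (true 1.3): 1.503
A: 3.04 then 3.93  (true 3.25 -> 4.25)
B: 25.77 then 22.44  (true 22.0 -> 19.0)
mE/I ratio: 0.106 -> 0.149  (true 0.129 -> 0.183)
```

The filter sees only the noisy channel (SNR < 5) yet recovers both
synaptic gains to within ~15%, the adapted observation-noise covariance
approaches the true 1.3, and the mE/I ratio rises across the step —
the designed shift toward excitation is detected without access to the
true parameters. The other scripts in `examples/` demonstrate the
generator, the ensemble-size sweep, the spectral-slope baseline and the
sleep-cohort statistics.

A thin CLI mirrors these capabilities:

```sh
eitrack simulate --seed 1 --output out/
eitrack fit --input out/synthetic.csv --nens 200 --seed 1 --output out/fit
eitrack sweep --sizes 40,100,200 --trials 5 --seed 7 --output out/sweep
```

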