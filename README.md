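# spikemod

Analysis of motor-cortex microelectrode-array recordings under a
subanesthetic drug: spiking-rate dynamics, multitaper spectral change,
naive-Bayes finger decoding, and the permutation-normalized modulation-depth
statistic — together with a synthetic-session generator that provides ground
truth for every stage.

## Who this is for

Electrophysiologists and neural-engineering groups who record spike rasters
and field potentials during a sensory task (here: randomized 5 s
single-finger brushings over four fingers) and want to quantify how a
pharmacological intervention changes (1) population firing rate, (2)
oscillatory power, and (3) the amount of stimulus information carried by the
population and by individual units.

## The statistics at the core

**Modulation depth.** For one unit, with μ_i and σ_i the mean and SD of its
trial firing rates when finger *i* is brushed,

    MD_ij = |μ_i − μ_j| / sqrt(σ_i² + σ_j²)
    MD_i  = min_{j≠i} MD_ij          (the most confusable comparison)
    MD    = (1/n) Σ_i MD_i           (over the n fingers presented)

Raw MD is biased upward at small trial counts (for the same reason the SEM
shrinks with n), so it is normalized by its own permutation null:
MD_rand is the mean MD over random shuffles of the trial → finger
assignment (1000 by default, per-finger trial counts preserved), and

    MD_N = MD / MD_rand.

An untuned unit has MD_N ≈ 1 regardless of trial count; MD_N > 2 is the
"modulated unit" criterion.

**Decoding.** Per-trial spike counts of all eligible (rate > 2 Hz) unsorted
multiunits in each trial's trimmed 3 s window are classified with naive
Bayes (independent Poisson likelihood per unit, uniform priors, exposed as
a scikit-learn estimator `PoissonNaiveBayes`) under leave-one-out
cross-validation, plus a cross-condition transfer test (train pre-drug,
decode during drug). Above-chance performance uses the exact one-tailed
binomial test; no normal approximation.

**Spectra.** Thomson multitaper estimation with time–bandwidth product 120
over 30 s windows, 239 DPSS tapers and 15 s steps, after FIR anti-aliased
decimation and a linear-phase FIR high-pass; band power change is reported
as the 20–45 Hz drug/pre ratio.

## Worked example

```python
import spikemod as sm

cfg = sm.RunConfig(
    population=sm.PopulationConfig(
        n_units=15, frac_tuned=0.5, tuning_gain=3.0, tuning_retention_prob=0.5,
        drug_factor_mean=1.3, drug_factor_sd=0.2, onset_tau_min=2.0),
    t_drug_on=300.0, drug_duration_s=900.0,
    brushing_windows={"pre": (20.0, 280.0), "early": (500.0, 800.0),
                      "late": (900.0, 1200.0)},
    n_trials_per_session=28, n_perm=100,
    spectrum_pre_window=(0.0, 120.0), spectrum_drug_offset=(300.0, 420.0),
    seed=5)
sm.run_pipeline(cfg, "out")
print(sm.generate_report("out"))
```

prints (abridged):

```
Condition firing rates (sorted multiunits, mean +/- SEM over units)
  pre : 7.54 +/- 0.89 Hz
  drug: 8.07 +/- 0.95 Hz
  paired t = 1.82, p = 0.0899; fraction of units increasing = 0.60

Band power change (drug / pre)
  20-45 Hz ratio = 2.27 (generator gain 3.00)

Finger decoding (naive Bayes)
 analysis  accuracy     sem  n  chance  p_binomial
  loo_pre         1       0 28    0.25   1.388e-17
 loo_drug      0.75 0.05786 56    0.25    5.99e-15
 transfer    0.6964 0.06144 56    0.25   2.834e-12

Modulation depth (permutation-normalized)
    pre: mean MD_N = 3.346; modulated (MD_N > 2): 9/15
  early: mean MD_N = 1.043; modulated (MD_N > 2): 0/15
   late: mean MD_N = 1.807; modulated (MD_N > 2): 4/15
```

Reading it: the simulated drug raises the population rate (factor ~1.3 was
injected), 20–45 Hz power rises (the ratio is below the injected gain of 3
because the measurement window sits on the onset ramp), decoding degrades
under drug but stays far above the 0.25 chance level, and mean MD_N drops
because half the tuned units lose their tuning — the same qualitative
pattern the analysis is designed to resolve.

The same stages are available from the shell: `spikemod pipeline run
--config run.yaml`, `spikemod decode loo`, `spikemod modulation mdn`,
`spikemod spectral compare`, etc.

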