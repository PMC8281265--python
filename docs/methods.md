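# Methods

This note documents the models, parameters and numerical choices behind
spikemod, and what the synthetic-data tests do and do not establish about
real recordings.

## Session model

A session is a units × 1 ms-bin spike-count raster, a trial log of 5 s
single-finger brushings (four fingers, computer-randomized uniformly), a
timeline with a pre-drug baseline (≥15 min in the emulated protocol), a
drug period (≥45 min) whose effect ramps in over 15–20 min, and one
broadband field-potential channel. All windows are half-open `[start, end)`
in session seconds; 1 ms bin `k` covers `[k, k+1)` ms and an event at time
`t` lands in bin `floor(1000·t)`. Unit sort quality uses the 1–4
convention (1 excluded, 2 sorted multiunit, 3–4 single unit); unsorted
multiunits — all threshold crossings including low-amplitude hash — are a
separate flag and are the population used for decoding and modulation
depth, because hash carries decodable information.

## Synthetic-session generator

Each unit is an inhomogeneous Poisson process on the 1 ms grid with rate

    λ(t) = baseline × drugfactor(t) × fingergain(t).

* **Baselines** are gamma distributed (shape 4, mean 6.4 Hz by default,
  inside the 4.7–8.1 Hz range of session baselines the analyses target), or
  uniform on an interval for calibration runs. Gamma was chosen because
  firing-rate distributions are positive and right-skewed; only means are
  constrained by the emulated data.
* **Drug effect.** Per-unit multiplicative factor drawn from a normal
  (mean 1.3, SD 0.25) conditioned on an increase/decrease indicator with
  P(increase) = 0.8, so the population fraction of rate-increasing units
  matches the emulated observation. The factor ramps in as
  `1 + (f−1)(1 − e^{−(t−t_on)/τ})` with τ = 6 min by default, so the rate
  plateaus at ~20–30 min; the emulated protocol reports the ramp shape only
  qualitatively, and the exponential is the simplest monotone form with a
  single time constant.
* **Tuning.** A tuned unit (default 50% of the population) has one
  preferred finger and a multiplicative gain (default 2) applied during
  brushings of that finger. Under drug, tuning is retained with probability
  `tuning_retention_prob` (default 0.5) — this is the mechanism that
  degrades decodability without necessarily changing rate. A single
  preferred finger with multiplicative gain is the simplest model
  consistent with unimodal single-unit tuning curves; real tuning is
  doubtless graded across fingers.
* **Movement contamination** replaces all units' rates with a high burst
  rate (default 200 Hz) inside short epochs, producing the simultaneous
  multi-channel activity the exclusion rules target.
* **Broadband** is a 1/f-power background (1 Hz knee, unit variance) plus
  Gaussian noise band-limited to 20–45 Hz (SD 2 by default) whose variance
  ramps to `drug_power_gain` times its pre-drug value with the same onset
  ramp. The default 1000 samples/s is a desk-scale stand-in for 30 kHz
  acquisition; the spectral stage accepts any rate. With these defaults the
  in-band background is ~3% of the oscillation power, so the measured
  20–45 Hz power ratio tracks the injected gain to within a few percent.

What the generator does **not** emulate: spike waveforms, refractoriness
and bursting (counts are exactly Poisson), rate nonstationarities other
than the drug ramp, graded multi-finger tuning, electrode crosstalk, and
any pharmacokinetics beyond a single exponential onset. Passing
parameter-recovery tests therefore shows the analysis code is correct and
calibrated under the stated statistical assumptions, not that those
assumptions hold for any particular real recording.

## Preprocessing

* **Spike detection** (for broadband input): 250 Hz zero-phase Butterworth
  high-pass, events at negative crossings of −4.5 × RMS with a 1 ms
  lockout. The lockout mirrors the 1 ms time-stamp quantization of the
  emulated acquisition chain.
* **Unit selection**: strictly > 2 Hz in the reference window for
  multiunit analyses; strictly > 0.5 Hz for sorted-unit spontaneous-rate
  summaries. Selection is computed once on the stated reference window and
  reused in every other window (paired contract).
* **Movement trials**: a trial is flagged when ≥ 30 distinct channels have
  a spike in the same 1 ms bin (channels, not total spikes); experimenter
  flags are preserved.
* **Dense epochs**: population counts in non-overlapping 3 ms bins; any
  bin strictly above the threshold excludes 1 s on each side of the bin
  center. The threshold is empirical by construction (it scales with
  population size and rate), so it is a required parameter;
  `suggest_dense_threshold` offers mean + 6 SD of a clean reference window
  as a default calibrated on the burst model. Whether the original rule
  counted spikes or active channels in the 3 ms bin is ambiguous; spikes
  are counted here, matching the rule's wording, with the channel-count
  variant available through the movement-trial rule.
* **Rates**: per-unit means over unmasked bins only, with the unmasked
  duration reported alongside; the running trend is a centered 5 min
  moving average (the emulated analysis does not state the alignment;
  centered avoids lag at onset), missing (NaN) where a window is fully
  masked. Condition comparison is the paired two-tailed t-test implemented
  as a one-sample test on the per-unit differences — the two are
  algebraically identical, which is how the "one-sample, two-tailed t test"
  phrasing of the emulated protocol is honored.

## Spectral estimation

Thomson multitaper with NW = 120, 30 s windows, 239 = 2·NW − 1 tapers,
15 s step; the half-bandwidth is W = NW/window = 4 Hz, i.e. the estimator
trades resolution for very low variance. The taper-count bound and the
window-carries-tapers condition are validated, never silently truncated.
Decimation uses an order-1000 FIR low-pass and requires an integer factor;
the high-pass is an order-1000 linear-phase FIR with group-delay
compensation. Its cutoff is unstated in the emulated protocol and defaults
to 1 Hz here; note an order-1000 FIR at 1 kHz has a ~3 Hz transition, so
the mean is removed explicitly before filtering to null DC. Movement
periods are deliberately **not** excluded from spectra (removing samples
would create discontinuities); normalizations offered are max-at-0-dB,
division by a reference window's time-average, division by the reference
magnitude at 10 Hz, and multiplication by f (1/f flattening), each tagged
in the result's provenance.

## Decoding

Naive Bayes with one Poisson likelihood per unit on trimmed-window counts.
The class rate estimate is `(Σ counts + 0.5) / n_trials` — half a spike of
additive smoothing so silent units never produce zero likelihoods. Priors
are uniform (the stimulus schedule is uniform); empirical priors and a
Gaussian likelihood (with variance floor) are available for sensitivity
checks. Ties break to the lowest finger and are counted. The trial's
first 2 s are discarded (experimenters switch fingers then), leaving 3 s
analysis windows. Leave-one-out folds may legitimately train on classes
with a single trial (the Poisson mean is estimable from one observation);
a full-session fit requires ≥ 2 trials per finger so a fold never loses a
class. Chance-level behaviour: at uniformly random schedules the session
class counts are unbalanced, which makes individual untuned sessions
decode slightly above or below 1/n_fingers (better-estimated majority
classes attract predictions, while the held-out trial weakens its own
class); the two effects cancel to ≈ 1/n_fingers in expectation, which is
what the calibration test asserts over 100 sessions. The exact binomial
test sums the probability mass function directly.

## Modulation depth

Sample SD (n − 1) is used throughout; the population-SD variant is
exposed (`ddof=0`) since the original convention is unstated. Permutations
shuffle the observed rate values over the fixed label vector — a label
shuffle without replacement, preserving per-finger trial counts exactly.
MD_rand averages the statistic over 1000 permutations by default. The
degenerate case of a zero-variance pair with distinct means is capped at
10⁶ with a warning (the separation is formally infinite); equal means with
zero variance give 0. The normalization is applied to the per-unit total
MD (MD_N = MD/MD_rand); the per-pair subscript that sometimes appears in
print for this definition is treated as typographical. ANOVA screening is
one-way fixed-effects with configurable α (0.05 for modulated-unit counts,
0.1 for display screening); the MD_N-vs-rate-change correlation regresses
MD_N on (drug − pre)/pre, the pre-normalization preventing high-rate units
from dominating, and reports R² with the regression F-test p.

## Pipeline and reproducibility

One master seed deterministically spawns per-stage seeds (SHA-256 of
`"{seed}:{stage}"`, truncated below 2³¹); a run is reproducible
byte-for-byte from its `RunConfig` alone, and the manifest records the
config hash, stage seeds and library versions. Any stage failure aborts
with the stage name; completed outputs are retained.

## Problem sizes

Default desk-scale runs use 15–50 units, 24–80 trials per brushing
session, sessions of 20–75 min at 1 ms resolution, 100–1000 permutations,
and 100 replicate sessions for chance calibration — sizes chosen so the
full suite and the calibration scripts complete in minutes on one core
while keeping Monte-Carlo error well inside every stated tolerance.

## Known limitations

* The Poisson spike model understates the count dispersion of real
  cortical data; MD_N calibration on real (overdispersed) data remains ≈ 1
  only because the permutation null is computed from the same trials, but
  decoding accuracies will differ from the Poisson-optimal ones.
* The naive-Bayes independence assumption ignores noise correlations
  between units.
* The spectral stage assumes an integer decimation factor and does not
  interpolate display artifacts.
* The dense-epoch threshold has no universal default; it must be
  calibrated per dataset.
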