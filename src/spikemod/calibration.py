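"""Null-calibration harnesses for the decoder and the MD_N statistic.

These routines generate untuned (label-free) synthetic data and measure
the two chance-level properties the analysis relies on:

* an untuned population decodes at 1/n_fingers under leave-one-out
  naive Bayes, and
* the permutation-normalized modulation depth MD_N of an untuned unit has
  expectation ~1 regardless of the number of trials per finger, even
  though raw MD inflates as trials get scarcer.
"""

from __future__ import annotations

import numpy as np

from . import decode as dec
from . import modulation as mod
from . import synthetic as syn
from .session import SessionTimeline


def untuned_session_accuracy(
    seed: int,
    n_units: int = 50,
    n_trials: int = 80,
    n_fingers: int = 4,
    rate_lo_hz: float = 5.0,
    rate_hi_hz: float = 10.0,
    trial_s: float = 5.0,
) -> float:
    """LOO naive-Bayes accuracy of one fully untuned synthetic session.

    Units are Poisson with uniform baselines in [rate_lo, rate_hi] Hz, no
    tuning, no drug; fingers are drawn uniformly.  The expected accuracy is
    the chance level 1/n_fingers.
    """
    ss = np.random.SeedSequence(seed)
    s_pop, s_trials, s_raster = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    window_s = n_trials * trial_s / 0.8  # ~20% slack for random gaps
    end = 10.0 + window_s
    timeline = SessionTimeline(
        t_drug_on=end,  # drug never starts during the recorded span
        pre_window=(0.0, end),
        drug_window=(end, end + 1.0),
        brushing_sessions=[("pre", 10.0, end)],
    )
    config = syn.PopulationConfig(
        n_units=n_units,
        baseline_dist="uniform",
        baseline_rate_lo_hz=rate_lo_hz,
        baseline_rate_hi_hz=rate_hi_hz,
        frac_tuned=0.0,
        drug_factor_mean=1.0,
        drug_factor_sd=0.0,
        n_fingers=n_fingers,
    )
    truth = syn.sample_population(config, s_pop)
    trials = syn.schedule_trials(timeline, n_trials, trial_s=trial_s,
                                 n_fingers=n_fingers, seed=s_trials)
    raster = syn.simulate_spike_raster(truth, timeline, trials, seed=s_raster,
                                       duration_s=end)
    feats = dec.trial_feature_matrix(raster, trials, np.arange(n_units))
    return dec.loo_cv_classify(feats).proportion_correct


def decoder_chance_accuracy(n_sessions: int = 100, seed: int = 0, **kwargs) -> float:
    """Mean LOO accuracy over replicate untuned sessions (chance calibration)."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n_sessions)]
    return float(np.mean([untuned_session_accuracy(s, **kwargs) for s in seeds]))


def mdn_null_calibration(
    n_units: int = 500,
    trials_per_finger: int = 20,
    n_perm: int = 200,
    n_fingers: int = 4,
    rate_lo_hz: float = 5.0,
    rate_hi_hz: float = 10.0,
    window_s: float = 3.0,
    seed: int = 0,
) -> tuple[float, float]:
    """(mean raw MD, mean MD_N) over simulated untuned units.

    Each unit's trial rates are Poisson counts over the trimmed analysis
    window at a constant baseline: the finger labels carry no information,
    so MD_N should average ~1 while raw MD depends on the trial count.
    """
    rng = np.random.default_rng(seed)
    fingers = np.repeat(np.arange(1, n_fingers + 1), trials_per_finger)
    mds, mdns = np.empty(n_units), np.empty(n_units)
    for u in range(n_units):
        rate = rng.uniform(rate_lo_hz, rate_hi_hz)
        counts = rng.poisson(rate * window_s, size=len(fingers))
        res = mod.md_normalized(
            counts / window_s,
            fingers,
            n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        mds[u], mdns[u] = res.md, res.md_n
    return float(mds.mean()), float(mdns.mean())
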