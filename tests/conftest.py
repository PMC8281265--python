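"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

import spikemod as sm


@pytest.fixture(scope="session")
def short_timeline() -> sm.SessionTimeline:
    """5 min pre, drug at 300 s, 15 min drug period, three brushing windows."""
    return sm.SessionTimeline(
        t_drug_on=300.0,
        pre_window=(0.0, 300.0),
        drug_window=(300.0, 1200.0),
        brushing_sessions=[("pre", 20.0, 280.0), ("early", 400.0, 700.0), ("late", 800.0, 1100.0)],
    )


@pytest.fixture(scope="session")
def tuned_truth() -> sm.GroundTruth:
    """12 units, half strongly tuned (gain 3), moderate drug effect."""
    cfg = sm.PopulationConfig(
        n_units=12, frac_tuned=0.5, tuning_gain=3.0, tuning_retention_prob=0.5,
        drug_factor_mean=1.3, drug_factor_sd=0.2, onset_tau_min=2.0,
    )
    return sm.sample_population(cfg, seed=101)


@pytest.fixture(scope="session")
def tuned_session(short_timeline, tuned_truth):
    """(raster, trials) for the tuned population on the short timeline."""
    trials = sm.schedule_trials(short_timeline, 24, seed=102)
    raster = sm.simulate_spike_raster(tuned_truth, short_timeline, trials, seed=103)
    return raster, trials


def make_untuned_raster(n_units=8, rate_hz=10.0, duration_s=60.0, seed=0) -> sm.SpikeRaster:
    """Constant-rate Poisson raster with no structure at all."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate_hz / 1000.0, size=(n_units, int(duration_s * 1000)))
    units = [sm.UnitMeta(unit_id=i, channel=i, unsorted=True) for i in range(n_units)]
    return sm.SpikeRaster(counts=counts, units=units)


@pytest.fixture()
def untuned_raster() -> sm.SpikeRaster:
    return make_untuned_raster(seed=7)
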