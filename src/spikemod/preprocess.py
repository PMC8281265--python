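"""Unit selection, artifact exclusion and firing-rate summaries.

This stage turns a raw session into the cleaned material the downstream
analyses consume:

* spike detection from a broadband channel by negative threshold crossing
  of the high-pass-filtered signal at -k x RMS;
* rate-based unit selection (strict > 2 Hz for multiunit analyses, > 0.5 Hz
  for spontaneous-activity summaries);
* movement-trial removal (>= 30 channels spiking in the same 1 ms bin);
* dense-epoch exclusion (population count in a 3 ms bin above threshold
  excludes the surrounding 1 s on each side) for rate computations;
* 5 min running-average rate trends and pre/drug condition summaries with
  the paired t comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .session import BroadbandSignal, SessionTimeline, SpikeRaster, make_trial_log


# ---------------------------------------------------------------------------
# spike detection


def detect_threshold_crossings(
    sig: BroadbandSignal,
    hp_cutoff_hz: float = 250.0,
    k_rms: float = 4.5,
    lockout_ms: float = 1.0,
) -> np.ndarray:
    """Detect spike times as negative-going crossings of -k_rms x RMS.

    The signal is high-pass filtered at ``hp_cutoff_hz`` (zero-phase, 4th
    order Butterworth), the RMS is computed over the whole record, and an
    event is logged whenever the filtered voltage crosses from above to
    below ``-k_rms * RMS``.  A lockout of ``lockout_ms`` after each event
    prevents double counting within one spike; the returned times are in
    seconds.
    """
    if sig.fs <= 2.0 * hp_cutoff_hz:
        raise ValidationError(f"fs={sig.fs} too low for a {hp_cutoff_hz} Hz high-pass")
    x = np.asarray(sig.samples, dtype=float)
    if x.ndim != 1:
        raise ValidationError("spike detection expects a single channel")
    sos = sps.butter(4, hp_cutoff_hz, btype="highpass", fs=sig.fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    rms = float(np.sqrt(np.mean(y**2)))
    if rms == 0.0:
        warnings.warn("flat signal: RMS is zero, no events detected", stacklevel=2)
        return np.array([])
    thr = -k_rms * rms
    below = y < thr
    crossings = np.flatnonzero(~below[:-1] & below[1:]) + 1
    if crossings.size == 0:
        return np.array([])
    lockout = int(round(lockout_ms / 1000.0 * sig.fs))
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= max(lockout, 1):
            kept.append(c)
    return np.asarray(kept) / sig.fs


# ---------------------------------------------------------------------------
# unit selection


def _unit_rates(raster: SpikeRaster, window: tuple[float, float]) -> np.ndarray:
    b0, b1 = raster.bin_of(window[0]), raster.bin_of(window[1])
    if b1 <= b0:
        raise ValidationError(f"empty selection window {window}")
    dur = (b1 - b0) / 1000.0
    return raster.counts[:, b0:b1].sum(axis=1) / dur


def select_units(
    raster: SpikeRaster, window: tuple[float, float], min_rate_hz: float = 2.0
) -> np.ndarray:
    """Indices of units with rate strictly above ``min_rate_hz`` in ``window``.

    The 2 Hz default is the multiunit inclusion rule; the selection is made
    on the stated reference window only (normally the pre-drug baseline) and
    reused unchanged in every other window.
    """
    return np.flatnonzero(_unit_rates(raster, window) > min_rate_hz)


def filter_spontaneous_units(
    raster: SpikeRaster, window: tuple[float, float], min_rate_hz: float = 0.5
) -> np.ndarray:
    """Sorted-unit spontaneous-activity rule: rate strictly > 0.5 Hz."""
    return select_units(raster, window, min_rate_hz=min_rate_hz)


# ---------------------------------------------------------------------------
# movement / artifact exclusion


def flag_movement_trials(
    raster: SpikeRaster, trials: pd.DataFrame, min_channels: int = 30
) -> pd.DataFrame:
    """Flag trials containing a 1 ms bin with >= min_channels active units.

    Counts distinct units with at least one spike in the bin (channels, not
    total spikes).  Experimenter-set flags are preserved (OR-ed with the
    automatic rule).
    """
    trials = make_trial_log(trials)
    active = (raster.counts > 0).sum(axis=0)
    flags = trials["movement_flag"].to_numpy().copy()
    for k, r in enumerate(trials.itertuples()):
        b0 = raster.bin_of(r.start_s)
        b1 = raster.bin_of(r.start_s + r.duration_s)
        if b1 > raster.n_bins:
            raise ValidationError(f"trial {k} extends past the raster")
        if (active[b0:b1] >= min_channels).any():
            flags[k] = True
    out = trials.copy()
    out["movement_flag"] = flags
    return out


@dataclass
class ExclusionMask:
    """Boolean per-1 ms-bin mask (True = excluded) with provenance runs."""

    mask: np.ndarray
    runs: list[tuple[float, float, str]] = field(default_factory=list)

    @property
    def excluded_s(self) -> float:
        return float(self.mask.sum()) / 1000.0

    def __and_len_check__(self, raster: SpikeRaster) -> None:  # pragma: no cover
        if len(self.mask) != raster.n_bins:
            raise ValidationError("mask length does not match raster")


def exclude_dense_epochs(
    raster: SpikeRaster,
    count_threshold: int,
    bin_ms: int = 3,
    pad_s: float = 1.0,
) -> ExclusionMask:
    """Exclude 1 s around any 3 ms bin whose population count exceeds threshold.

    The population spike count is taken in non-overlapping ``bin_ms`` bins;
    a bin strictly exceeding ``count_threshold`` excludes
    ``[center - pad_s, center + pad_s)``.  The threshold is empirical by
    nature (it depends on population size and rate) and therefore a required
    argument; :func:`suggest_dense_threshold` provides a quantile-based
    default.
    """
    if count_threshold <= 0:
        raise ValidationError("count_threshold must be positive")
    pop = raster.counts.sum(axis=0)
    n_coarse = raster.n_bins // bin_ms
    coarse = pop[: n_coarse * bin_ms].reshape(n_coarse, bin_ms).sum(axis=1)
    tail = pop[n_coarse * bin_ms :].sum()
    hot = np.flatnonzero(coarse > count_threshold).tolist()
    if raster.n_bins % bin_ms and tail > count_threshold:
        hot.append(n_coarse)
    mask = np.zeros(raster.n_bins, dtype=bool)
    runs: list[tuple[float, float, str]] = []
    pad = int(round(pad_s * 1000))
    for h in hot:
        center = h * bin_ms + bin_ms // 2
        a, b = max(0, center - pad), min(raster.n_bins, center + pad)
        mask[a:b] = True
        runs.append((a / 1000.0, b / 1000.0, "dense-epoch"))
    return ExclusionMask(mask=mask, runs=runs)


def suggest_dense_threshold(raster: SpikeRaster, window: tuple[float, float], k_sd: float = 6.0) -> int:
    """Mean + k_sd * SD of the population 3 ms count in a clean reference window."""
    b0, b1 = raster.bin_of(window[0]), raster.bin_of(window[1])
    pop = raster.counts[:, b0:b1].sum(axis=0)
    n3 = len(pop) // 3
    coarse = pop[: n3 * 3].reshape(n3, 3).sum(axis=1)
    return int(np.ceil(coarse.mean() + k_sd * coarse.std()))


def trim_trial_window(trial, discard_s: float = 2.0) -> tuple[float, float]:
    """Analysis window of one trial: drop the first ``discard_s`` seconds.

    The first 2 s of each 5 s brushing are contaminated by the experimenter
    switching fingers, leaving a 3 s analysis window.
    """
    start = float(trial["start_s"] if isinstance(trial, (dict, pd.Series)) else trial.start_s)
    dur = float(trial["duration_s"] if isinstance(trial, (dict, pd.Series)) else trial.duration_s)
    if dur <= discard_s:
        raise ValidationError(f"trial duration {dur} s leaves no analysis window")
    return (start + discard_s, start + dur)


# ---------------------------------------------------------------------------
# rate summaries


def running_rate_trend(
    raster: SpikeRaster,
    mask: ExclusionMask | None = None,
    window_min: float = 5.0,
    step_s: float = 10.0,
    normalize_window: tuple[float, float] | None = None,
    unit_idx: np.ndarray | None = None,
) -> pd.DataFrame:
    """Population-mean firing rate as a centered running average.

    The rate at time t averages unmasked 1 ms bins in
    ``[t - window/2, t + window/2)`` across the selected units.  Fully
    masked windows yield NaN (missing, never zero).  With
    ``normalize_window`` the trend is divided by the trend's mean rate over
    that window (baseline-normalised trend).
    """
    counts = raster.counts if unit_idx is None else raster.counts[unit_idx]
    n_units = counts.shape[0]
    pop = counts.sum(axis=0).astype(float)
    keep = np.ones(raster.n_bins) if mask is None else (~mask.mask).astype(float)
    pop = pop * keep
    half = int(round(window_min * 60.0 * 1000 / 2))
    cs_pop = np.concatenate([[0.0], np.cumsum(pop)])
    cs_keep = np.concatenate([[0.0], np.cumsum(keep)])
    centers = np.arange(half, raster.n_bins - half + 1, int(round(step_s * 1000)))
    rates = np.full(len(centers), np.nan)
    for k, c in enumerate(centers):
        a, b = c - half, c + half
        good = cs_keep[b] - cs_keep[a]
        if good > 0:
            rates[k] = (cs_pop[b] - cs_pop[a]) / (good / 1000.0) / n_units
    out = pd.DataFrame({"time_s": centers / 1000.0, "rate_hz": rates})
    if normalize_window is not None:
        w0, w1 = normalize_window
        sel = (out["time_s"] >= w0) & (out["time_s"] < w1)
        ref = out.loc[sel, "rate_hz"].mean()
        if not np.isfinite(ref) or ref == 0:
            raise DegenerateDataError("baseline window has no valid rate to normalise by")
        out["rate_norm"] = out["rate_hz"] / ref
    return out


@dataclass
class RateSummary:
    """Per-unit mean rates for one condition window plus the population summary."""

    condition: str
    unit_rates_hz: np.ndarray
    mean_hz: float
    sem_hz: float
    unmasked_s: float

    @classmethod
    def from_rates(cls, condition: str, rates: np.ndarray, unmasked_s: float) -> "RateSummary":
        rates = np.asarray(rates, dtype=float)
        sem = float(rates.std(ddof=1) / np.sqrt(len(rates))) if len(rates) > 1 else 0.0
        return cls(condition, rates, float(rates.mean()), sem, unmasked_s)


def _masked_window_rates(
    raster: SpikeRaster,
    mask: ExclusionMask | None,
    window: tuple[float, float],
    unit_idx: np.ndarray,
) -> tuple[np.ndarray, float]:
    b0, b1 = raster.bin_of(window[0]), raster.bin_of(window[1])
    keep = np.ones(b1 - b0, dtype=bool) if mask is None else ~mask.mask[b0:b1]
    dur = keep.sum() / 1000.0
    if dur <= 0:
        raise DegenerateDataError(f"window {window} is fully masked")
    rates = raster.counts[np.ix_(unit_idx, np.arange(b0, b1)[keep])].sum(axis=1) / dur
    return rates, dur


def condition_rate_summary(
    raster: SpikeRaster,
    mask: ExclusionMask | None,
    timeline: SessionTimeline,
    unit_idx: np.ndarray | None = None,
) -> tuple[RateSummary, RateSummary]:
    """Mean +/- SEM rate in the pre-drug and drug windows over the same units.

    Per-unit rates use unmasked time only; the SEM is across units.  The
    paired contract: the identical unit set is used in both conditions.
    """
    if unit_idx is None:
        unit_idx = np.arange(raster.n_units)
    unit_idx = np.asarray(unit_idx)
    if unit_idx.size == 0:
        raise DegenerateDataError("no eligible units")
    pre_rates, pre_dur = _masked_window_rates(raster, mask, timeline.pre_window, unit_idx)
    drug_rates, drug_dur = _masked_window_rates(raster, mask, timeline.drug_window, unit_idx)
    return (
        RateSummary.from_rates("pre", pre_rates, pre_dur),
        RateSummary.from_rates("drug", drug_rates, drug_dur),
    )


def compare_condition_rates(pre_rates: np.ndarray, drug_rates: np.ndarray) -> tuple[float, float]:
    """Paired two-tailed t-test on per-unit (pre, drug) rate pairs.

    Implemented as the one-sample t-test on the paired differences, which is
    algebraically the paired t-test.  Zero variance of the differences is a
    degenerate input.
    """
    pre_rates = np.asarray(pre_rates, dtype=float)
    drug_rates = np.asarray(drug_rates, dtype=float)
    if pre_rates.shape != drug_rates.shape or pre_rates.ndim != 1:
        raise ValidationError("pre and drug rate vectors must be paired 1-D arrays")
    if len(pre_rates) < 2:
        raise ValidationError("need at least two paired units")
    diff = drug_rates - pre_rates
    if np.allclose(diff.std(ddof=1), 0.0):
        raise DegenerateDataError("zero variance of paired differences")
    t, p = stats.ttest_rel(drug_rates, pre_rates)
    return float(t), float(p)


def rate_change_histogram(
    pre_rates: np.ndarray,
    drug_rates: np.ndarray,
    change_bins: np.ndarray | int = 20,
    rate_bins: np.ndarray | int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of (drug - pre rate change) x (pre rate) over units."""
    pre_rates = np.asarray(pre_rates, dtype=float)
    drug_rates = np.asarray(drug_rates, dtype=float)
    if pre_rates.shape != drug_rates.shape:
        raise ValidationError("paired vectors required")
    h, xe, ye = np.histogram2d(drug_rates - pre_rates, pre_rates, bins=[change_bins, rate_bins])
    return h, xe, ye
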