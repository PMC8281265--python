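"""Permutation-normalized modulation depth and tuning statistics.

A unit's modulation depth between fingers i and j is the d'-like separation

    MD_ij = |mu_i - mu_j| / sqrt(sigma_i^2 + sigma_j^2)

where mu_i, sigma_i are the mean and SD of the unit's trial firing rates
when finger i is brushed.  Because finger i must be distinguished from the
*most confusable* alternative, MD_i = min over j != i of MD_ij, and the
unit's total modulation depth MD is the average of MD_i over the fingers
presented.

Raw MD is biased upward for small trial counts (for the same reason the
SEM shrinks with n), and it depends on overall rate variability, so it is
normalized by its own permutation expectation: MD_rand is the mean MD over
random shuffles of the trial -> finger assignment (per-finger trial counts
preserved), and MD_N = MD / MD_rand.  For an untuned unit MD_N is ~1
regardless of trial count; MD_N > 2 is the "modulated unit" criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError

# MD_ij cap used when both group SDs are exactly zero but the means differ
DEFAULT_ZERO_VAR_CAP = 1e6


# ---------------------------------------------------------------------------
# core statistic

FingerRateSample = dict[int, np.ndarray]
"""Per-finger trial firing rates (Hz); keys are 1-based finger labels."""


def sample_from_trials(rates: np.ndarray, fingers: np.ndarray) -> FingerRateSample:
    """Group a per-trial rate vector by finger label."""
    rates = np.asarray(rates, dtype=float)
    fingers = np.asarray(fingers)
    return {int(f): rates[fingers == f] for f in np.unique(fingers)}


def md_pair(mu_i: float, sd_i: float, mu_j: float, sd_j: float,
            zero_var_cap: float = DEFAULT_ZERO_VAR_CAP) -> float:
    """Pairwise modulation depth |mu_i - mu_j| / sqrt(sd_i^2 + sd_j^2).

    Symmetric and non-negative.  The degenerate case of two zero-variance
    groups is resolved by policy: equal means give 0; different means give
    ``zero_var_cap`` with a warning (the separation is formally infinite).
    """
    num = abs(mu_i - mu_j)
    denom = np.sqrt(sd_i**2 + sd_j**2)
    if denom == 0.0:
        if num == 0.0:
            return 0.0
        warnings.warn("zero-variance pair with distinct means; MD capped", stacklevel=2)
        return zero_var_cap
    return float(num / denom)


def _md_from_moments(
    means: np.ndarray, variances: np.ndarray, zero_var_cap: float = DEFAULT_ZERO_VAR_CAP
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized MD over the trailing finger axis.

    ``means``/``variances`` have shape (..., F).  Returns (MD_i with shape
    (..., F), MD with shape (...,)).
    """
    num = np.abs(means[..., :, None] - means[..., None, :])
    denom = np.sqrt(variances[..., :, None] + variances[..., None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        md_ij = num / denom
    md_ij = np.where(denom == 0.0, np.where(num == 0.0, 0.0, zero_var_cap), md_ij)
    f = means.shape[-1]
    eye = np.eye(f, dtype=bool)
    md_ij = np.where(eye, np.inf, md_ij)  # exclude j == i from the minimum
    md_i = md_ij.min(axis=-1)
    return md_i, md_i.mean(axis=-1)


def md_unit(
    sample: FingerRateSample, ddof: int = 1, zero_var_cap: float = DEFAULT_ZERO_VAR_CAP
) -> tuple[dict[int, float], float]:
    """MD_i per finger (minimum over comparison fingers) and the total MD.

    Uses the sample SD (``ddof=1``) by default; ``ddof=0`` gives the
    population convention.
    """
    fingers = sorted(sample)
    if len(fingers) < 2:
        raise ValidationError("modulation depth needs at least two fingers")
    for f in fingers:
        if len(sample[f]) < 2:
            raise DegenerateDataError(f"finger {f} has fewer than 2 trials")
    means = np.array([np.mean(sample[f]) for f in fingers])
    variances = np.array([np.var(sample[f], ddof=ddof) for f in fingers])
    md_i, md = _md_from_moments(means, variances, zero_var_cap)
    return dict(zip(fingers, md_i.tolist())), float(md)


@dataclass
class ModulationResult:
    """Per-unit modulation depth with its permutation normalization."""

    md_i: dict[int, float]
    md: float
    md_rand: float
    md_n: float
    n_perm: int
    seed: int | None = None
    session_label: str = ""
    unit_id: int | None = None

    def __post_init__(self) -> None:
        if self.md < 0 or self.md_rand <= 0 or self.md_n < 0:
            raise ValidationError("MD must be >= 0 and MD_rand > 0")


def md_normalized(
    rates: np.ndarray,
    fingers: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    ddof: int = 1,
    zero_var_cap: float = DEFAULT_ZERO_VAR_CAP,
    force_identity: bool = False,
    session_label: str = "",
    unit_id: int | None = None,
) -> ModulationResult:
    """Permutation-normalized modulation depth of one unit.

    ``rates`` are the unit's per-trial firing rates and ``fingers`` the
    trial labels.  MD_rand averages the MD statistic over ``n_perm`` random
    shuffles of the trial -> finger assignment; the shuffle permutes the
    observed rate values over the fixed label vector, so per-finger trial
    counts are preserved exactly.  ``force_identity`` replaces every
    permutation with the identity (then MD_N == 1 by construction), which
    is useful for self-normalization checks.
    """
    rates = np.asarray(rates, dtype=float)
    fingers = np.asarray(fingers)
    labels = np.unique(fingers)
    n_fingers = len(labels)
    if len(rates) != len(fingers):
        raise ValidationError("one finger label per trial rate required")
    if len(rates) < 2 * n_fingers:
        raise DegenerateDataError(
            f"{len(rates)} trials cannot give 2 per finger over {n_fingers} fingers"
        )
    md_i, md = md_unit(sample_from_trials(rates, fingers), ddof=ddof, zero_var_cap=zero_var_cap)

    onehot = (fingers[:, None] == labels[None, :]).astype(float)
    n_per = onehot.sum(axis=0)
    rng = np.random.default_rng(seed)
    if force_identity:
        perm_rates = np.broadcast_to(rates, (n_perm, len(rates)))
    else:
        perm_rates = np.stack([rng.permutation(rates) for _ in range(n_perm)])
    means = perm_rates @ onehot / n_per
    ex2 = (perm_rates**2) @ onehot / n_per
    variances = np.clip(ex2 - means**2, 0.0, None)
    if ddof == 1:
        variances *= n_per / (n_per - 1)
    _, md_perm = _md_from_moments(means, variances, zero_var_cap)
    md_rand = float(md_perm.mean())
    if md_rand == 0.0:
        raise DegenerateDataError("MD_rand is zero; normalization undefined")
    return ModulationResult(
        md_i=md_i,
        md=md,
        md_rand=md_rand,
        md_n=md / md_rand,
        n_perm=n_perm,
        seed=seed,
        session_label=session_label,
        unit_id=unit_id,
    )


def md_session(
    features,
    n_perm: int = 1000,
    seed: int | None = None,
    session_label: str = "",
    **kwargs,
) -> list[ModulationResult]:
    """MD_N for every unit of a trial feature matrix (one seed per unit)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(features.X.shape[1])
    out = []
    for u in range(features.X.shape[1]):
        rates = features.X[:, u] / features.window_s
        out.append(
            md_normalized(
                rates,
                features.fingers,
                n_perm=n_perm,
                seed=children[u],
                session_label=session_label,
                unit_id=int(features.unit_ids[u]),
                **kwargs,
            )
        )
    return out


def count_modulated(results: list[ModulationResult] | np.ndarray, threshold: float = 2.0) -> int:
    """Number of units with MD_N strictly above ``threshold``."""
    vals = np.asarray([r.md_n if isinstance(r, ModulationResult) else r for r in results])
    return int((vals > threshold).sum())


# ---------------------------------------------------------------------------
# tuning curves and screening


def tuning_curve(sample: FingerRateSample) -> pd.DataFrame:
    """Per-finger mean, SEM and trial count of a unit's firing rate."""
    rows = []
    for f in sorted(sample):
        r = np.asarray(sample[f], dtype=float)
        if len(r) == 0:
            raise ValidationError(f"finger {f} has no trials")
        if len(r) == 1:
            warnings.warn(f"finger {f}: single trial, SEM reported as 0", stacklevel=2)
            sem = 0.0
        else:
            sem = float(r.std(ddof=1) / np.sqrt(len(r)))
        rows.append({"finger": f, "mean_hz": float(r.mean()), "sem_hz": sem, "n": len(r)})
    return pd.DataFrame(rows)


def anova_screen(sample: FingerRateSample, alpha: float = 0.05) -> tuple[float, float, bool]:
    """One-way fixed-effects ANOVA across finger groups.

    Returns (F, p, modulated flag with flag = p < alpha).  alpha = 0.05 is
    the modulated-unit count criterion; 0.1 the laxer display screening.
    """
    groups = [np.asarray(sample[f], dtype=float) for f in sorted(sample)]
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two fingers")
    for g in groups:
        if len(g) < 2:
            raise DegenerateDataError("every finger needs at least 2 trials")
    if all(np.var(g) == 0.0 for g in groups):
        raise DegenerateDataError("zero within-group variance everywhere; F undefined")
    f_stat, p = stats.f_oneway(*groups)
    return float(f_stat), float(p), bool(p < alpha)


def md_rate_correlation(
    md_n: np.ndarray, pre_rates: np.ndarray, drug_rates: np.ndarray
) -> tuple[float, float]:
    """OLS of MD_N on the normalized rate change (drug - pre) / pre.

    The change is normalized by the pre-drug rate so high-rate units do not
    dominate.  Units with non-positive pre-drug rate are excluded with a
    warning.  Returns (R^2, p) where p is the regression F-test p-value
    (identical to the slope t-test for a single predictor).
    """
    md_n = np.asarray(md_n, dtype=float)
    pre_rates = np.asarray(pre_rates, dtype=float)
    drug_rates = np.asarray(drug_rates, dtype=float)
    if not (md_n.shape == pre_rates.shape == drug_rates.shape):
        raise ValidationError("md_n, pre_rates and drug_rates must be paired")
    ok = pre_rates > 0
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} unit(s) with zero pre-drug rate", stacklevel=2)
    if ok.sum() < 3:
        raise DegenerateDataError("need at least 3 units with positive pre-drug rate")
    x = (drug_rates[ok] - pre_rates[ok]) / pre_rates[ok]
    if np.allclose(x, x[0]):
        raise DegenerateDataError("constant predictor; slope undefined")
    res = stats.linregress(x, md_n[ok])
    return float(res.rvalue**2), float(res.pvalue)


def fisher_modulated_counts(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact p for a 2x2 modulated/not x condition table."""
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n:
            raise ValidationError(f"invalid table cell k={k}, n={n}")
    _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
    return float(p)
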