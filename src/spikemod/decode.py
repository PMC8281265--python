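"""Naive-Bayes finger decoding with leave-one-out cross-validation.

Features are per-trial spike counts of the eligible (rate > 2 Hz) unsorted
multiunits in each trial's trimmed 3 s window.  The classifier is naive
Bayes with an independent Poisson likelihood per unit (counts are the
natural sufficient statistic of a Poisson spike model; a Gaussian family is
available for sensitivity checks) and uniform class priors, because the
stimulus schedule draws fingers uniformly at random.  Above-chance
performance is assessed with the exact one-tailed binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import DegenerateDataError, ValidationError
from .preprocess import trim_trial_window
from .session import SpikeRaster, make_trial_log


@dataclass
class TrialFeatureMatrix:
    """Trials x units spike-count matrix with finger and session labels."""

    X: np.ndarray
    fingers: np.ndarray
    session_labels: np.ndarray
    unit_ids: np.ndarray
    window_s: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise ValidationError("X must be trials x units")
        if np.any(self.X < 0):
            raise ValidationError("spike counts must be non-negative")
        if len(self.fingers) != self.X.shape[0]:
            raise ValidationError("one finger label per trial required")
        if len(self.unit_ids) != self.X.shape[1]:
            raise ValidationError("one unit id per column required")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    def subset_fingers(self, fingers: list[int]) -> "TrialFeatureMatrix":
        """Restrict to trials of the listed fingers (visualization subsets)."""
        sel = np.isin(self.fingers, fingers)
        return TrialFeatureMatrix(
            self.X[sel], self.fingers[sel], self.session_labels[sel], self.unit_ids, self.window_s
        )

    def subset_session(self, labels: str | list[str]) -> "TrialFeatureMatrix":
        labels = [labels] if isinstance(labels, str) else labels
        sel = np.isin(self.session_labels, labels)
        return TrialFeatureMatrix(
            self.X[sel], self.fingers[sel], self.session_labels[sel], self.unit_ids, self.window_s
        )


def trial_feature_matrix(
    raster: SpikeRaster,
    trials: pd.DataFrame,
    unit_idx: np.ndarray,
    discard_s: float = 2.0,
) -> TrialFeatureMatrix:
    """Spike counts per retained trial in the trimmed analysis window.

    Movement-flagged trials are dropped.  No ANOVA prescreening is applied:
    weakly informative units are deliberately kept.
    """
    trials = make_trial_log(trials)
    unit_idx = np.asarray(unit_idx)
    if unit_idx.size == 0:
        raise ValidationError("empty unit set")
    kept = trials[~trials["movement_flag"]]
    if len(kept) == 0:
        raise ValidationError("no trials left after movement exclusion")
    rows, fingers, labels = [], [], []
    win = None
    for r in kept.itertuples():
        a, b = trim_trial_window(r, discard_s=discard_s)
        b0, b1 = raster.bin_of(a), raster.bin_of(b)
        if b1 > raster.n_bins:
            raise ValidationError("trial window extends past the raster")
        rows.append(raster.counts[unit_idx, b0:b1].sum(axis=1))
        fingers.append(r.finger)
        labels.append(r.session_label)
        win = (b1 - b0) / 1000.0
    return TrialFeatureMatrix(
        X=np.asarray(rows),
        fingers=np.asarray(fingers),
        session_labels=np.asarray(labels),
        unit_ids=np.asarray([raster.units[i].unit_id for i in unit_idx]),
        window_s=win,
    )


class PoissonNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes on spike counts with per-unit Poisson likelihoods.

    Parameters
    ----------
    pseudocount : float
        Additive smoothing: the class rate for a unit is
        ``(sum of counts + pseudocount) / n_trials``, guaranteeing nonzero
        likelihoods for silent units.
    priors : {"uniform", "empirical"}
        Class priors.  Uniform matches a uniformly randomised stimulus
        schedule and is the default.
    family : {"poisson", "gaussian"}
        Per-unit likelihood family.  Gaussian (with a variance floor) is a
        sensitivity-check alternative.

    Ties in the posterior are broken toward the lowest class label, which
    is deterministic and logged in ``tie_count_``.
    """

    def __init__(self, pseudocount: float = 0.5, priors: str = "uniform", family: str = "poisson"):
        self.pseudocount = pseudocount
        self.priors = priors
        self.family = family

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValidationError("X must be trials x units with one label per trial")
        if self.priors not in ("uniform", "empirical"):
            raise ValidationError(f"unknown priors {self.priors!r}")
        if self.family not in ("poisson", "gaussian"):
            raise ValidationError(f"unknown family {self.family!r}")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise DegenerateDataError("need at least two classes to fit")
        counts = np.array([(y == c).sum() for c in self.classes_])
        # Poisson rates are estimable from one trial; Gaussian needs a variance
        min_trials = 1 if self.family == "poisson" else 2
        if (counts < min_trials).any():
            bad = self.classes_[counts < min_trials]
            raise DegenerateDataError(
                f"classes {bad.tolist()} have fewer than {min_trials} trials"
            )
        self.class_count_ = counts
        if self.family == "poisson":
            self.rate_ = np.stack(
                [(X[y == c].sum(axis=0) + self.pseudocount) / (y == c).sum() for c in self.classes_]
            )
        else:
            self.theta_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
            var = np.stack([X[y == c].var(axis=0, ddof=1) for c in self.classes_])
            floor = max(1e-9, 1e-3 * float(var.mean())) if var.mean() > 0 else 1e-9
            self.var_ = np.maximum(var, floor)
        if self.priors == "uniform":
            self.class_log_prior_ = np.full(len(self.classes_), -np.log(len(self.classes_)))
        else:
            self.class_log_prior_ = np.log(counts / counts.sum())
        self.tie_count_ = 0
        return self

    def _joint_log_likelihood(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.family == "poisson":
            # sum_u [ x log(lambda) - lambda ]; the log(x!) term is class-free
            jll = X @ np.log(self.rate_).T - self.rate_.sum(axis=1)
        else:
            jll = np.stack(
                [
                    -0.5 * (np.log(2 * np.pi * v) + (X - m) ** 2 / v).sum(axis=1)
                    for m, v in zip(self.theta_, self.var_)
                ],
                axis=1,
            )
        return jll + self.class_log_prior_

    def predict_log_proba(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        return jll - special.logsumexp(jll, axis=1, keepdims=True)

    def predict_proba(self, X) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        best = np.argmax(jll, axis=1)  # argmax takes the first (lowest-label) maximum
        ties = (jll == jll[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
        self.tie_count_ = int(ties.sum())
        return self.classes_[best]


def nb_fit(features: TrialFeatureMatrix, **kwargs) -> PoissonNaiveBayes:
    """Fit the naive-Bayes decoder on all trials of a feature matrix.

    A full-session fit requires every finger to have at least 2 trials (so
    a leave-one-out fold never loses a class outright); individual LOO
    folds may legitimately train on 1-trial classes via the estimator
    directly.
    """
    fingers, counts = np.unique(features.fingers, return_counts=True)
    if (counts < 2).any():
        raise DegenerateDataError(
            f"fingers {fingers[counts < 2].tolist()} have fewer than 2 trials"
        )
    return PoissonNaiveBayes(**kwargs).fit(features.X, features.fingers)


@dataclass
class ClassificationResult:
    """Confusion matrix and summary statistics of one decoding run."""

    confusion: pd.DataFrame  # rows true finger, columns decoded finger
    n_trials: int
    proportion_correct: float
    sem: float
    chance: float
    binomial_p: float
    mode: str

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray, chance: float, mode: str
    ) -> "ClassificationResult":
        labels = np.unique(np.concatenate([y_true, y_pred]))
        conf = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
        for t, p in zip(y_true, y_pred):
            conf.loc[t, p] += 1
        n = len(y_true)
        k = int((y_true == y_pred).sum())
        phat = k / n
        return cls(
            confusion=conf,
            n_trials=n,
            proportion_correct=phat,
            sem=float(np.sqrt(phat * (1 - phat) / n)),
            chance=chance,
            binomial_p=binomial_above_chance(k, n, chance),
            mode=mode,
        )


def loo_cv_classify(features: TrialFeatureMatrix, **kwargs) -> ClassificationResult:
    """Leave-one-out cross-validated decoding of the finger labels.

    Each trial is decoded by a model fit on all remaining trials.  The run
    is fully deterministic: folds are the trials in order and posterior
    ties break toward the lowest finger.
    """
    X, y = features.X, features.fingers
    n = len(y)
    preds = np.empty(n, dtype=y.dtype)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        try:
            model = PoissonNaiveBayes(**kwargs).fit(X[train], y[train])
        except DegenerateDataError as exc:
            raise DegenerateDataError(f"LOO fold {i}: {exc}") from exc
        preds[i] = model.predict(X[i : i + 1])[0]
    chance = 1.0 / len(np.unique(y))
    return ClassificationResult.from_predictions(y, preds, chance, mode="loo-within")


def cross_condition_classify(
    train: TrialFeatureMatrix, test: TrialFeatureMatrix, **kwargs
) -> ClassificationResult:
    """Fit once on ``train`` and decode ``test`` (no leakage).

    Used for the transfer analysis: a decoder trained on pre-drug trials
    classifying drug-period trials.  Unit sets must match exactly.
    """
    if not np.array_equal(train.unit_ids, test.unit_ids):
        raise ValidationError("train and test feature matrices use different unit sets")
    model = PoissonNaiveBayes(**kwargs).fit(train.X, train.fingers)
    preds = model.predict(test.X)
    chance = 1.0 / len(np.unique(train.fingers))
    return ClassificationResult.from_predictions(
        test.fingers, preds, chance, mode="train-pre-test-drug"
    )


def binomial_above_chance(k_correct: int, n_trials: int, chance: float) -> float:
    """Exact one-tailed binomial p-value P(X >= k) under Binomial(n, chance).

    Computed by direct summation of the probability mass function — no
    normal approximation at any n.
    """
    if not 0 <= k_correct <= n_trials:
        raise ValidationError(f"k={k_correct} outside [0, {n_trials}]")
    if not 0.0 < chance < 1.0:
        raise ValidationError(f"chance must be in (0, 1), got {chance}")
    ks = np.arange(k_correct, n_trials + 1)
    return float(np.minimum(stats.binom.pmf(ks, n_trials, chance).sum(), 1.0))


def bonferroni_adjust(alpha: float, m: int) -> float:
    """Per-comparison significance level alpha / m."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha / m
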