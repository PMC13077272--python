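"""Concordance, accuracy, cross-validated splits, and bootstrap comparison.

Conventions. A pair of patients is comparable iff the earlier observed time
carries an event (so censored-before-event pairs and tied times are not
comparable; pairs tied on time where both are events are likewise excluded).
Tied predicted risks on a comparable pair count one half. These are the
standard Harrell conventions.

The model-comparison procedure resamples the test set with replacement,
recomputes every model's C-index on each resample, and tests each model pair
with a paired statistic on the resampled values. Because the resampled
C-indexes of two models are computed on the *same* resamples, their paired
differences are correlated through the shared sample: the spread of the
bootstrap differences estimates the sampling standard deviation of the
observed difference itself, so the test statistic is
``mean(d*) / sd(d*)`` (not divided by ``sqrt(B)``), referred to a t
distribution with ``B - 1`` degrees of freedom. Bonferroni correction
multiplies each p-value by the number of model pairs; 95% confidence
intervals are bootstrap percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "EvalResult",
    "c_index",
    "accuracy",
    "split_folds",
    "split_and_cv",
    "bootstrap_compare",
]


@dataclass
class EvalResult:
    c_index: float
    accuracy: float | None = None
    per_fold: list = field(default_factory=list)
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self):
        if self.ci_low is not None and not (
                self.ci_low <= self.c_index <= self.ci_high):
            raise ValueError("point estimate outside its confidence interval")


def c_index(times: np.ndarray, events: np.ndarray, risks: np.ndarray,
            _block: int = 512) -> float:
    """Concordance index for right-censored data.

    Fraction of comparable pairs whose predicted risk ordering matches the
    observed survival ordering; tied risks count 0.5. Raises if no pair is
    comparable (e.g. an all-censored cohort).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risks = np.asarray(risks, dtype=float)
    if not (len(times) == len(events) == len(risks)):
        raise ValueError("times, events and risks must have equal length")
    n = len(times)
    concordant = 0.0
    comparable = 0
    # blockwise O(n^2) with vectorised inner comparisons
    for start in range(0, n, _block):
        sl = slice(start, min(start + _block, n))
        ti, ei, ri = times[sl, None], events[sl, None], risks[sl, None]
        comp = (ti < times[None, :]) & (ei == 1)
        comparable += int(comp.sum())
        concordant += float(((ri > risks[None, :]) & comp).sum())
        concordant += 0.5 * float(((ri == risks[None, :]) & comp).sum())
    if comparable == 0:
        raise ValueError("no comparable pairs (all censored or all tied)")
    return concordant / comparable


def accuracy(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Fraction of exact matches between binary labels and predictions."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have the same shape")
    return float(np.mean(labels == predictions))


def split_folds(events: np.ndarray, seed: int, n_folds: int = 5,
                val_fraction: float = 0.25
                ) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Five seeded 60/20/20 train/validation/test splits, stratified by event.

    The five test sets are the disjoint parts of a stratified 5-fold
    partition (20% each); the remaining 80% of each fold is split 75/25 into
    train (60%) and validation (20%), again stratified by the event
    indicator.
    """
    events = np.asarray(events, dtype=int)
    if min(np.bincount(events, minlength=2)) < n_folds:
        raise ValueError("too few events (or censorings) for stratified folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    idx = np.arange(len(events))
    for k, (rest, test) in enumerate(skf.split(idx, events)):
        train, val = train_test_split(
            rest, test_size=val_fraction, stratify=events[rest],
            random_state=seed + k)
        folds.append((np.sort(train), np.sort(val), np.sort(test)))
    return folds


def split_and_cv(times: np.ndarray, events: np.ndarray, fit_predict,
                 seed: int = 0, n_folds: int = 5) -> tuple[list, EvalResult]:
    """Run 5-fold cross-validation of a survival learner.

    ``fit_predict(train_idx, val_idx, test_idx) -> risks over test_idx``.
    Returns the folds and the aggregated result (mean C-index with the
    per-fold values attached).
    """
    folds = split_folds(events, seed, n_folds=n_folds)
    per_fold = []
    for train, val, test in folds:
        risks = fit_predict(train, val, test)
        per_fold.append(c_index(times[test], events[test], risks))
    result = EvalResult(c_index=float(np.mean(per_fold)), per_fold=per_fold)
    return folds, result


def bootstrap_compare(times: np.ndarray, events: np.ndarray,
                      risks_by_model: dict, n_boot: int = 1000,
                      seed: int = 0, max_redraws: int = 100) -> dict:
    """Paired bootstrap comparison of models scored on the same test set.

    For each of ``n_boot`` resamples of the test patients, every model's
    C-index is recomputed; each model pair is tested with the paired
    statistic described in the module docstring, Bonferroni-corrected over
    pairs. Degenerate resamples without comparable pairs are redrawn (and
    counted). Returns ``{"p_adjusted": {(a, b): p}, "ci": {model: (lo, hi)},
    "c_index": {model: point estimate}, "distributions": {...},
    "redraws": int}``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    names = list(risks_by_model)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    rng = np.random.default_rng(seed)
    n = len(times)
    boot = {m: np.empty(n_boot) for m in names}
    redraws = 0
    for b in range(n_boot):
        for _ in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            try:
                vals = {m: c_index(times[idx], events[idx],
                                   np.asarray(risks_by_model[m])[idx])
                        for m in names}
                break
            except ValueError:
                redraws += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap sample")
        for m in names:
            boot[m][b] = vals[m]
    if redraws:
        warnings.warn(f"{redraws} degenerate bootstrap resample(s) redrawn",
                      stacklevel=2)

    pairs = list(combinations(names, 2))
    p_adj = {}
    for a, b in pairs:
        d = boot[a] - boot[b]
        sd = d.std(ddof=1)
        if sd == 0.0:
            p = 1.0
        else:
            t = d.mean() / sd
            p = 2.0 * sps.t.sf(abs(t), df=n_boot - 1)
        p_adj[(a, b)] = min(1.0, p * len(pairs))

    ci = {m: (float(np.percentile(boot[m], 2.5)),
              float(np.percentile(boot[m], 97.5))) for m in names}
    point = {m: c_index(times, events, np.asarray(risks_by_model[m]))
             for m in names}
    return {"p_adjusted": p_adj, "ci": ci, "c_index": point,
            "distributions": boot, "redraws": redraws}
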