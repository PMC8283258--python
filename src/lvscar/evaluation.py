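"""Reported metrics: accuracy, sensitivity/specificity, ROC/AUC, bootstrap
confidence intervals, Fleiss' kappa, and apex/mid/base region roll-up.

Accuracy is the pooled fraction of correct out-of-fold predictions.  ROC
curves come from a threshold sweep over the predicted probabilities
(scikit-learn), AUC by the trapezoidal rule.  Confidence intervals use the
percentile bootstrap over resampled (probability, label) pairs; a +/- 1 SD
band is available as an alternative.  Fleiss' kappa quantifies
chance-corrected agreement between multiple binary raters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve
from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa as _sm_fleiss

__all__ = [
    "EvalReport",
    "accuracy",
    "sensitivity_specificity",
    "roc_auc",
    "bootstrap_ci",
    "fleiss_kappa",
    "region_rollup",
    "evaluate",
]


@dataclass
class EvalReport:
    """The acceptance surface of any classification run."""

    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    ci_low: float
    ci_high: float
    n_samples: int
    n_positive: int
    roc_points: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Slice classification report",
            "---------------------------",
            f"samples            {self.n_samples:>8d}",
            f"positive (scar)    {self.n_positive:>8d}",
            f"accuracy           {self.accuracy:>8.3f}",
            f"AUC                {self.auc:>8.3f}  (95% CI {self.ci_low:.3f}-{self.ci_high:.3f})",
            f"sensitivity        {self.sensitivity:>8.3f}",
            f"specificity        {self.specificity:>8.3f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_samples": self.n_samples,
            "n_positive": self.n_positive,
        }


def accuracy(calls, labels) -> float:
    """Correct predictions over total predictions."""
    calls = np.asarray(calls)
    labels = np.asarray(labels)
    if calls.shape != labels.shape or len(calls) == 0:
        raise ValueError("calls and labels must be equal-length and non-empty")
    return float((calls == labels).mean())


def sensitivity_specificity(calls, labels) -> tuple:
    """(TP/(TP+FN), TN/(TN+FP)); both classes must be present."""
    calls = np.asarray(calls)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not pos.any():
        raise ValueError("no positive labels present")
    if not neg.any():
        raise ValueError("no negative labels present")
    sens = float((calls[pos] == 1).mean())
    spec = float((calls[neg] == 0).mean())
    return sens, spec


def roc_auc(probabilities, labels) -> tuple:
    """(AUC, roc_points) by threshold sweep; ties step simultaneously.

    ``roc_points`` is a list of (fpr, tpr, threshold) triples, monotone
    non-decreasing in both coordinates; AUC is the trapezoidal integral.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes in the labels")
    fpr, tpr, thr = roc_curve(labels, probabilities)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))


def bootstrap_ci(
    probabilities,
    labels,
    statistic,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    band: str = "percentile",
) -> tuple:
    """Bootstrap interval for ``statistic(probabilities, labels)``.

    Resamples (probability, label) pairs with replacement; resamples that
    collapse to a single class are redrawn.  ``band='percentile'`` gives the
    (alpha/2, 1-alpha/2) percentile interval; ``band='sd'`` gives mean +/- 1
    standard deviation of the bootstrap distribution.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if n < 10:
        raise ValueError("bootstrap needs at least 10 samples")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) > 1:
                break
        vals[b] = statistic(probabilities[idx], labels[idx])
    if band == "sd":
        m, s = float(vals.mean()), float(vals.std())
        return m - s, m + s
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def fleiss_kappa(ratings) -> float:
    """Fleiss' kappa for an items x raters matrix of categorical ratings.

    kappa = (P_bar - P_e) / (1 - P_e) over per-item agreement and marginal
    category proportions.  Undefined (error) when expected agreement is 1,
    i.e. every rating falls in one category.
    """
    ratings = np.asarray(ratings)
    if ratings.ndim != 2 or ratings.shape[0] < 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be an items x raters matrix with >=2 of each")
    counts, _ = aggregate_raters(ratings)
    p_cat = counts.sum(axis=0) / counts.sum()
    if np.isclose((p_cat**2).sum(), 1.0):
        raise ValueError("expected agreement is 1 (all ratings in one category); kappa undefined")
    return float(_sm_fleiss(counts, method="fleiss"))


def region_rollup(calls, positions, thirds=(1.0 / 3.0, 2.0 / 3.0)) -> dict:
    """Collapse slice calls to apex/mid/base region calls.

    Slices are binned by thirds of normalized apex-to-base position; a region
    is positive iff any retained slice in it is positive, and indeterminate
    (None) when it holds no retained slices.
    """
    calls = np.asarray(calls)
    positions = np.asarray(positions, dtype=float)
    lo, hi = thirds
    bins = {
        "apex": positions < lo,
        "mid": (positions >= lo) & (positions <= hi),
        "base": positions > hi,
    }
    out = {}
    for name, m in bins.items():
        out[name] = bool(calls[m].any()) if m.any() else None
    return out


def evaluate(
    probabilities,
    labels,
    threshold: float = 0.5,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvalReport:
    """Full report for one prediction set: accuracy, sens/spec, AUC + CI."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    calls = (probabilities >= threshold).astype(np.int64)
    auc, roc_points = roc_auc(probabilities, labels)
    sens, spec = sensitivity_specificity(calls, labels)
    lo, hi = bootstrap_ci(
        probabilities, labels, lambda p, y: roc_auc(p, y)[0], n_boot=n_boot, seed=seed
    )
    return EvalReport(
        accuracy=accuracy(calls, labels),
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        ci_low=min(lo, auc),
        ci_high=max(hi, auc),
        n_samples=int(len(labels)),
        n_positive=int((labels == 1).sum()),
        roc_points=roc_points,
    )
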