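"""Diagnostic metrics with exact binomial confidence intervals.

Each of the five screening metrics (accuracy, sensitivity, specificity,
positive and negative predictive value) is a binomial proportion k/n, so
its 95% interval is computed exactly by the Clopper–Pearson method via
the beta-quantile characterisation:

    lower = BetaInv(alpha/2;   k,     n - k + 1)        (0 when k = 0)
    upper = BetaInv(1-alpha/2; k + 1, n - k)            (1 when k = n)

The module also reconstructs integer confusion matrices consistent with
percentages that were rounded for publication (useful to recover exact
counts from a printed results table), and provides an ablation harness
that scores a model under several feature masks on a shared split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import beta

METRIC_NAMES = ["accuracy", "sensitivity", "specificity", "ppv", "npv"]


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass(frozen=True)
class MetricCI:
    name: str
    estimate: float
    lower: float
    upper: float
    level: float
    k: int
    n: int


def metrics_from_cm(cm: ConfusionMatrix) -> Dict[str, Optional[Tuple[int, int]]]:
    """The five metrics as exact (k, n) binomial counts.

    A metric whose denominator is zero maps to ``None`` (undefined) rather
    than raising.
    """
    pairs = {
        "accuracy": (cm.TP + cm.TN, cm.total),
        "sensitivity": (cm.TP, cm.TP + cm.FN),
        "specificity": (cm.TN, cm.TN + cm.FP),
        "ppv": (cm.TP, cm.TP + cm.FP),
        "npv": (cm.TN, cm.TN + cm.FN),
    }
    return {name: (k, n) if n > 0 else None for name, (k, n) in pairs.items()}


def clopper_pearson(k: int, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Exact two-sided binomial confidence interval for k successes in n trials."""
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"require 0 <= k <= n, n >= 1; got k={k}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lower, upper


def metric_cis(cm: ConfusionMatrix, level: float = 0.95) -> List[MetricCI]:
    """Point estimates with exact intervals for every defined metric."""
    out = []
    for name, kn in metrics_from_cm(cm).items():
        if kn is None:
            continue
        k, n = kn
        lo, hi = clopper_pearson(k, n, level)
        out.append(MetricCI(name, k / n, lo, hi, level, k, n))
    return out


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of published tables."""
    scale = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def reconstruct_confusion_from_rounded(
    n_total: int,
    n_pos: int,
    rounded_metrics: Dict[str, float],
    decimals: int = 1,
) -> List[ConfusionMatrix]:
    """All integer confusion matrices on ``n_total`` subjects (``n_pos``
    positive) whose accuracy/sensitivity/specificity, in percent, round to
    the published values.

    Exhaustive over TP in [0, n_pos] x TN in [0, n_total - n_pos], returned
    with TP ascending (TN ascending within ties).  PPV and NPV are then
    determined by the matrix and serve as a consistency check downstream.
    """
    if not 0 < n_pos < n_total:
        raise ValueError("require 0 < n_pos < n_total")
    n_neg = n_total - n_pos
    want = {m: rounded_metrics[m] for m in ("accuracy", "sensitivity", "specificity")}
    sols = []
    for tp in range(n_pos + 1):
        if round_half_up(100.0 * tp / n_pos, decimals) != want["sensitivity"]:
            continue
        for tn in range(n_neg + 1):
            if round_half_up(100.0 * tn / n_neg, decimals) != want["specificity"]:
                continue
            if round_half_up(100.0 * (tp + tn) / n_total, decimals) != want["accuracy"]:
                continue
            sols.append(ConfusionMatrix(TP=tp, FP=n_neg - tn, TN=tn, FN=n_pos - tp))
    return sols


def ablation_study(
    table: pd.DataFrame,
    spec,
    feature_sets: Dict[str, Sequence[str]],
    *,
    test_fraction: float = 0.10,
    seed: int = 0,
    label_col: str = "label",
    level: float = 0.95,
) -> pd.DataFrame:
    """Score one model spec under several named feature masks on a shared
    stratified hold-out split.

    Training rows are oversampled to balance; the test rows keep their
    natural prevalence.  Returns one row per mask with the five metrics in
    percent plus the confusion counts.
    """
    from . import classify  # late import; classify depends on this module

    for name, cols in feature_sets.items():
        if not cols:
            raise ValueError(f"feature set {name!r} is empty")
    plan = classify.stratified_split(table, test_fraction, seed, label_col)
    train = table[table["subject_id"].isin(plan.train_ids)]
    test = table[table["subject_id"].isin(plan.test_ids)]
    rows = []
    for name, cols in feature_sets.items():
        model = classify.train_final(train, spec, list(cols), label_col=label_col, seed=seed)
        y_pred = classify.predict(model, test)
        cm = ConfusionMatrix.from_labels(test[label_col].to_numpy(), y_pred)
        row = {"features": name, "n_features": len(cols)}
        for mci in metric_cis(cm, level):
            row[mci.name] = round_half_up(100.0 * mci.estimate, 1)
            row[f"{mci.name}_ci_low"] = round_half_up(100.0 * mci.lower, 1)
            row[f"{mci.name}_ci_high"] = round_half_up(100.0 * mci.upper, 1)
        row.update({"TP": cm.TP, "FP": cm.FP, "TN": cm.TN, "FN": cm.FN})
        rows.append(row)
    return pd.DataFrame(rows)


def metrics_report(cm: ConfusionMatrix, level: float = 0.95) -> dict:
    """JSON-ready report: per metric {estimate, lower, upper, k, n, level}."""
    return {
        mci.name: {
            "estimate": mci.estimate, "lower": mci.lower, "upper": mci.upper,
            "k": mci.k, "n": mci.n, "level": mci.level,
        }
        for mci in metric_cis(cm, level)
    }
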