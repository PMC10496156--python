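"""Dataset balancing, splitting, cross-validation and model training.

Three tree-ensemble families are supported: extremely randomized trees,
gradient boosting, and extreme gradient boosting.  Class imbalance is
handled by random oversampling of the minority class; by default the
oversampling happens *inside* each training fold (and on the training side
of the hold-out split) so that duplicated rows never leak into the data a
model is evaluated on.  A ``pre_split`` mode that balances the whole table
first is available for protocol-fidelity comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from xgboost import XGBClassifier

from .errors import DegenerateLabelsError, SchemaError
from .features import FEATURE_COLUMNS
from .evaluate import ConfusionMatrix

MODEL_FAMILIES = (
    "extremely_randomized_trees",
    "gradient_boosting",
    "extreme_gradient_boosting",
)


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus hyperparameters and a mandatory seed."""

    family: str
    hyperparams: tuple = ()  # sorted (name, value) pairs; hashable
    seed: int = 0
    name: Optional[str] = None

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")

    @classmethod
    def make(cls, family: str, seed: int, name: str | None = None, **hyperparams) -> "ModelSpec":
        return cls(family, tuple(sorted(hyperparams.items())), seed, name or family)

    @property
    def params(self) -> dict:
        return dict(self.hyperparams)


def build_estimator(spec: ModelSpec):
    """Instantiate the sklearn/xgboost estimator for a spec, seed-pinned."""
    p = spec.params
    if spec.family == "extremely_randomized_trees":
        return ExtraTreesClassifier(random_state=spec.seed, n_jobs=1, **p)
    if spec.family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=spec.seed, **p)
    return XGBClassifier(
        random_state=spec.seed, n_jobs=1, verbosity=0, eval_metric="logloss", **p,
    )


@dataclass
class SplitPlan:
    train_ids: List[str]
    test_ids: List[str]
    test_fraction: float
    stratified: bool
    seed: int


def _check_two_classes(y: pd.Series) -> None:
    if y.nunique() < 2:
        raise DegenerateLabelsError("training data contains a single class")


def balance_by_oversampling(table: pd.DataFrame, seed: int, label_col: str = "label") -> pd.DataFrame:
    """Duplicate minority-class rows (sampling with replacement) until the
    class counts are equal.  Every original row is retained."""
    _check_two_classes(table[label_col])
    counts = table[label_col].value_counts()
    minority = counts.idxmin()
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    pool = table[table[label_col] == minority]
    extra = pool.iloc[rng.integers(0, len(pool), size=deficit)]
    return pd.concat([table, extra], ignore_index=True)


def stratified_split(
    table: pd.DataFrame, test_fraction: float = 0.10, seed: int = 0, label_col: str = "label"
) -> SplitPlan:
    """Seeded stratified hold-out split on subject ids."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    y = table[label_col]
    if y.value_counts().min() < 2:
        raise DegenerateLabelsError("each class needs >= 2 members for stratification")
    n_test = int(round(test_fraction * len(table)))
    train_ids, test_ids = train_test_split(
        table["subject_id"].tolist(),
        test_size=n_test,
        stratify=y,
        random_state=seed,
        shuffle=True,
    )
    return SplitPlan(list(train_ids), list(test_ids), test_fraction, True, seed)


def _xy(table: pd.DataFrame, feature_cols: Sequence[str], label_col: str):
    missing = [c for c in feature_cols if c not in table.columns]
    if missing:
        raise SchemaError(f"table lacks feature columns {missing}")
    return table[list(feature_cols)].to_numpy(dtype=float), table[label_col].to_numpy(dtype=int)


@dataclass
class CVResult:
    fold_matrices: List[ConfusionMatrix]
    pooled: ConfusionMatrix
    accuracy: float
    per_sample_correct: np.ndarray  # aligned with the table's row order
    predictions: np.ndarray


def cross_validate(
    table: pd.DataFrame,
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    *,
    feature_cols: Sequence[str] = tuple(FEATURE_COLUMNS),
    label_col: str = "label",
    oversample: str = "train_folds",  # "train_folds" | "pre_split" | "none"
) -> CVResult:
    """Seeded stratified k-fold cross-validation.

    Every row is held out exactly once; oversampling, when enabled in the
    default ``train_folds`` mode, is applied only to each fold's training
    rows so the validation rows keep their natural class balance.
    """
    work = table.reset_index(drop=True)
    if oversample == "pre_split":
        work = balance_by_oversampling(work, seed, label_col)
    X, y = _xy(work, feature_cols, label_col)
    _check_two_classes(work[label_col])
    if min(np.bincount(y)) < k:
        raise DegenerateLabelsError(f"every class needs >= {k} members for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.full(len(y), -1, dtype=int)
    fold_cms = []
    for fold_i, (tr, te) in enumerate(skf.split(X, y)):
        fold_df = work.iloc[tr]
        if oversample == "train_folds":
            fold_df = balance_by_oversampling(fold_df, seed + 1000 + fold_i, label_col)
        Xtr, ytr = _xy(fold_df, feature_cols, label_col)
        est = build_estimator(replace(spec, seed=spec.seed))
        est.fit(Xtr, ytr)
        yp = np.asarray(est.predict(X[te]), dtype=int)
        preds[te] = yp
        fold_cms.append(ConfusionMatrix.from_labels(y[te], yp))
    pooled = ConfusionMatrix(
        TP=sum(m.TP for m in fold_cms), FP=sum(m.FP for m in fold_cms),
        TN=sum(m.TN for m in fold_cms), FN=sum(m.FN for m in fold_cms),
    )
    correct = (preds == y)
    return CVResult(fold_cms, pooled, float(correct.mean()), correct, preds)


def rank_models(
    table: pd.DataFrame,
    candidate_specs: Sequence[ModelSpec],
    k: int = 10,
    seed: int = 0,
    *,
    feature_cols: Sequence[str] = tuple(FEATURE_COLUMNS),
    top: int = 3,
    **cv_kwargs,
) -> List[tuple]:
    """Rank candidates by pooled CV accuracy; stable sort keeps list order
    on ties.  Returns the ``top`` (spec, accuracy) pairs, best first."""
    scored = []
    for spec in candidate_specs:
        res = cross_validate(table, spec, k=k, seed=seed, feature_cols=feature_cols, **cv_kwargs)
        scored.append((spec, res.accuracy))
    order = sorted(range(len(scored)), key=lambda i: -scored[i][1])
    return [scored[i] for i in order[:top]]


@dataclass
class TrainedModel:
    spec: ModelSpec
    feature_cols: List[str]
    estimator: object
    seed: int


def train_final(
    table: pd.DataFrame,
    spec: ModelSpec,
    mask_cols: Sequence[str],
    *,
    label_col: str = "label",
    oversample: bool = True,
    seed: int = 0,
) -> TrainedModel:
    """Fit the final model on the (optionally oversampled) training table
    restricted to the masked feature columns."""
    if not mask_cols:
        raise ValueError("feature mask must be non-empty")
    work = balance_by_oversampling(table, seed, label_col) if oversample else table
    X, y = _xy(work, mask_cols, label_col)
    _check_two_classes(work[label_col])
    est = build_estimator(spec)
    est.fit(X, y)
    return TrainedModel(spec, list(mask_cols), est, seed)


def predict(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    """One predicted label (0/1) per row; empty table → empty array."""
    if len(table) == 0:
        return np.array([], dtype=int)
    missing = [c for c in model.feature_cols if c not in table.columns]
    if missing:
        raise SchemaError(f"prediction table lacks columns {missing}")
    X = table[model.feature_cols].to_numpy(dtype=float)
    return np.asarray(model.estimator.predict(X), dtype=int)
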