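"""Evaluation protocol: error metrics, subject-wise CV, tolerance accuracy and
coverage bounds.

Stage-proportion errors are analysed in percentage points (pp), per stage,
with subjects pooled within a stage.  Two complementary summaries of the
error distribution are provided:

* fixed-tolerance accuracy — the share of subjects whose absolute error falls
  within ±b pp for fixed b (answers *what coverage does a given tolerance
  achieve?*);
* the coverage bound b_c — the smallest symmetric half-width such that at
  least c% of absolute errors lie within ±b_c (the inverse question).  The
  order-statistic definition is used: b_c is the ceil(c·n/100)-th smallest
  |e|, with no interpolation.

Cross-validation is subject-wise: a subject's episode is never split between
training and test folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidArgumentError
from .staging import STAGE_NAMES, fit_stage_models, predict_proportions_table

__all__ = [
    "rmse",
    "mae",
    "pearson_r",
    "subject_wise_kfold",
    "FoldAssignment",
    "fixed_tolerance_accuracy",
    "coverage_bound",
    "cross_validate_staging",
    "error_table_pp",
]


def _paired(pred, truth) -> Tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if p.size != t.size:
        raise InvalidArgumentError("pred and truth differ in length")
    if p.size == 0:
        raise InvalidArgumentError("pred and truth are empty")
    return p, t


def rmse(pred, truth) -> float:
    """Root mean squared error."""
    p, t = _paired(pred, truth)
    return float(np.sqrt(np.mean((p - t) ** 2)))


def mae(pred, truth) -> float:
    """Mean absolute error."""
    p, t = _paired(pred, truth)
    return float(np.mean(np.abs(p - t)))


def pearson_r(x, y) -> float:
    """Product-moment correlation; degenerate on zero-variance input."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise InvalidArgumentError("pearson_r needs two equal-length arrays, n >= 2")
    sx, sy = np.std(x), np.std(y)
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("pearson_r is undefined for zero-variance input")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


@dataclass
class FoldAssignment:
    """Map subject_id -> fold index, with near-equal fold sizes."""

    assignment: Dict[str, int]
    k: int
    seed: Optional[int]

    def fold_subjects(self, fold: int) -> Tuple[list, list]:
        """(train_subjects, test_subjects) for one fold."""
        test = [s for s, f in self.assignment.items() if f == fold]
        train = [s for s, f in self.assignment.items() if f != fold]
        return train, test


def subject_wise_kfold(
    subject_ids: Sequence[str], k: int = 5, seed: Optional[int] = 7
) -> FoldAssignment:
    """Randomly partition subjects into k folds of near-equal size.

    Every subject lands in exactly one fold; fold sizes differ by at most
    one.  Train/test sets per fold are disjoint by construction.
    """
    subjects = list(subject_ids)
    if len(set(subjects)) != len(subjects):
        raise InvalidArgumentError("subject_ids must be unique")
    if k < 2 or k > len(subjects):
        raise InvalidArgumentError("require 2 <= k <= number of subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    assignment = {subjects[int(j)]: int(i % k) for i, j in enumerate(order)}
    return FoldAssignment(assignment=assignment, k=k, seed=seed)


def error_table_pp(pred: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Signed per-subject, per-stage errors (pred - truth) in percentage points."""
    missing = [s for s in STAGE_NAMES if s not in pred.columns or s not in truth.columns]
    if missing:
        raise InvalidArgumentError(f"stage columns missing: {missing}")
    common = pred.index.intersection(truth.index)
    if len(common) == 0:
        raise InvalidArgumentError("pred and truth share no subjects")
    return 100.0 * (
        pred.loc[common, list(STAGE_NAMES)] - truth.loc[common, list(STAGE_NAMES)]
    )


def fixed_tolerance_accuracy(
    errors_pp: pd.DataFrame, bounds_pp: Sequence[float] = (5.0, 10.0, 20.0)
) -> pd.DataFrame:
    """Percentage of subjects with |error| <= b, per stage and bound.

    Returns a (bound x stage) table with an ``average`` column across stages.
    """
    if len(errors_pp) == 0:
        raise InvalidArgumentError("error table is empty")
    rows = {}
    for b in bounds_pp:
        accs = {
            s: 100.0 * float(np.mean(np.abs(errors_pp[s].to_numpy()) <= b))
            for s in STAGE_NAMES
        }
        accs["average"] = float(np.mean(list(accs.values())))
        rows[b] = accs
    return pd.DataFrame.from_dict(rows, orient="index")


def coverage_bound(abs_errors_pp, coverage_pct: float) -> float:
    """Smallest half-width b_c with at least ``coverage_pct``% of |e| <= b_c.

    Implemented as the ceil(c*n/100)-th order statistic of the absolute
    errors.
    """
    if not 0 < coverage_pct <= 100:
        raise InvalidArgumentError("coverage_pct must lie in (0, 100]")
    e = np.abs(np.asarray(abs_errors_pp, dtype=float).ravel())
    if e.size == 0:
        raise InvalidArgumentError("coverage_bound needs at least one error")
    k = int(np.ceil(coverage_pct * e.size / 100.0))
    return float(np.sort(e)[k - 1])


def cross_validate_staging(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    regressor_kind: str = "rfr",
    k: int = 5,
    seed: int = 7,
    standardize: bool = True,
) -> Tuple[pd.DataFrame, FoldAssignment]:
    """Subject-wise k-fold CV of the staging regressors.

    Returns held-out simplex predictions (one row per subject, aligned with
    ``Y``) and the fold assignment used.  The model seed for stochastic
    learners is derived from the CV seed.
    """
    folds = subject_wise_kfold(list(X.index), k=k, seed=seed)
    preds = []
    for fold in range(k):
        train, test = folds.fold_subjects(fold)
        bundle = fit_stage_models(
            X.loc[train],
            Y.loc[train],
            regressor_kind=regressor_kind,
            seed=seed + fold,
            standardize=standardize,
            feature_order=tuple(X.columns),
        )
        preds.append(predict_proportions_table(bundle, X.loc[test]))
    pred = pd.concat(preds).loc[X.index]
    return pred, folds
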