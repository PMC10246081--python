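"""Phenotype prediction from vectorized connectivity features.

Evaluation follows the standard neuroimaging protocol: linear models (ridge
regression with alpha=1 for continuous targets, L2 logistic regression with
C=1, max 1000 iterations for binary targets) scored over repeated random
80/20 train/test splits (20 repetitions by default), reporting RMSE for
regression and ROC AUC from continuous decision scores for classification.
Age targets are centered by the *training* mean only (no test leakage).

Two feature views (e.g. the angle-basis reconstruction and its residual) are
combined by output averaging on identical splits: each view gets its own
model, their decision scores / predictions are averaged and the average is
scored.  Averaging makes "the same view twice" exactly equal to the single
view, which is the correct null behaviour for an ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.linear_model import Lasso, LogisticRegression, Ridge
from sklearn.metrics import roc_auc_score

__all__ = [
    "PredictionResult",
    "bootstrap_eval",
    "ensemble_eval",
    "transfer_eval",
    "select_features",
    "compare",
    "filter_ancestry",
]

_TASKS = ("regression", "classification")
_MAX_SPLIT_TRIES = 1000


@dataclass(frozen=True)
class PredictionResult:
    task: str
    per_rep_metric: list[float]
    mean: float
    std: float
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.task not in _TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        reps = self.config.get("n_reps")
        if reps is not None and len(self.per_rep_metric) != reps:
            raise ValueError("per_rep_metric length does not match configured repetitions")
        vals = np.asarray(self.per_rep_metric, dtype=float)
        if self.task == "classification" and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("AUC values must lie in [0, 1]")
        if self.task == "regression" and vals.min() < 0:
            raise ValueError("RMSE values must be nonnegative")


def _validate_xy(features, targets, task):
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets)
    if x.ndim != 2:
        raise ValueError("features must be 2-D")
    if y.shape[0] != x.shape[0]:
        raise ValueError("features and targets disagree on number of rows")
    if task not in _TASKS:
        raise ValueError(f"task must be one of {_TASKS}")
    if np.all(x.std(axis=0) == 0):
        raise ValueError("degenerate features: zero variance everywhere")
    if task == "classification":
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"classification needs exactly 2 classes, got {classes.size}")
        y = (y == classes[1]).astype(int)  # classes sorted; positive = larger label
    else:
        y = y.astype(float)
    return x, y


def _split(rng, m, test_fraction, y, task):
    """Random split; resampled until both classes appear in train and test."""
    n_test = max(1, int(round(test_fraction * m)))
    if n_test >= m:
        raise ValueError("test fraction leaves no training rows")
    for _ in range(_MAX_SPLIT_TRIES):
        perm = rng.permutation(m)
        test, train = perm[:n_test], perm[n_test:]
        if task == "regression":
            return train, test
        if len(np.unique(y[train])) == 2 and len(np.unique(y[test])) == 2:
            return train, test
    raise ValueError("could not draw a split with both classes in train and test")


def _fit_predict(x_train, y_train, x_test, task):
    """Fit the standard linear model; return continuous outputs on x_test.

    Regression outputs are on the train-mean-centered scale (the constant
    cancels in RMSE); classification outputs are decision scores.
    """
    if task == "regression":
        center = y_train.mean()
        model = Ridge(alpha=1.0, max_iter=1000)
        model.fit(x_train, y_train - center)
        return model.predict(x_test), center
    model = LogisticRegression(C=1.0, max_iter=1000)
    model.fit(x_train, y_train)
    return model.decision_function(x_test), None


def _score(y_test, output, center, task):
    if task == "regression":
        return float(np.sqrt(np.mean(((y_test - center) - output) ** 2)))
    return float(roc_auc_score(y_test, output))


def _eval_views(views, targets, task, n_reps, test_fraction, seed):
    """Shared engine: one model per view per rep on identical splits."""
    xs = []
    y = None
    for v in views:
        x, y = _validate_xy(v, targets, task)
        xs.append(x)
    if any(x.shape[0] != xs[0].shape[0] for x in xs):
        raise ValueError("all feature views must have the same rows")
    m = xs[0].shape[0]
    if m < 10:
        raise ValueError("need at least 10 rows")
    metrics = []
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        train, test = _split(rng, m, test_fraction, y, task)
        outputs = []
        center = None
        for x in xs:
            out, center = _fit_predict(x[train], y[train], x[test], task)
            outputs.append(out)
        avg = np.mean(outputs, axis=0)
        metrics.append(_score(y[test], avg, center, task))
    vals = np.asarray(metrics)
    return PredictionResult(
        task=task,
        per_rep_metric=[float(v) for v in vals],
        mean=float(vals.mean()),
        std=float(vals.std(ddof=1)) if n_reps > 1 else 0.0,
        config={
            "n_reps": n_reps,
            "test_fraction": test_fraction,
            "seed": seed,
            "alpha": 1.0,
            "C": 1.0,
            "n_views": len(views),
        },
    )


def bootstrap_eval(
    features,
    targets,
    task: str,
    n_reps: int = 20,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> PredictionResult:
    """Repeated random-split evaluation of one feature view."""
    return _eval_views([features], targets, task, n_reps, test_fraction, seed)


def ensemble_eval(
    features_a,
    features_b,
    targets,
    task: str,
    n_reps: int = 20,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> PredictionResult:
    """Two-view output-averaging ensemble on identical splits."""
    return _eval_views([features_a, features_b], targets, task, n_reps, test_fraction, seed)


def transfer_eval(train_features, train_targets, test_features, test_targets, task: str) -> float:
    """Cross-cohort transfer: one fit on the full training cohort, one evaluation.

    For classification the two cohorts must share the same label vocabulary.
    """
    x_tr, y_tr = _validate_xy(train_features, train_targets, task)
    if task == "classification":
        vocab_tr = set(np.unique(np.asarray(train_targets)).tolist())
        vocab_te = set(np.unique(np.asarray(test_targets)).tolist())
        if vocab_te - vocab_tr:
            raise ValueError(
                f"test labels {sorted(vocab_te - vocab_tr)!r} absent from training vocabulary"
            )
    x_te, y_te = _validate_xy(test_features, test_targets, task)
    if x_te.shape[1] != x_tr.shape[1]:
        raise ValueError("feature dimension differs between cohorts")
    out, center = _fit_predict(x_tr, y_tr, x_te, task)
    return _score(y_te, out, center, task)


def select_features(features, targets, task: str, method: str = "ridge", k: int = 10):
    """Indices of the k largest-magnitude coefficients of a linear selector.

    Fit on the rows given (by protocol, a designated selection half of the
    data; the caller re-evaluates on the held-out half with
    :func:`bootstrap_eval` restricted to the returned indices).  ``ridge``
    maps to L2 (Ridge / L2-logistic), ``lasso`` to L1 (Lasso / L1-logistic).
    """
    x, y = _validate_xy(features, targets, task)
    if not 0 <= k <= x.shape[1]:
        raise ValueError(f"k must be in [0, {x.shape[1]}], got {k}")
    if k == 0:
        return []
    if method not in ("ridge", "lasso"):
        raise ValueError(f"method must be 'ridge' or 'lasso', got {method!r}")
    if task == "regression":
        model = Ridge(alpha=1.0) if method == "ridge" else Lasso(alpha=0.01, max_iter=5000)
        model.fit(x, y - y.mean())
        coefs = model.coef_
    else:
        if method == "ridge":
            model = LogisticRegression(C=1.0, max_iter=1000)
        else:
            model = LogisticRegression(C=1.0, l1_ratio=1, solver="liblinear", max_iter=1000)
        model.fit(x, y)
        coefs = model.coef_.ravel()
    order = np.argsort(-np.abs(coefs), kind="stable")
    return sorted(int(i) for i in order[:k])


def compare(result_a: PredictionResult, result_b: PredictionResult) -> float:
    """Two-sided Welch t-test p-value between two per-repetition metric samples."""
    a = np.asarray(result_a.per_rep_metric, dtype=float)
    b = np.asarray(result_b.per_rep_metric, dtype=float)
    if a.shape != b.shape:
        raise ValueError("repetition counts differ")
    if np.array_equal(a, b):
        return 1.0  # zero t-statistic convention
    t = scipy.stats.ttest_ind(a, b, equal_var=False)
    p = float(t.pvalue)
    return 1.0 if np.isnan(p) else p


def filter_ancestry(table, labels=("AA", "EA"), column: str = "race"):
    """Keep only rows whose ancestry label is in ``labels`` (applied before any split)."""
    keep = table[column].isin(list(labels))
    return table.loc[keep].reset_index(drop=True)
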