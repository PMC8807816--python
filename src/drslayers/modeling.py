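"""Regression and classification experiments under grouped iterated cross-validation.

Thickness regression (linear support-vector regression vs. Gaussian process
regression with an exponential kernel) and per-layer tissue classification
(quadratic-kernel SVM, fat as the positive class) are evaluated with
iterated 10-fold cross-validation: folds are drawn over measurement
*locations*, never over individual spectra, so repeated acquisitions of one
spot cannot leak between training and test sets. Results are averaged over
the iterations (20 by default).

Reported statistics: mean +/- SD of the absolute thickness error over all
held-out predictions, Bland-Altman bias and 95% limits of agreement,
iteration-averaged accuracy / MCC / AUC / sensitivity / specificity, and a
mean ROC curve (vertical averaging on a fixed false-positive-rate grid)
with an SD band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.metrics import roc_curve
from sklearn.svm import SVC, SVR

from .metrics import auc as rank_auc
from .metrics import bland_altman, mcc as mcc_from_counts

__all__ = [
    "StudyTable",
    "CVConfig",
    "RegressionReport",
    "ClassificationReport",
    "grouped_kfold",
    "run_regression",
    "run_classification",
    "REGRESSION_MODELS",
]

logger = logging.getLogger(__name__)

#: False-positive-rate grid for vertical ROC averaging.
ROC_FPR_GRID = np.linspace(0.0, 1.0, 101)

REGRESSION_MODELS = ("linear_svm", "exponential_gpr", "mean_baseline")


@dataclass(frozen=True)
class StudyTable:
    """Per-measurement features plus targets, labels and CV group ids.

    ``frame`` must contain columns ``sample_id``, ``location_id``,
    ``thickness_mm``, ``top_label``, ``bottom_label`` and every name in
    ``feature_names``.
    """

    frame: pd.DataFrame
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        required = {"sample_id", "location_id", "thickness_mm", "top_label", "bottom_label"}
        missing = required.union(self.feature_names) - set(self.frame.columns)
        if missing:
            raise ValueError(f"StudyTable missing columns: {sorted(missing)}")
        if self.frame["thickness_mm"].isna().any():
            raise ValueError("missing thickness targets")
        if len(self.frame) == 0:
            raise ValueError("empty study table")

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def groups(self) -> np.ndarray:
        return self.frame["location_id"].to_numpy()


@dataclass(frozen=True)
class CVConfig:
    """Iterated grouped k-fold settings (10 folds, 20 iterations by default)."""

    k: int = 10
    iterations: int = 20
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class RegressionReport:
    """Thickness-regression evaluation summary (errors in mm)."""

    model: str
    mean_abs_error: float
    sd_abs_error: float
    per_sample_pred: pd.Series
    per_sample_abs_error: pd.Series
    bias: float
    lower_loa: float
    upper_loa: float
    n_samples: int
    n_iterations: int


@dataclass(frozen=True)
class ClassificationReport:
    """Binary tissue-classification summary; metrics averaged over iterations."""

    layer: str
    positive_label: str
    accuracy: float
    mcc: float
    auc: float
    sensitivity: float
    specificity: float
    metric_sds: dict[str, float]
    roc_fpr: np.ndarray
    roc_tpr_mean: np.ndarray
    roc_tpr_sd: np.ndarray
    n_samples: int
    n_iterations: int
    refit_events: int = field(default=0)


def grouped_kfold(groups: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Assign every sample to one of ``k`` folds, keeping groups intact.

    Distinct group ids are shuffled (deterministically for a given seed) and
    split into ``k`` nearly equal blocks, so fold sizes in *groups* differ by
    at most one and no group ever spans two folds.
    """
    groups = np.asarray(groups)
    unique = np.unique(groups)
    if len(unique) < k:
        raise ValueError(f"need at least {k} distinct groups, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    fold_of_group: dict = {}
    for fold, chunk in enumerate(np.array_split(unique[order], k)):
        for g in chunk:
            fold_of_group[g] = fold
    return np.array([fold_of_group[g] for g in groups], dtype=int)


def _zscore_train_test(
    X_train: np.ndarray, X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score with training-fold statistics, dropping zero-variance features."""
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance feature(s)", stacklevel=3
        )
    return (X_train[:, keep] - mean[keep]) / sd[keep], (X_test[:, keep] - mean[keep]) / sd[keep]


def _make_regressor(model: str, seed: int):
    if model == "linear_svm":
        return SVR(kernel="linear", C=1.0, epsilon=0.1)
    if model == "exponential_gpr":
        # Matern nu=1/2 is the exponential (Ornstein-Uhlenbeck) kernel
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=1.0, length_scale_bounds=(1e-2, 1e3), nu=0.5
        ) + WhiteKernel(1e-2, (1e-8, 1e1))
        return GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=3,
            random_state=seed,
        )
    if model == "mean_baseline":
        return _MeanBaseline()
    raise ValueError(f"unknown regression model {model!r}; choose from {REGRESSION_MODELS}")


class _MeanBaseline:
    """Predict the training-set mean thickness (reference for skill checks)."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


def run_regression(
    table: StudyTable, model: str = "exponential_gpr", cv: CVConfig = CVConfig()
) -> RegressionReport:
    """Evaluate a thickness regressor under iterated grouped 10-fold CV.

    Per iteration, folds are redrawn with seed ``base_seed + iteration``,
    features are z-scored on the training folds, and held-out predictions
    are collected; the report gives the mean and SD of the absolute error
    over all held-out predictions of all iterations, per-sample mean
    predictions, and Bland-Altman agreement statistics of those means.
    """
    y = table.frame["thickness_mm"].to_numpy(dtype=float)
    X = table.X
    sample_ids = table.frame["sample_id"].to_numpy()
    groups = table.groups
    all_abs_errors: list[np.ndarray] = []
    pred_sum = np.zeros(len(y))
    for it in range(cv.iterations):
        folds = grouped_kfold(groups, cv.k, cv.base_seed + it)
        preds = np.empty(len(y))
        for fold in range(cv.k):
            test = folds == fold
            train = ~test
            Xtr, Xte = _zscore_train_test(X[train], X[test])
            reg = _make_regressor(model, seed=cv.base_seed + it)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # GPR convergence chatter
                reg.fit(Xtr, y[train])
            preds[test] = reg.predict(Xte)
        all_abs_errors.append(np.abs(preds - y))
        pred_sum += preds
    abs_errors = np.concatenate(all_abs_errors)
    per_sample_pred = pd.Series(pred_sum / cv.iterations, index=sample_ids)
    per_sample_abs_error = pd.Series(
        np.mean(np.stack(all_abs_errors), axis=0), index=sample_ids
    )
    bias, lo, hi = bland_altman(per_sample_pred.to_numpy(), y)
    return RegressionReport(
        model=model,
        mean_abs_error=float(abs_errors.mean()),
        sd_abs_error=float(abs_errors.std(ddof=1)),
        per_sample_pred=per_sample_pred,
        per_sample_abs_error=per_sample_abs_error,
        bias=bias,
        lower_loa=lo,
        upper_loa=hi,
        n_samples=len(y),
        n_iterations=cv.iterations,
    )


def _confusion(pred_pos: np.ndarray, is_pos: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum(pred_pos & is_pos))
    tn = int(np.sum(~pred_pos & ~is_pos))
    fp = int(np.sum(pred_pos & ~is_pos))
    fn = int(np.sum(~pred_pos & is_pos))
    return tp, tn, fp, fn


def run_classification(
    table: StudyTable,
    layer: str = "first",
    cv: CVConfig = CVConfig(),
    positive_label: str = "fat",
) -> ClassificationReport:
    """Classify one tissue layer with a quadratic-kernel SVM under grouped CV.

    ``layer='first'`` targets the top-layer label on all samples;
    ``layer='second'`` targets the bottom-layer label on two-layered samples
    only (thickness > 0). Metrics are computed per iteration over that
    iteration's pooled held-out predictions, then averaged across iterations;
    the ROC curve is vertically averaged on a 101-point FPR grid. If a fold
    draw leaves a training fold single-class, folds for that iteration are
    redrawn with an incremented seed (logged).
    """
    if layer == "first":
        frame = table.frame
        labels = frame["top_label"]
    elif layer == "second":
        frame = table.frame[table.frame["thickness_mm"] > 0]
        labels = frame["bottom_label"]
    else:
        raise ValueError("layer must be 'first' or 'second'")
    is_pos = (labels == positive_label).to_numpy()
    if is_pos.all() or not is_pos.any():
        raise ValueError("classification needs both classes present")
    X = frame[list(table.feature_names)].to_numpy(dtype=float)
    groups = frame["location_id"].to_numpy()

    per_iter = {m: [] for m in ("accuracy", "mcc", "auc", "sensitivity", "specificity")}
    tprs: list[np.ndarray] = []
    refit_events = 0
    for it in range(cv.iterations):
        seed = cv.base_seed + it
        for _attempt in range(20):
            folds = grouped_kfold(groups, cv.k, seed)
            ok = all(
                len(np.unique(is_pos[folds != fold])) == 2 for fold in range(cv.k)
            )
            if ok:
                break
            refit_events += 1
            logger.info("single-class training fold at iteration %d; redrawing", it)
            seed += cv.iterations  # stay clear of other iterations' seeds
        else:
            raise RuntimeError("could not draw folds with both classes in training")
        scores = np.empty(len(is_pos))
        pred_pos = np.empty(len(is_pos), dtype=bool)
        for fold in range(cv.k):
            test = folds == fold
            train = ~test
            Xtr, Xte = _zscore_train_test(X[train], X[test])
            clf = SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=1.0)
            clf.fit(Xtr, is_pos[train])
            margin = clf.decision_function(Xte)
            scores[test] = margin
            pred_pos[test] = margin > 0
        tp, tn, fp, fn = _confusion(pred_pos, is_pos)
        per_iter["accuracy"].append((tp + tn) / len(is_pos))
        per_iter["mcc"].append(mcc_from_counts(tp, tn, fp, fn))
        per_iter["auc"].append(rank_auc(scores, is_pos))
        per_iter["sensitivity"].append(tp / (tp + fn))
        per_iter["specificity"].append(tn / (tn + fp))
        fpr, tpr, _ = roc_curve(is_pos, scores)
        tprs.append(np.interp(ROC_FPR_GRID, fpr, tpr))
    means = {m: float(np.mean(v)) for m, v in per_iter.items()}
    sds = {m: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for m, v in per_iter.items()}
    tpr_stack = np.stack(tprs)
    return ClassificationReport(
        layer=layer,
        positive_label=positive_label,
        accuracy=means["accuracy"],
        mcc=means["mcc"],
        auc=means["auc"],
        sensitivity=means["sensitivity"],
        specificity=means["specificity"],
        metric_sds=sds,
        roc_fpr=ROC_FPR_GRID.copy(),
        roc_tpr_mean=tpr_stack.mean(axis=0),
        roc_tpr_sd=tpr_stack.std(axis=0, ddof=1) if len(tprs) > 1 else np.zeros_like(ROC_FPR_GRID),
        n_samples=len(is_pos),
        n_iterations=cv.iterations,
        refit_events=refit_events,
    )
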