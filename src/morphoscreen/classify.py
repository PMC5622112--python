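"""Linear-SVM discrimination of treated vs control cell populations.

The decision function is the linear score Y = w . x + b, where w is the
normal vector to the separating hyperplane (the weight assigned to each
feature) and b the bias. Accuracy is A = (X1 + X2) / N: correctly assigned
incidences of the two classes over the test size, ranging from 0.5 (chance,
for balanced classes) to 1.0 (perfect).

Features are z-scored with parameters fitted on training rows only; the
margin optimization is delegated to scikit-learn's liblinear solver — the
contract here is the linear decision form, the no-leakage cross-validation
protocol, and the accuracy bookkeeping.

Label convention throughout: +1 = treated, -1 = control. Tie scores (Y = 0)
are assigned to the control class deterministically.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import LinearSVC

from .synthetic import feature_matrix

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# Standardization
# --------------------------------------------------------------------------- #

@dataclass
class Standardizer:
    """Per-feature z-scoring parameters (zero-variance features map to 0)."""

    mean_: np.ndarray
    scale_: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_) / self.scale_


def standardize_fit(X: np.ndarray) -> Standardizer:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("standardize_fit needs a 2D array with >= 2 rows")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)  # constant columns -> 0 after apply
    return Standardizer(mean_=mean, scale_=scale)


def standardize_apply(standardizer: Standardizer, X: np.ndarray) -> np.ndarray:
    return standardizer.apply(X)


# --------------------------------------------------------------------------- #
# Model
# --------------------------------------------------------------------------- #

@dataclass
class LinearSVMModel:
    """w, b of the linear decision function plus the training standardizer."""

    w: np.ndarray
    b: float
    standardizer: Standardizer | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "w": self.w.tolist(),
            "b": self.b,
            "standardizer": None
            if self.standardizer is None
            else {
                "mean": self.standardizer.mean_.tolist(),
                "scale": self.standardizer.scale_.tolist(),
            },
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearSVMModel":
        std = d.get("standardizer")
        return cls(
            w=np.asarray(d["w"], dtype=float),
            b=float(d["b"]),
            standardizer=None
            if std is None
            else Standardizer(
                mean_=np.asarray(std["mean"]), scale_=np.asarray(std["scale"])
            ),
            metadata=d.get("metadata", {}),
        )


@dataclass
class ClassificationResult:
    """Accuracy bookkeeping: A = (X1 + X2) / N."""

    scores: np.ndarray
    predictions: np.ndarray
    x1: int  # correct control (-1) assignments
    x2: int  # correct treated (+1) assignments
    n: int
    accuracy: float


@dataclass
class CVResult:
    mean_accuracy: float
    se: float
    fold_accuracies: np.ndarray


def train_svm(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, seed: int = 0
) -> LinearSVMModel:
    """Fit a linear max-margin classifier on standardized rows.

    Both classes must be present. The solver is liblinear (squared hinge);
    w and b are exposed directly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    svc = LinearSVC(C=C, dual=False, random_state=seed, max_iter=10000)
    svc.fit(X, y)
    return LinearSVMModel(
        w=svc.coef_.ravel().copy(),
        b=float(svc.intercept_[0]),
        metadata={"C": C, "seed": seed, "n_train": int(len(y))},
    )


def fit_model(
    X_raw: np.ndarray, y: np.ndarray, C: float = 1.0, seed: int = 0, **metadata
) -> LinearSVMModel:
    """Standardize (fit on these rows) then train; returns a complete model."""
    std = standardize_fit(X_raw)
    model = train_svm(std.apply(X_raw), y, C=C, seed=seed)
    model.standardizer = std
    model.metadata.update(metadata)
    return model


def score(model: LinearSVMModel, x: np.ndarray) -> np.ndarray | float:
    """Y = w . x + b for one standardized vector or a stack of them."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.w.shape[0]:
        raise ValueError(
            f"dimension mismatch: x has {x.shape[-1]} features, "
            f"model has {model.w.shape[0]}"
        )
    y = x @ model.w + model.b
    return float(y) if np.ndim(y) == 0 else y


def decision_scores(model: LinearSVMModel, X_raw: np.ndarray) -> np.ndarray:
    """Scores for raw rows: applies the model's standardizer first."""
    if model.standardizer is None:
        raise ValueError("model has no standardizer; use score() on standardized x")
    return np.atleast_1d(score(model, model.standardizer.apply(X_raw)))


def predict(model: LinearSVMModel, X_raw: np.ndarray) -> np.ndarray:
    """+1 treated / -1 control; ties (Y = 0) go to control."""
    return np.where(decision_scores(model, X_raw) > 0, 1, -1)


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> ClassificationResult:
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    n = labels.size
    if n == 0:
        raise ValueError("empty input")
    correct = predictions == labels
    x1 = int(np.sum(correct & (labels == -1)))
    x2 = int(np.sum(correct & (labels == 1)))
    return ClassificationResult(
        scores=np.asarray(predictions, dtype=float),
        predictions=predictions,
        x1=x1,
        x2=x2,
        n=n,
        accuracy=(x1 + x2) / n,
    )


def evaluate(model: LinearSVMModel, X_raw: np.ndarray, y: np.ndarray) -> ClassificationResult:
    res = accuracy(predict(model, X_raw), y)
    res.scores = decision_scores(model, X_raw)
    return res


# --------------------------------------------------------------------------- #
# Cross-validation
# --------------------------------------------------------------------------- #

def cross_validate(
    X: np.ndarray, y: np.ndarray, k: int = 10, C: float = 1.0, seed: int = 0
) -> CVResult:
    """Stratified k-fold CV with standardizer and SVM fitted per fold.

    k = n is accepted as leave-one-out (unstratified by necessity); otherwise
    each class must contain at least k rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k == n:
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        counts = np.unique(y, return_counts=True)[1]
        if counts.min() < k:
            raise ValueError(
                f"smallest class has {counts.min()} rows, fewer than k={k} folds"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
    accs = []
    for train_idx, test_idx in folds:
        model = fit_model(X[train_idx], y[train_idx], C=C, seed=seed)
        accs.append(evaluate(model, X[test_idx], y[test_idx]).accuracy)
    accs = np.asarray(accs)
    se = float(accs.std(ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0
    return CVResult(float(accs.mean()), se, accs)


# --------------------------------------------------------------------------- #
# Study-level constructs
# --------------------------------------------------------------------------- #

def _balance(
    Xa: np.ndarray, Xb: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Downsample the larger of two row blocks to the smaller's size."""
    na, nb = len(Xa), len(Xb)
    m = min(na, nb)
    if na > m:
        Xa = Xa[rng.choice(na, m, replace=False)]
    if nb > m:
        Xb = Xb[rng.choice(nb, m, replace=False)]
    return Xa, Xb


def _condition_block(
    table: pd.DataFrame, dose: float, duration: int, experiment: int
) -> np.ndarray | None:
    sel = (
        (table["dose_M"] == dose)
        & (table["duration_h"] == duration)
        & (table["experiment"] == experiment)
    )
    if not sel.any():
        return None
    return feature_matrix(table.loc[sel])


def dose_response_curve(
    table: pd.DataFrame,
    k: int = 10,
    C: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-dose classification accuracy with four-trial error bars.

    For each duration and nonzero dose, the four control-group x
    treated-group pairings across the two experimental repeats are each
    classified with k-fold CV; the table reports the mean over the four
    trials, the trial-to-trial standard error, and the mean within-trial CV
    standard error (the two error sources are kept separate).
    """
    experiments = sorted(table["experiment"].unique())
    durations = sorted(table["duration_h"].unique())
    doses = sorted(d for d in table["dose_M"].unique() if d > 0)
    rng = np.random.default_rng(seed)
    rows = []
    for duration in durations:
        controls = {
            e: _condition_block(table, 0.0, duration, e) for e in experiments
        }
        for dose in doses:
            trial_accs, trial_ses = [], []
            skip = False
            for ce, te in itertools.product(experiments, experiments):
                Xc = controls[ce]
                Xt = _condition_block(table, dose, duration, te)
                if Xc is None or Xt is None:
                    logger.warning(
                        "missing group (dose=%g, duration=%d, exp %s/%s); "
                        "dose skipped",
                        dose,
                        duration,
                        ce,
                        te,
                    )
                    skip = True
                    break
                Xc_b, Xt_b = _balance(Xc, Xt, rng)
                X = np.vstack([Xc_b, Xt_b])
                y = np.concatenate([-np.ones(len(Xc_b)), np.ones(len(Xt_b))])
                cv = cross_validate(X, y, k=k, C=C, seed=seed)
                trial_accs.append(cv.mean_accuracy)
                trial_ses.append(cv.se)
            if skip:
                continue
            trial_accs = np.asarray(trial_accs)
            rows.append(
                {
                    "duration_h": duration,
                    "dose_M": dose,
                    "accuracy": float(trial_accs.mean()),
                    "se_trials": float(
                        trial_accs.std(ddof=1) / np.sqrt(len(trial_accs))
                    ),
                    "mean_cv_se": float(np.mean(trial_ses)),
                    "n_trials": len(trial_accs),
                }
            )
    return pd.DataFrame(rows)


def transfer_matrix(
    table: pd.DataFrame,
    duration: int = 24,
    C: float = 1.0,
    seed: int = 0,
    holdout: float = 0.2,
) -> pd.DataFrame:
    """Accuracy of single models applied across all conditions.

    Rows are training conditions (dose, experiment), columns testing
    conditions. Each model is trained on a (1 - holdout) stratified split of
    its condition; the diagonal is evaluated on the held-out split only,
    off-diagonal cells on the full test condition. Missing datasets yield
    NaN, never 0.
    """
    experiments = sorted(table["experiment"].unique())
    doses = sorted(d for d in table["dose_M"].unique() if d > 0)
    conditions = [(d, e) for e in experiments for d in doses]
    rng = np.random.default_rng(seed)

    def dataset(dose, exp):
        Xc = _condition_block(table, 0.0, duration, exp)
        Xt = _condition_block(table, dose, duration, exp)
        if Xc is None or Xt is None:
            return None
        Xc, Xt = _balance(Xc, Xt, rng)
        X = np.vstack([Xc, Xt])
        y = np.concatenate([-np.ones(len(Xc)), np.ones(len(Xt))])
        return X, y

    datasets = {cond: dataset(*cond) for cond in conditions}
    labels = [f"{d:g}M/exp{e}" for d, e in conditions]
    out = pd.DataFrame(np.nan, index=labels, columns=labels)

    for (train_cond, train_label) in zip(conditions, labels):
        ds = datasets[train_cond]
        if ds is None:
            continue
        X, y = ds
        X_tr, X_ho, y_tr, y_ho = train_test_split(
            X, y, test_size=holdout, stratify=y, random_state=seed
        )
        model = fit_model(X_tr, y_tr, C=C, seed=seed)
        for (test_cond, test_label) in zip(conditions, labels):
            if test_cond == train_cond:
                out.loc[train_label, test_label] = evaluate(
                    model, X_ho, y_ho
                ).accuracy
            elif datasets[test_cond] is not None:
                Xt, yt = datasets[test_cond]
                out.loc[train_label, test_label] = evaluate(model, Xt, yt).accuracy
    return out


def score_histogram(
    model: LinearSVMModel,
    X_raw: np.ndarray,
    y: np.ndarray,
    bins: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aligned per-class histograms of the decision score Y.

    Returns (bin_edges, control_counts, treated_counts); counts sum to the
    class sizes.
    """
    ys = decision_scores(model, X_raw)
    y = np.asarray(y)
    lo, hi = ys.min(), ys.max()
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    control, _ = np.histogram(ys[y == -1], bins=edges)
    treated, _ = np.histogram(ys[y == 1], bins=edges)
    return edges, control, treated


def train_on_table(
    table: pd.DataFrame,
    dose: float,
    duration: int = 24,
    experiment: int = 1,
    C: float = 1.0,
    seed: int = 0,
) -> LinearSVMModel:
    """Convenience: fit control-vs-treated at one condition of a table."""
    Xc = _condition_block(table, 0.0, duration, experiment)
    Xt = _condition_block(table, dose, duration, experiment)
    if Xc is None or Xt is None:
        raise ValueError(
            f"missing control or treated data at dose={dose:g}, "
            f"duration={duration}, experiment={experiment}"
        )
    rng = np.random.default_rng(seed)
    Xc, Xt = _balance(Xc, Xt, rng)
    X = np.vstack([Xc, Xt])
    y = np.concatenate([-np.ones(len(Xc)), np.ones(len(Xt))])
    return fit_model(
        X, y, C=C, seed=seed, dose_M=dose, duration_h=duration, experiment=experiment
    )
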