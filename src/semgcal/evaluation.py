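"""Classification and evaluation of the cross-session protocol.

The workflow per dataset cell: standardize features with training-set
statistics only, train a frozen-hyperparameter classifier (default: RBF
soft-margin SVM with C=1 and a median-distance kernel width), predict the
test frames, smooth predictions with a causal 3-frame mode vote within
each trial, and score frame-level accuracy (%).

``run_cross_session_table`` produces the variant x test-session x n_calib
accuracy table with per-variant averages and the improvement row
(cumulative average minus the single baseline accuracy).
``run_training_grid`` + ``average_accuracy_curves`` + ``fit_log_curve``
produce the accuracy-vs-training-amount analysis: average accuracy (AA)
marginalised over sessions or trials, with logarithmic fits
y = a*ln(x) + b whose slopes quantify which axis of data collection pays
more.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import META_COLUMNS
from .protocol import (DatasetAssembly, GridCell, ProtocolSpec, Triple, VARIANTS,
                       assemble_dataset)

__all__ = [
    "Standardizer", "ClassifierSpec", "EvalTable", "CurveFit",
    "make_classifier", "train_predict", "mode_postprocess", "accuracy",
    "evaluate_assembly", "run_cross_session_table", "improvement_from_accuracies",
    "run_training_grid", "average_accuracy_curves", "fit_log_curve",
    "compare_classifiers",
]

logger = logging.getLogger(__name__)

STD_FLOOR = 1e-12


class Standardizer:
    """Per-feature z-scoring with statistics estimated from training rows only."""

    def __init__(self) -> None:
        self.mean_: Optional[np.ndarray] = None
        self.std_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0, ddof=0)
        if np.any(std < STD_FLOOR):
            logger.warning("%d constant feature(s); std floored", int((std < STD_FLOOR).sum()))
        self.std_ = np.maximum(std, STD_FLOOR)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("standardizer not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.std_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


@dataclass(frozen=True)
class ClassifierSpec:
    """Frozen classifier choice; hyperparameters never change between the
    dataset variants of one experiment."""

    algorithm: str = "svm"
    params: Tuple[Tuple[str, object], ...] = ()
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps([self.algorithm, list(map(list, self.params)), self.seed])
        return hashlib.sha256(payload.encode()).hexdigest()

    @property
    def param_dict(self) -> Dict[str, object]:
        return dict(self.params)


def _median_heuristic_gamma(X: np.ndarray, max_rows: int = 256) -> float:
    """RBF width from the median pairwise distance, order-insensitively:
    rows are put in a canonical (lexicographic) order before subsampling."""
    X = np.asarray(X, dtype=float)
    order = np.lexsort(X.T[::-1])
    Xs = X[order]
    if Xs.shape[0] > max_rows:
        pick = np.linspace(0, Xs.shape[0] - 1, max_rows).round().astype(int)
        Xs = Xs[pick]
    sq = np.sum(Xs**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (Xs @ Xs.T), 0.0)
    med = float(np.median(np.sqrt(d2[np.triu_indices(len(Xs), k=1)])))
    if med <= 0:
        return 1.0 / X.shape[1]
    return 1.0 / (2.0 * med**2)


def make_classifier(spec: ClassifierSpec, X_train: np.ndarray):
    """Instantiate the sklearn estimator for a ClassifierSpec.

    The SVM kernel width is resolved from the (standardized) training data
    by the median-distance heuristic unless given explicitly.
    """
    params = spec.param_dict
    if spec.algorithm == "svm":
        from sklearn.svm import SVC
        gamma = params.pop("gamma", None)
        if gamma is None:
            gamma = _median_heuristic_gamma(X_train)
        return SVC(C=params.pop("C", 1.0), kernel="rbf", gamma=gamma,
                   random_state=spec.seed, **params)
    if spec.algorithm == "knn":
        from sklearn.neighbors import KNeighborsClassifier
        return KNeighborsClassifier(n_neighbors=params.pop("n_neighbors", 5), **params)
    if spec.algorithm == "lda":
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        return LinearDiscriminantAnalysis(**params)
    if spec.algorithm == "mlp":
        from sklearn.neural_network import MLPClassifier
        return MLPClassifier(hidden_layer_sizes=params.pop("hidden_layer_sizes", (100,)),
                             max_iter=params.pop("max_iter", 300),
                             random_state=spec.seed, **params)
    if spec.algorithm == "lgbm":
        import lightgbm
        return lightgbm.LGBMClassifier(random_state=spec.seed, verbosity=-1, **params)
    if spec.algorithm == "xgboost":
        import xgboost
        return xgboost.XGBClassifier(random_state=spec.seed, **params)
    raise ValueError(f"unknown algorithm {spec.algorithm!r}")


def _rows_for(features: pd.DataFrame, membership: Sequence[Triple]) -> pd.DataFrame:
    idx = pd.MultiIndex.from_frame(features[["session", "gesture", "trial"]])
    mask = idx.isin(membership)
    return features.loc[mask]


def train_predict(
    assembly: DatasetAssembly,
    features: pd.DataFrame,
    spec: ClassifierSpec,
) -> pd.DataFrame:
    """Train on the assembly's training rows, predict its test rows.

    Returns the test metadata plus ``y_true`` (gesture) and raw ``y_pred``.
    Deterministic given (features, spec); insensitive to training-row order.
    """
    feature_cols = [c for c in features.columns if c not in META_COLUMNS]
    train_df = _rows_for(features, assembly.train)
    test_df = _rows_for(features, assembly.test)
    if len(train_df) == 0 or len(test_df) == 0:
        raise ValueError("assembly memberships resolve to empty row sets")
    y_train = train_df["gesture"].to_numpy()
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    scaler = Standardizer()
    X_train = scaler.fit_transform(train_df[feature_cols].to_numpy())
    X_test = scaler.transform(test_df[feature_cols].to_numpy())
    clf = make_classifier(spec, X_train)
    clf.fit(X_train, y_train)
    out = test_df[list(META_COLUMNS)].copy()
    out["y_true"] = test_df["gesture"].to_numpy()
    out["y_pred"] = clf.predict(X_test)
    return out


def mode_postprocess(predictions: Sequence, group: int = 3) -> np.ndarray:
    """Causal mode vote over the last ``group`` raw predictions.

    Window clipped at the sequence start; ties go to the most recent raw
    prediction among the tied values.  Apply within one trial's stream.
    """
    if group < 1 or group % 2 == 0:
        raise ValueError("group must be odd and >= 1")
    preds = np.asarray(predictions)
    out = preds.copy()
    for i in range(len(preds)):
        window = preds[max(0, i - group + 1): i + 1]
        values, counts = np.unique(window, return_counts=True)
        best = counts.max()
        tied = set(values[counts == best])
        # most recent raw prediction among tied values
        for v in window[::-1]:
            if v in tied:
                out[i] = v
                break
    return out


def accuracy(predicted: Sequence, true: Sequence) -> float:
    """Percentage of correctly classified samples."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("length mismatch")
    if predicted.size == 0:
        raise ValueError("empty input")
    return 100.0 * float(np.mean(predicted == true))


def _postprocess_by_trial(pred_df: pd.DataFrame, group: int = 3) -> pd.DataFrame:
    out = pred_df.copy()
    for _, idx in pred_df.groupby(["session", "gesture", "trial"], sort=True).groups.items():
        sub = pred_df.loc[idx].sort_values("frame")
        out.loc[sub.index, "y_pred"] = mode_postprocess(sub["y_pred"].to_numpy(), group)
    return out


def evaluate_assembly(
    assembly: DatasetAssembly,
    features: pd.DataFrame,
    spec: ClassifierSpec,
    group: int = 3,
) -> float:
    """Accuracy (%) of one dataset cell after mode post-processing."""
    preds = train_predict(assembly, features, spec)
    preds = _postprocess_by_trial(preds, group)
    return accuracy(preds["y_pred"], preds["y_true"])


@dataclass
class EvalTable:
    """Accuracy per (variant, test session, n_calib) plus derived summaries."""

    cells: pd.DataFrame  # columns: variant, test_session, n_calib, accuracy

    def summary(self) -> pd.DataFrame:
        """Mean accuracy over test sessions, variants x n_calib."""
        return self.cells.pivot_table(index="variant", columns="n_calib",
                                      values="accuracy", aggfunc="mean")

    def variant_averages(self) -> pd.Series:
        return self.summary().mean(axis=1)

    def improvements(self) -> pd.Series:
        """Cumulative-dataset average minus the baseline accuracy, per
        n_calib, with the overall average under key 'average'."""
        s = self.summary()
        baseline = float(s.loc["baseline"].iloc[0])
        cumulative = s.loc["cumulative"]
        imp = cumulative - baseline
        imp.loc["average"] = float(cumulative.mean() - baseline)
        return imp


def improvement_from_accuracies(baseline: float, cumulative: Sequence[float]) -> Dict:
    """Improvement row from a baseline accuracy and the cumulative-dataset
    accuracies at increasing calibration-trial counts (all in %)."""
    cumulative = [float(c) for c in cumulative]
    return {
        "per_n_calib": [c - baseline for c in cumulative],
        "average": float(np.mean(cumulative)) - baseline,
    }


def run_cross_session_table(
    features: pd.DataFrame,
    protocol: ProtocolSpec,
    spec: ClassifierSpec,
    gestures: Sequence[int],
    n_calib_range: Sequence[int] = (1, 2, 3, 4, 5),
    variants: Sequence[str] = VARIANTS,
    group: int = 3,
) -> EvalTable:
    """Evaluate every variant x test session x n_calib cell.

    The baseline cell is independent of n_calib, so it is computed once
    per test session and replicated across the n_calib columns.
    """
    records = []
    for test_session in protocol.calib_sessions:
        baseline_acc = None
        for variant in variants:
            for n_calib in n_calib_range:
                if variant == "baseline" and baseline_acc is not None:
                    acc = baseline_acc
                else:
                    assembly = assemble_dataset(protocol, variant, test_session,
                                                n_calib, gestures)
                    acc = evaluate_assembly(assembly, features, spec, group)
                    if variant == "baseline":
                        baseline_acc = acc
                records.append({"variant": variant, "test_session": test_session,
                                "n_calib": n_calib, "accuracy": acc})
    return EvalTable(cells=pd.DataFrame.from_records(records))


def run_training_grid(
    features: pd.DataFrame,
    cells: Sequence[GridCell],
    test_membership: Sequence[Triple],
    spec: ClassifierSpec,
    group: int = 3,
) -> pd.DataFrame:
    """Accuracy for every (n_sessions, n_trials) training set of the grid."""
    records = []
    for cell in cells:
        assembly = DatasetAssembly(variant="baseline", test_session=test_membership[0][0],
                                   n_calib=1, train=cell.train, test=tuple(test_membership))
        acc = evaluate_assembly(assembly, features, spec, group)
        records.append({"n_sessions": cell.n_sessions, "n_trials": cell.n_trials,
                        "accuracy": acc})
    return pd.DataFrame.from_records(records)


def average_accuracy_curves(grid: pd.DataFrame) -> Tuple[pd.Series, pd.Series]:
    """Marginal average-accuracy curves from a complete grid.

    Returns (AA vs n_trials, AA vs n_sessions): each point averages the
    accuracy over the other grid coordinate.
    """
    pivot = grid.pivot(index="n_sessions", columns="n_trials", values="accuracy")
    if pivot.isna().any().any():
        raise ValueError("grid is incomplete")
    return pivot.mean(axis=0), pivot.mean(axis=1)


@dataclass(frozen=True)
class CurveFit:
    """Least-squares fit of y = slope*ln(x) + intercept."""

    slope: float
    intercept: float
    r_squared: float


def fit_log_curve(x: Sequence[float], y: Sequence[float]) -> CurveFit:
    """OLS of y on ln(x); R^2 = 1 - SSres/SStot (1 when y is constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct x values")
    if np.any(x < 1):
        raise ValueError("fit defined for x >= 1")
    lx = np.log(x)
    slope, intercept = np.polyfit(lx, y, 1)
    resid = y - (slope * lx + intercept)
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sstot == 0 else 1.0 - float(np.sum(resid**2)) / sstot
    return CurveFit(slope=float(slope), intercept=float(intercept), r_squared=r2)


def compare_classifiers(
    features: pd.DataFrame,
    protocol: ProtocolSpec,
    gestures: Sequence[int],
    algorithms: Sequence[str] = ("knn", "lda", "svm"),
    seed: int = 0,
    group: int = 3,
) -> pd.DataFrame:
    """Classifier comparison on the baseline dataset (mean over test sessions)."""
    records = []
    for algorithm in algorithms:
        spec = ClassifierSpec(algorithm=algorithm, seed=seed)
        accs = []
        for test_session in protocol.calib_sessions:
            assembly = assemble_dataset(protocol, "baseline", test_session, 1, gestures)
            accs.append(evaluate_assembly(assembly, features, spec, group))
        records.append({"algorithm": algorithm, "accuracy": float(np.mean(accs))})
    return pd.DataFrame.from_records(records)
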