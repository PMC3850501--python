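"""Support-vector-machine classification on panel-ratio features.

The SVM consumes the same gene-pair ratios the ratioscore panel selected,
encoded as log2(subject ratio / panel threshold) so that 0 marks the
ratioscore decision boundary and the features are invariant to per-subject
expression scaling. Training mirrors the study design: a stratified 60/40
train/validation split, hyperparameters chosen by L-fold cross-validated
accuracy within the 60%, final refit on the full 60%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .containers import ExpressionMatrix
from .metrics import EvalMetrics, compute_metrics
from .ratios import RatioPanel


@dataclass
class SvmConfig:
    train_frac: float = 0.6
    cv_folds: int = 10
    kernel: str = "rbf"
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if not self.c_grid or (self.kernel == "rbf" and not self.gamma_grid):
            raise ValueError("hyperparameter grids must be non-empty")
        if any(c <= 0 for c in self.c_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("hyperparameters must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class SvmFitReport:
    model: SVC = field(repr=False)
    config: SvmConfig
    best_params: dict
    train_ids: list[str]
    validation_ids: list[str]
    calls: pd.Series = field(repr=False)  # per-subject boolean prediction
    truth: pd.Series = field(repr=False)
    train_metrics: EvalMetrics = field(init=False)
    validation_metrics: EvalMetrics = field(init=False)
    total_metrics: EvalMetrics = field(init=False)

    def __post_init__(self) -> None:
        both = set(self.train_ids) & set(self.validation_ids)
        if both:
            raise ValueError(f"subjects in both splits: {sorted(both)}")
        self.train_metrics = compute_metrics(
            self.calls.loc[self.train_ids], self.truth.loc[self.train_ids]
        )
        self.validation_metrics = compute_metrics(
            self.calls.loc[self.validation_ids], self.truth.loc[self.validation_ids]
        )
        self.total_metrics = compute_metrics(self.calls, self.truth)


def build_ratio_features(panel: RatioPanel, expr: ExpressionMatrix) -> pd.DataFrame:
    """Subjects x panel-ratios matrix of log2(ratio value / threshold)."""
    if not panel.ratios:
        raise ValueError("empty panel")
    missing = {g for r in panel.ratios for g in r.pair} - set(expr.gene_ids)
    if missing:
        raise KeyError(f"panel genes absent from expression matrix: {sorted(missing)}")
    cols = {}
    for r in panel.ratios:
        vals = expr.levels[r.numerator_gene] / expr.levels[r.denominator_gene]
        cols[f"{r.numerator_gene}/{r.denominator_gene}"] = np.log2(vals / r.threshold)
    return pd.DataFrame(cols, index=expr.levels.index)


def _param_grid(config: SvmConfig) -> dict:
    grid = {"C": list(config.c_grid)}
    if config.kernel == "rbf":
        grid["gamma"] = list(config.gamma_grid)
    return grid


def train_svm(features: pd.DataFrame, labels, config: SvmConfig) -> SvmFitReport:
    """Stratified 60/40 split, L-fold CV grid search on the 60%, refit, report."""
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features))
    y = pd.Series(np.asarray(labels, dtype=bool), index=features.index)
    if y.nunique() < 2:
        raise ValueError("labels contain a single class")
    X_tr, X_val, y_tr, y_val = train_test_split(
        features, y,
        train_size=config.train_frac,
        stratify=y,
        random_state=config.seed,
    )
    if int(y_tr.sum()) < config.cv_folds or int((~y_tr).sum()) < config.cv_folds:
        raise ValueError(
            f"cv_folds={config.cv_folds} exceeds the size of a class in the training split"
        )
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    search = GridSearchCV(
        SVC(kernel=config.kernel),
        _param_grid(config),
        scoring="accuracy",
        cv=cv,
        n_jobs=1,
    )
    search.fit(X_tr.to_numpy(), y_tr.to_numpy())
    model = search.best_estimator_
    calls = pd.Series(
        model.predict(features.to_numpy()).astype(bool), index=features.index
    )
    return SvmFitReport(
        model=model,
        config=config,
        best_params=dict(search.best_params_),
        train_ids=list(X_tr.index),
        validation_ids=list(X_val.index),
        calls=calls,
        truth=y,
    )


def predict_svm(model: SVC, features) -> np.ndarray:
    """Binary call vector for a fitted model; deterministic."""
    X = features.to_numpy() if isinstance(features, pd.DataFrame) else np.asarray(features)
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature count {X.shape[1]} does not match training ({model.n_features_in_})"
        )
    return model.predict(X).astype(bool)


def save_svm(report: SvmFitReport, path: str | Path) -> None:
    """Serialize the fitted SVM and its report to a JSON text file."""
    m = report.model
    payload = {
        "kernel": m.kernel,
        "gamma": float(m._gamma) if m.kernel == "rbf" else None,
        "intercept": m.intercept_.tolist(),
        "dual_coef": m.dual_coef_.tolist(),
        "support_vectors": m.support_vectors_.tolist(),
        "classes": [bool(c) for c in m.classes_],
        "best_params": report.best_params,
        "config": {
            "train_frac": report.config.train_frac,
            "cv_folds": report.config.cv_folds,
            "kernel": report.config.kernel,
            "seed": report.config.seed,
        },
        "train_ids": report.train_ids,
        "validation_ids": report.validation_ids,
        "metrics": {
            "train": report.train_metrics.as_dict(),
            "validation": report.validation_metrics.as_dict(),
            "total": report.total_metrics.as_dict(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


class SvmPredictor:
    """Re-applies a serialized SVM decision function (rbf or linear kernel)."""

    def __init__(self, payload: dict):
        self.kernel = payload["kernel"]
        self.gamma = payload["gamma"]
        self.intercept = np.asarray(payload["intercept"], dtype=float)
        self.dual_coef = np.asarray(payload["dual_coef"], dtype=float)
        self.support_vectors = np.asarray(payload["support_vectors"], dtype=float)
        self.classes = payload["classes"]

    def decision_function(self, X) -> np.ndarray:
        X = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if self.kernel == "rbf":
            d2 = ((X[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
            K = np.exp(-self.gamma * d2)
        else:
            K = X @ self.support_vectors.T
        return K @ self.dual_coef[0] + self.intercept[0]

    def predict(self, X) -> np.ndarray:
        dec = self.decision_function(X)
        return np.where(dec > 0, self.classes[1], self.classes[0]).astype(bool)


def load_svm(path: str | Path) -> SvmPredictor:
    return SvmPredictor(json.loads(Path(path).read_text()))
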