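"""RBF-SVM baselines over handcrafted feature subsets.

These reproduce the classical comparison the CNN is benchmarked against:
an RBF-kernel support vector machine per feature subset (single features,
the 2-feature 2D and 3D sets, the 4-feature combination, the extended
panels), with hyperparameters chosen by inner cross-validated AUROC and
evaluation on a shared held-out split. Features must be z-scored with
statistics fitted on training rows only; S/G2 is the positive class and
ROC uses the decision-function margin (AUROC is rank-based, so no
probability calibration is needed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .features import zscore_apply, zscore_fit
from .metrics import accuracy_at, auroc

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (1e-3, 1e-2, 1e-1, 1.0, 10.0)


@dataclass(frozen=True)
class SvmExperiment:
    """One named SVM run over a feature subset."""

    name: str
    features: tuple[str, ...]
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_folds: int = 5
    outer_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("feature subset must be nonempty")
        if self.inner_folds < 2 or self.outer_folds < 2:
            raise ValueError("fold counts must be >= 2")


def fit_svm(X: np.ndarray, y: np.ndarray, exp: SvmExperiment):
    """Inner-CV grid search over (C, gamma) by AUROC, refit on all rows.

    ``X`` must already be z-scored. Returns (fitted SVC, best params dict).
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("cannot fit an SVM on single-class labels")
    cv = StratifiedKFold(exp.inner_folds, shuffle=True, random_state=exp.seed)
    search = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": list(exp.c_grid), "gamma": list(exp.gamma_grid)},
        scoring="roc_auc", cv=cv, refit=True)
    search.fit(np.asarray(X), y)
    return search.best_estimator_, dict(search.best_params_)


def score_svm(model: SVC, X: np.ndarray) -> np.ndarray:
    """Continuous scores oriented so higher = more S/G2-like (label 1)."""
    scores = model.decision_function(np.asarray(X))
    return scores if model.classes_[-1] == 1 else -scores


def nested_cv_auroc(features: pd.DataFrame, labels: np.ndarray,
                    exp: SvmExperiment) -> dict:
    """Outer-CV estimate: per outer fold, scale + grid-search on the
    training part only, score the held-out part. Returns mean and
    per-fold AUROCs."""
    labels = np.asarray(labels)
    outer = StratifiedKFold(exp.outer_folds, shuffle=True, random_state=exp.seed)
    cols = list(exp.features)
    aucs = []
    for train_idx, test_idx in outer.split(features, labels):
        stats = zscore_fit(features.iloc[train_idx], slice(None), columns=cols)
        Xtr = zscore_apply(features.iloc[train_idx], stats).to_numpy()
        Xte = zscore_apply(features.iloc[test_idx], stats).to_numpy()
        model, _ = fit_svm(Xtr, labels[train_idx], exp)
        aucs.append(auroc(labels[test_idx], score_svm(model, Xte)))
    return {"auroc_mean": float(np.mean(aucs)), "auroc_folds": aucs}


def run_feature_panel(features: pd.DataFrame, labels: np.ndarray,
                      panel: list[SvmExperiment], test_fraction: float = 0.3,
                      seed: int = 0) -> pd.DataFrame:
    """Run every experiment on one shared stratified held-out split.

    Scaling and hyperparameter selection see only the training rows.
    Returns one report row per experiment: AUROC, accuracy (margin > 0),
    and the selected hyperparameters.
    """
    labels = np.asarray(labels)
    missing = set(c for e in panel for c in e.features) - set(features.columns)
    if missing:
        raise KeyError(f"feature columns missing from table: {sorted(missing)}")
    idx = np.arange(len(features))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=labels)
    rows = []
    for exp in panel:
        cols = list(exp.features)
        stats = zscore_fit(features, train_idx, columns=cols)
        Xtr = zscore_apply(features.iloc[train_idx], stats).to_numpy()
        Xte = zscore_apply(features.iloc[test_idx], stats).to_numpy()
        model, params = fit_svm(Xtr, labels[train_idx], exp)
        scores = score_svm(model, Xte)
        rows.append({
            "name": exp.name, "n_features": len(cols),
            "auroc": auroc(labels[test_idx], scores),
            "accuracy": accuracy_at(labels[test_idx], scores, threshold=0.0),
            "C": params["C"], "gamma": params["gamma"],
        })
    return pd.DataFrame(rows)


# -------------------------------------------------------------------------
# model-object surface

@dataclass
class SVMResults:
    """Fitted-baseline results: held-out AUROC/accuracy + chosen params."""

    experiment: SvmExperiment
    model: SVC
    params: dict
    auroc: float
    accuracy: float
    n_train: int
    n_test: int

    def summary(self) -> str:
        lines = [
            f"SVM baseline: {self.experiment.name}",
            f"  features ({len(self.experiment.features)}): "
            + ", ".join(self.experiment.features),
            f"  selected C = {self.params['C']}, gamma = {self.params['gamma']}",
            f"  train n = {self.n_train}, test n = {self.n_test}",
            f"  held-out AUROC   = {self.auroc:.4f}",
            f"  held-out accuracy = {self.accuracy:.4f}  (margin > 0)",
        ]
        return "\n".join(lines)


class SVMBaseline:
    """statsmodels-style wrapper: build from a feature table, ``fit()``
    returns an :class:`SVMResults`."""

    def __init__(self, features: pd.DataFrame, labels,
                 experiment: SvmExperiment, test_fraction: float = 0.3) -> None:
        self.features = features
        self.labels = np.asarray(labels)
        self.experiment = experiment
        self.test_fraction = test_fraction

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str,
                       experiment: SvmExperiment, **kw) -> "SVMBaseline":
        return cls(df.drop(columns=[label_column]), df[label_column].to_numpy(),
                   experiment, **kw)

    def fit(self) -> SVMResults:
        exp = self.experiment
        idx = np.arange(len(self.features))
        train_idx, test_idx = train_test_split(
            idx, test_size=self.test_fraction, random_state=exp.seed,
            stratify=self.labels)
        stats = zscore_fit(self.features, train_idx, columns=list(exp.features))
        Xtr = zscore_apply(self.features.iloc[train_idx], stats).to_numpy()
        Xte = zscore_apply(self.features.iloc[test_idx], stats).to_numpy()
        model, params = fit_svm(Xtr, self.labels[train_idx], exp)
        scores = score_svm(model, Xte)
        return SVMResults(
            experiment=exp, model=model, params=params,
            auroc=auroc(self.labels[test_idx], scores),
            accuracy=accuracy_at(self.labels[test_idx], scores, threshold=0.0),
            n_train=len(train_idx), n_test=len(test_idx))


__all__ = ["SvmExperiment", "fit_svm", "score_svm", "nested_cv_auroc",
           "run_feature_panel", "SVMBaseline", "SVMResults",
           "DEFAULT_C_GRID", "DEFAULT_GAMMA_GRID"]
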