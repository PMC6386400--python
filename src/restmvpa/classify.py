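"""Classifier construction: ELM with L-grid search, and SVM baselines.

The SVM baselines (linear and RBF) use the canonical eight-point
logarithmic grids for the box constraint C and kernel scale gamma
(0.001 ... 10000), tuned by exhaustive inner-CV grid search with ties
broken toward the smallest C, then the smallest gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .elm import elm_grid_search, elm_train, elm_vote_predict
from .rng import substream

__all__ = ["SvmGridSpec", "FittedClassifier", "train_classifier",
           "svm_grid_search", "DEFAULT_C_GRID", "DEFAULT_GAMMA_GRID"]

DEFAULT_C_GRID = (0.001, 0.01, 0.1, 1, 10, 100, 1000, 10000)
DEFAULT_GAMMA_GRID = (0.001, 0.01, 0.1, 1, 10, 100, 1000, 10000)


@dataclass
class SvmGridSpec:
    C_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("grids must be non-empty")
        if min(self.C_grid) <= 0 or min(self.gamma_grid) <= 0:
            raise ValueError("grid values must be positive")


@dataclass
class FittedClassifier:
    """A trained model plus everything needed to predict and log the fit."""

    kind: str
    predict_fn: object
    params: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted labels in {0, 1}."""
        return np.asarray(self.predict_fn(X), int)


def svm_grid_search(X: np.ndarray, y: np.ndarray, spec: SvmGridSpec,
                    kernel: str = "rbf", inner_cv_folds: int = 5,
                    seed: int = 0) -> tuple[SVC, dict]:
    """Exhaustive (C, gamma) grid search by stratified inner-CV accuracy."""
    X = np.asarray(X, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    y = np.asarray(y, int)
    n_folds = min(inner_cv_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        raise ValueError("too few samples per class for inner CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    gamma_grid = spec.gamma_grid if kernel == "rbf" else (None,)
    best = None  # (acc, C, gamma)
    for C in sorted(spec.C_grid):
        for gamma in (sorted(gamma_grid) if kernel == "rbf" else gamma_grid):
            correct = 0
            for train, test in splits:
                svm = SVC(kernel=kernel, C=C,
                          **({"gamma": gamma} if gamma is not None else {}))
                svm.fit(X[train], y[train])
                correct += int((svm.predict(X[test]) == y[test]).sum())
            acc = correct / len(y)
            if best is None or acc > best[0]:
                best = (acc, C, gamma)
    acc, C, gamma = best
    final = SVC(kernel=kernel, C=C,
                **({"gamma": gamma} if gamma is not None else {}))
    final.fit(X, y)
    return final, {"C": C, "gamma": gamma, "cv_accuracy": acc, "kernel": kernel}


def train_classifier(X: np.ndarray, y: np.ndarray, kind: str,
                     elm_l_grid=range(1, 401), elm_repeats: int = 100,
                     inner_cv_folds: int = 5, seed: int = 0,
                     svm_spec: SvmGridSpec | None = None) -> FittedClassifier:
    """Fit the configured classifier on training data with inner-CV tuning.

    For the ELM the selected L is refit as an ensemble of ``elm_repeats``
    seeded initialisations whose majority vote gives test predictions.
    """
    y = np.asarray(y, int)
    if kind == "elm":
        best_L, cv_acc = elm_grid_search(
            X, y, L_grid=elm_l_grid, n_repeats=elm_repeats,
            inner_cv_folds=inner_cv_folds, seed=seed,
        )
        y_pm = np.where(y > 0, 1, -1)
        models = [
            elm_train(X, y_pm, best_L,
                      seed=int(substream(seed, f"elm-final-{r}").integers(2**31 - 1)))
            for r in range(max(1, elm_repeats))
        ]
        return FittedClassifier(
            kind="elm",
            predict_fn=lambda Xt: (elm_vote_predict(models, Xt) > 0).astype(int),
            params={"L": best_L, "cv_accuracy": cv_acc,
                    "n_models": len(models)},
        )
    if kind in ("svm_linear", "svm_rbf"):
        kernel = "linear" if kind == "svm_linear" else "rbf"
        model, params = svm_grid_search(
            X, y, svm_spec or SvmGridSpec(), kernel=kernel,
            inner_cv_folds=inner_cv_folds, seed=seed,
        )
        return FittedClassifier(kind=kind, predict_fn=model.predict,
                                params=params)
    raise ValueError(f"unknown classifier {kind!r}")
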