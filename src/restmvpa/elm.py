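"""Extreme learning machine for binary classification.

A single-hidden-layer network whose input weights and biases are drawn
randomly (Uniform(-1, 1)) and never trained; with H = sigmoid(X W^T + b)
the output weights are the minimum-norm least-squares solution
beta = H^+ y of a single linear system (Moore-Penrose pseudoinverse; no
iterative optimisation).  Targets are coded -1/+1 and the decision is
sign(H beta) with sign(0) -> +1.

Because the hidden layer is random, the hidden-node count L is selected by
a grid search in which every L is evaluated over ``n_repeats`` seeded
initialisations and the inner-CV validation accuracy is averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .rng import substream

__all__ = ["ElmModel", "elm_train", "elm_predict", "elm_grid_search",
           "elm_vote_predict"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class ElmModel:
    input_weights: np.ndarray   # (L, d)
    biases: np.ndarray          # (L,)
    output_weights: np.ndarray  # (L,)
    L: int
    activation: str = "sigmoid"
    seed: int = 0

    def hidden(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.shape[1] != self.input_weights.shape[1]:
            raise ValueError(
                f"feature dim {X.shape[1]} != model dim "
                f"{self.input_weights.shape[1]}"
            )
        return _sigmoid(X @ self.input_weights.T + self.biases)


def elm_train(X: np.ndarray, y: np.ndarray, L: int, seed: int = 0,
              ridge: float = 0.0) -> ElmModel:
    """Train an ELM: random hidden layer, closed-form output solve.

    ``ridge`` adds an optional Tikhonov term for ill-conditioned hidden
    matrices; the default 0 is the pure pseudoinverse solve.
    """
    if L < 1:
        raise ValueError("need at least one hidden node")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.shape[0] < 2 or len(np.unique(y)) < 2:
        raise ValueError("need >= 2 samples with both labels present")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(L, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=L)
    H = _sigmoid(X @ W.T + b)
    if ridge > 0:
        beta = np.linalg.solve(H.T @ H + ridge * np.eye(L), H.T @ y)
    else:
        beta = np.linalg.pinv(H) @ y
    return ElmModel(input_weights=W, biases=b, output_weights=beta, L=L,
                    seed=seed)


def elm_predict(model: ElmModel, X: np.ndarray) -> np.ndarray:
    """Labels in {-1, +1} via sign(H beta); sign(0) -> +1."""
    scores = model.hidden(X) @ model.output_weights
    return np.where(scores >= 0, 1, -1)


def elm_vote_predict(models: list[ElmModel], X: np.ndarray) -> np.ndarray:
    """Majority vote over an ensemble of ELMs (ties -> +1)."""
    votes = np.sum([elm_predict(m, X) for m in models], axis=0)
    return np.where(votes >= 0, 1, -1)


def elm_grid_search(X: np.ndarray, y: np.ndarray,
                    L_grid=range(1, 401), n_repeats: int = 100,
                    inner_cv_folds: int = 5, seed: int = 0,
                    ) -> tuple[int, float]:
    """Select the hidden-node count maximising mean validation accuracy.

    For each L the inner-CV accuracy is averaged over ``n_repeats`` seeded
    random initialisations; ties go to the smallest L.
    """
    L_grid = sorted({int(L) for L in L_grid})
    if not L_grid:
        raise ValueError("empty L_grid")
    y = np.asarray(y)
    y_pm = np.where(y > 0, 1, -1)
    classes = np.asarray(y_pm > 0, int)
    n_folds = min(inner_cv_folds, int(np.bincount(classes).min()))
    if n_folds < 2:
        raise ValueError("too few samples per class for inner CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, classes))
    best_L, best_acc = None, -1.0
    for L in L_grid:
        correct = 0
        total = 0
        for rep in range(n_repeats):
            rep_seed = int(substream(seed, f"elm-L{L}-rep{rep}").integers(2**31 - 1))
            for train, test in splits:
                try:
                    model = elm_train(X[train], y_pm[train], L, seed=rep_seed)
                except ValueError:
                    continue
                correct += int((elm_predict(model, X[test]) == y_pm[test]).sum())
                total += len(test)
        acc = correct / total if total else 0.0
        if acc > best_acc:
            best_L, best_acc = L, acc
    return int(best_L), float(best_acc)
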