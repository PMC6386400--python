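"""Training-data-only feature reduction.

Stage one is univariate: a pooled-variance two-sample t map per measure,
thresholded at the exact Student quantile for the fold's degrees of
freedom, followed by Monte-Carlo cluster-extent correction (simulated
Gaussian-noise volumes smoothed to the analysis FWHM, as in AlphaSim).
Stage two is multivariate on the concatenated surviving features: linear
SVM recursive feature elimination (ranking by the squared weight,
eliminating the weakest each round) or an L1-penalised least-squares
(LASSO) path with the penalty chosen by cross-validated MSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io import MaskVolume
from .measures import FeatureMatrix
from .preprocess import fwhm_to_sigma_vox

logger = logging.getLogger("restmvpa")

__all__ = [
    "TTestMap",
    "ClusterRule",
    "SelectionResult",
    "LassoFit",
    "critical_t",
    "two_sample_t_map",
    "cluster_extent_filter",
    "alphasim_min_cluster",
    "univariate_mask",
    "svm_rfe_rank",
    "rfe_select_k",
    "lasso_select",
    "Standardizer",
]


def critical_t(alpha: float, df: int) -> float:
    """Two-tailed Student-t critical value at level ``alpha``."""
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


@dataclass
class TTestMap:
    t: np.ndarray          # 3-D grid
    p: np.ndarray          # two-tailed p grid
    df: int
    alpha_voxel: float
    critical_t: float
    n_zero_variance: int = 0


@dataclass
class ClusterRule:
    alpha_voxel: float = 0.05
    alpha_cluster: float = 0.05
    min_cluster_voxels: int = 1
    connectivity: int = 26           # 6 | 18 | 26
    n_iter: int = 1000
    fwhm_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class SelectionResult:
    kept: np.ndarray                 # ordered feature indices
    ranking: np.ndarray              # per-feature rank (1 = best) or |coef|
    method: str                      # ttest | rfe | lasso
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kept = np.asarray(self.kept, int)
        if len(set(self.kept.tolist())) != len(self.kept):
            raise ValueError("duplicate kept indices")


@dataclass
class LassoFit:
    gamma0: float
    gamma: np.ndarray
    lam: float
    cv_mse_curve: list[tuple[float, float]]


def cluster_volume_mm3(n_voxels: int, voxel_size_mm) -> float:
    """Volume of an ``n_voxels`` cluster in cubic millimetres."""
    voxel_size_mm = np.broadcast_to(np.atleast_1d(voxel_size_mm), (3,))
    return float(n_voxels * np.prod(voxel_size_mm))


# ---------------------------------------------------------------------------
# Univariate stage


def two_sample_t_map(maps_group0: np.ndarray, maps_group1: np.ndarray,
                     mask: MaskVolume, alpha_voxel: float = 0.05) -> TTestMap:
    """Pooled-variance two-sample t per in-mask voxel.

    ``maps_groupX`` are (n_subjects, X, Y, Z) stacks.  Zero-pooled-variance
    voxels get t = 0, p = 1 and are counted in ``n_zero_variance``.
    """
    g0 = np.asarray(maps_group0, float)
    g1 = np.asarray(maps_group1, float)
    n0, n1 = g0.shape[0], g1.shape[0]
    if n0 < 2 or n1 < 2:
        raise ValueError("need n >= 2 per group")
    if g0.shape[1:] != g1.shape[1:] or g0.shape[1:] != mask.data.shape:
        raise ValueError("group map dims do not match")
    df = n0 + n1 - 2
    m = mask.data
    x0 = g0[:, m]
    x1 = g1[:, m]
    mean_diff = x1.mean(axis=0) - x0.mean(axis=0)
    ss0 = ((x0 - x0.mean(axis=0)) ** 2).sum(axis=0)
    ss1 = ((x1 - x1.mean(axis=0)) ** 2).sum(axis=0)
    pooled = (ss0 + ss1) / df
    se = np.sqrt(pooled * (1.0 / n0 + 1.0 / n1))
    zero = se == 0
    t_v = np.zeros_like(mean_diff)
    np.divide(mean_diff, se, out=t_v, where=~zero)
    p_v = 2.0 * stats.t.sf(np.abs(t_v), df)
    p_v[zero] = 1.0
    t = np.zeros(m.shape)
    p = np.ones(m.shape)
    t[m] = t_v
    p[m] = p_v
    return TTestMap(t=t, p=p, df=df, alpha_voxel=alpha_voxel,
                    critical_t=critical_t(alpha_voxel, df),
                    n_zero_variance=int(zero.sum()))


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def cluster_extent_filter(suprathreshold: np.ndarray | MaskVolume,
                          rule: ClusterRule) -> np.ndarray:
    """Drop connected components smaller than ``rule.min_cluster_voxels``."""
    binary = suprathreshold.data if isinstance(suprathreshold, MaskVolume) \
        else np.asarray(suprathreshold).astype(bool)
    labels, n = ndimage.label(binary, structure=_structure(rule.connectivity))
    if n == 0:
        return np.zeros_like(binary)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= rule.min_cluster_voxels
    keep[0] = False
    return keep[labels]


def alphasim_min_cluster(mask: MaskVolume, fwhm_mm: float, voxel_size_mm,
                         alpha_voxel: float = 0.05, alpha_cluster: float = 0.05,
                         n_iter: int = 1000, seed: int = 0,
                         connectivity: int = 26) -> int:
    """Monte-Carlo minimum cluster extent at family-wise level alpha_cluster.

    Each iteration draws a Gaussian-noise volume, smooths it to ``fwhm_mm``,
    re-standardises over the mask, thresholds two-tailed at ``alpha_voxel``
    and records the largest supra-threshold cluster; the returned size is
    the smallest s with P(max cluster >= s) <= alpha_cluster.
    """
    if alpha_cluster < 1.0 / n_iter:
        raise ValueError(
            f"alpha_cluster={alpha_cluster} unresolvable with n_iter={n_iter}"
        )
    rng = np.random.default_rng(seed)
    z_crit = stats.norm.ppf(1.0 - alpha_voxel / 2.0)
    structure = _structure(connectivity)
    m = mask.data
    sigma = fwhm_to_sigma_vox(fwhm_mm, voxel_size_mm) if fwhm_mm > 0 else None
    max_sizes = np.zeros(n_iter, int)
    for i in range(n_iter):
        vol = rng.standard_normal(m.shape)
        if sigma is not None:
            vol = ndimage.gaussian_filter(vol, sigma=np.broadcast_to(sigma, (3,)))
        vals = vol[m]
        vol_z = np.zeros_like(vol)
        vol_z[m] = (vals - vals.mean()) / vals.std()
        supra = (np.abs(vol_z) > z_crit) & m
        labels, n = ndimage.label(supra, structure=structure)
        if n:
            max_sizes[i] = np.bincount(labels.ravel())[1:].max()
    # P(max >= s) for s = 1.. ; smallest s meeting the level
    for s in range(1, int(max_sizes.max()) + 2):
        if np.mean(max_sizes >= s) <= alpha_cluster:
            return s
    return int(max_sizes.max()) + 1


def univariate_mask(tmaps: dict[str, TTestMap], mask: MaskVolume,
                    rule: ClusterRule | None = None,
                    ) -> tuple[dict[str, MaskVolume], dict]:
    """Threshold each measure's |t| map and apply cluster-extent filtering.

    Returns per-measure selection masks (each measure keeps its own
    surviving voxels; concatenation is their disjoint union across
    measures) plus a report of per-measure voxel counts.  Raises when every
    measure's mask is empty.
    """
    out: dict[str, MaskVolume] = {}
    report: dict[str, int] = {}
    for name, tm in tmaps.items():
        supra = (np.abs(tm.t) >= tm.critical_t) & mask.data
        if rule is not None and rule.min_cluster_voxels > 1:
            supra = cluster_extent_filter(supra, rule)
        report[name] = int(supra.sum())
        if supra.any():
            out[name] = MaskVolume(data=supra, affine=mask.affine)
    if not out:
        raise ValueError(
            "univariate selection kept no voxel in any measure; "
            "consider a larger alpha_voxel or weaker cluster rule"
        )
    return out, report


# ---------------------------------------------------------------------------
# Standardisation (training statistics only)


@dataclass
class Standardizer:
    """Column z-scoring with statistics frozen from the training rows."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


# ---------------------------------------------------------------------------
# SVM-RFE


def svm_rfe_rank(X: np.ndarray, y: np.ndarray, step: int | None = None,
                 C: float = 1.0) -> SelectionResult:
    """Recursive feature elimination with a linear SVM.

    Repeatedly fits the SVM, scores features by the squared weight w_j^2 and
    removes the weakest ``step`` features (default: 1 for <= 500 features,
    else 10% per round) until none remain.  ``ranking[j]`` is 1 for the
    last-surviving (most informative) feature; ties in w_j^2 are broken by
    eliminating the lower column index first.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    q = X.shape[1]
    remaining = list(range(q))
    elimination_order: list[int] = []
    while remaining:
        if len(remaining) == 1:
            elimination_order.append(remaining.pop())
            break
        this_step = step if step is not None else (
            1 if len(remaining) <= 500 else max(1, len(remaining) // 10)
        )
        this_step = min(this_step, len(remaining) - 1)
        svm = SVC(kernel="linear", C=C)
        try:
            svm.fit(X[:, remaining], y)
        except Exception as exc:  # pragma: no cover - converge guard
            raise RuntimeError(
                f"SVM failed with {len(remaining)} features remaining: {exc}"
            ) from exc
        crit = np.asarray(svm.coef_).ravel() ** 2
        # stable argsort: among equal criteria the lower column index goes first
        drop_local = np.argsort(crit, kind="stable")[:this_step]
        for loc in sorted(drop_local.tolist()):
            elimination_order.append(remaining[loc])
        remaining = [f for k, f in enumerate(remaining) if k not in set(drop_local.tolist())]
    ranking = np.empty(q, int)
    for pos, feat in enumerate(elimination_order):
        ranking[feat] = q - pos  # last eliminated -> rank 1
    return SelectionResult(
        kept=np.argsort(ranking, kind="stable"),
        ranking=ranking,
        method="rfe",
        params={"C": C, "step": step},
    )


def _inner_cv_accuracy(X: np.ndarray, y: np.ndarray, n_folds: int, seed: int,
                       C: float = 1.0) -> float:
    """Stratified k-fold accuracy of a linear SVM (model-selection metric)."""
    n_folds = min(n_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        raise ValueError("too few samples per class for inner CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    correct = 0
    for train, test in skf.split(X, y):
        svm = SVC(kernel="linear", C=C)
        svm.fit(X[train], y[train])
        correct += int((svm.predict(X[test]) == y[test]).sum())
    return correct / len(y)


def rfe_select_k(X: np.ndarray, y: np.ndarray, ranking: SelectionResult,
                 k_grid, inner_cv_folds: int = 5, seed: int = 0,
                 ) -> SelectionResult:
    """Choose how many top-ranked features to keep by inner-CV accuracy.

    Evaluates each k in ``k_grid`` on the training data only; ties go to
    the smallest k.
    """
    k_grid = sorted({int(k) for k in np.atleast_1d(list(k_grid))})
    if not k_grid:
        raise ValueError("empty k_grid")
    q = X.shape[1]
    order = np.argsort(ranking.ranking, kind="stable")
    best_k, best_acc = None, -1.0
    accs = {}
    for k in k_grid:
        k_eff = min(k, q)
        acc = _inner_cv_accuracy(X[:, order[:k_eff]], y, inner_cv_folds, seed)
        accs[k] = acc
        if acc > best_acc:
            best_k, best_acc = k_eff, acc
    kept = order[:best_k]
    return SelectionResult(
        kept=kept,
        ranking=ranking.ranking,
        method="rfe",
        params={"k": int(best_k), "cv_accuracy": best_acc,
                "k_grid": k_grid, "grid_accuracies": accs},
    )


# ---------------------------------------------------------------------------
# LASSO


def lasso_lambda_max(X: np.ndarray, u: np.ndarray) -> float:
    """Smallest penalty at which all LASSO coefficients are zero.

    For the objective (1/2n) ||u - g0 - X g||^2 + lam * ||g||_1 this is
    max_j |x_j . (u - mean(u))| / n on centred columns.
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    uc = u - u.mean()
    return float(np.max(np.abs(Xc.T @ uc)) / n)


def lasso_select(X: np.ndarray, y: np.ndarray, lambda_grid=None,
                 inner_cv_folds: int = 5, seed: int = 0, n_lambda: int = 50,
                 ) -> tuple[LassoFit, SelectionResult]:
    """L1-penalised least squares on standardised features.

    Labels are regressed as a continuous response; the penalty is chosen to
    minimise cross-validated MSE over a log-spaced grid from lambda_max
    down, and the kept features are those with nonzero coefficients at the
    optimum.  Standardisation uses training statistics computed internally.
    """
    X = np.asarray(X, float)
    u = np.asarray(y, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite inputs")
    scaler = Standardizer.fit(X)
    Xs = scaler.transform(X)
    lam_max = lasso_lambda_max(Xs, u)
    if lambda_grid is None:
        lambda_grid = np.geomspace(lam_max, max(lam_max * 1e-3, 1e-12), n_lambda)
    lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]

    y_int = np.asarray(y, int)
    n_folds = min(inner_cv_folds, int(np.bincount(y_int).min()))
    skf = StratifiedKFold(n_splits=max(2, n_folds), shuffle=True, random_state=seed)
    splits = list(skf.split(Xs, y_int))
    curve = []
    for lam in lambda_grid:
        mse = 0.0
        for train, test in splits:
            fold_scaler = Standardizer.fit(X[train])
            model = _fit_lasso(fold_scaler.transform(X[train]), u[train], lam)
            pred = fold_scaler.transform(X[test]) @ model[1] + model[0]
            mse += float(((pred - u[test]) ** 2).sum())
        curve.append((float(lam), mse / len(u)))
    best_lam = min(curve, key=lambda t: (t[1], -t[0]))[0]
    gamma0, gamma = _fit_lasso(Xs, u, best_lam)
    kept = np.flatnonzero(gamma != 0)
    fit = LassoFit(gamma0=gamma0, gamma=gamma, lam=best_lam, cv_mse_curve=curve)
    return fit, SelectionResult(
        kept=kept, ranking=np.abs(gamma), method="lasso",
        params={"lambda": best_lam, "n_kept": int(kept.size)},
    )


def _fit_lasso(Xs: np.ndarray, u: np.ndarray, lam: float,
               ) -> tuple[float, np.ndarray]:
    """Coordinate-descent solve of the (1/2n) MSE + lam*L1 objective."""
    if lam <= 0:
        Xc = Xs - Xs.mean(axis=0)
        coef, *_ = np.linalg.lstsq(Xc, u - u.mean(), rcond=None)
        g0 = float(u.mean() - Xs.mean(axis=0) @ coef)
        return g0, coef
    model = Lasso(alpha=lam, fit_intercept=True, max_iter=50_000, tol=1e-8)
    model.fit(Xs, u)
    return float(model.intercept_), np.asarray(model.coef_)
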