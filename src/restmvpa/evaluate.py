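"""Outer cross-validation, performance metrics and permutation testing.

Per outer fold the full supervised chain — univariate t masking with
cluster-extent correction, optional SVM-RFE or LASSO reduction, classifier
tuning — is refit on the training rows only; the held-out rows are only
ever transformed and predicted.  Measure maps themselves are per-subject,
unsupervised quantities and are computed once for the whole cohort before
splitting.

Six metrics are reported per fold and as mean +/- SD across folds:
ACC = (TP+TN)/total, SEN = TP/(TP+FN), SPEC = TN/(TN+FP),
BAC = (SEN+SPEC)/2, PPV = TP/(TP+FP), NPV = TN/(TN+FN), all as
percentages.  Zero-denominator metrics are flagged undefined and excluded
from fold averages (with the exclusion count reported) rather than
propagated as NaN.  Pooled-count metrics over all test decisions are
reported alongside the fold averages.

Significance is assessed by permuting the pooled test labels against the
fixed predictions (the pipeline is not rerun), with
p = (1 + #{null >= observed}) / (1 + P).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import train_classifier
from .io import MaskVolume, RunConfig
from .measures import FeatureMatrix, MEASURE_ORDER
from .rng import substream, substream_seed
from .selection import (ClusterRule, Standardizer, alphasim_min_cluster,
                        lasso_select, rfe_select_k, svm_rfe_rank,
                        two_sample_t_map, univariate_mask)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "PermutationResult",
    "confusion_metrics",
    "make_folds",
    "cross_validate",
    "permutation_test",
]

METRIC_NAMES = ("ACC", "SEN", "SPEC", "BAC", "PPV", "NPV")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, int)
        y_pred = np.asarray(y_pred, int)
        return cls(
            TP=int(((y_true == 1) & (y_pred == 1)).sum()),
            TN=int(((y_true == 0) & (y_pred == 0)).sum()),
            FP=int(((y_true == 0) & (y_pred == 1)).sum()),
            FN=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """The six metrics as percentages; zero-denominator entries are None."""
    if counts.total == 0:
        raise ValueError("no test decisions")

    def ratio(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    acc = ratio(counts.TP + counts.TN, counts.total)
    sen = ratio(counts.TP, counts.TP + counts.FN)
    spec = ratio(counts.TN, counts.TN + counts.FP)
    bac = (sen + spec) / 2.0 if sen is not None and spec is not None else None
    return {
        "ACC": acc,
        "SEN": sen,
        "SPEC": spec,
        "BAC": bac,
        "PPV": ratio(counts.TP, counts.TP + counts.FP),
        "NPV": ratio(counts.TN, counts.TN + counts.FN),
    }


@dataclass
class MetricsReport:
    per_fold: list[dict]                 # metric dicts (may contain None)
    mean: dict[str, float | None]
    sd: dict[str, float | None]
    pooled: dict[str, float | None]      # metrics on pooled confusion counts
    n_undefined: dict[str, int]
    fold_artifacts: list[dict] = field(default_factory=list)

    @classmethod
    def from_folds(cls, fold_counts: list[ConfusionCounts],
                   fold_artifacts: list[dict] | None = None) -> "MetricsReport":
        per_fold = [confusion_metrics(c) for c in fold_counts]
        mean, sd, n_undef = {}, {}, {}
        for name in METRIC_NAMES:
            vals = [m[name] for m in per_fold if m[name] is not None]
            n_undef[name] = len(per_fold) - len(vals)
            mean[name] = float(np.mean(vals)) if vals else None
            sd[name] = float(np.std(vals)) if vals else None
        pooled_counts = ConfusionCounts(
            TP=sum(c.TP for c in fold_counts),
            TN=sum(c.TN for c in fold_counts),
            FP=sum(c.FP for c in fold_counts),
            FN=sum(c.FN for c in fold_counts),
        )
        return cls(per_fold=per_fold, mean=mean, sd=sd,
                   pooled=confusion_metrics(pooled_counts),
                   n_undefined=n_undef,
                   fold_artifacts=fold_artifacts or [])


@dataclass
class PermutationResult:
    observed_acc: float
    null_accs: np.ndarray
    p_value: float
    P: int
    seed: int


# ---------------------------------------------------------------------------
# Fold construction


def make_folds(labels, kind: str = "loo", k: int = 10, seed: int = 0,
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train_idx, test_idx) pairs: leave-one-out or stratified k-fold."""
    labels = np.asarray(labels, int)
    n = len(labels)
    if kind == "loo":
        return [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    if kind != "kfold":
        raise ValueError(f"unknown CV kind {kind!r}")
    if k < 2:
        raise ValueError("k must be >= 2")
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(n), labels)]


# ---------------------------------------------------------------------------
# Outer cross-validation


def _fold_feature_matrix(stacks: dict[str, np.ndarray],
                         sel_masks: dict[str, MaskVolume],
                         labels: np.ndarray) -> FeatureMatrix:
    fixed = [m for m in MEASURE_ORDER if m in sel_masks]
    rest = sorted(n for n in sel_masks if n not in MEASURE_ORDER)
    cols: list[tuple[str, int]] = []
    blocks = []
    n = len(labels)
    for name in fixed + rest:
        idx = sel_masks[name].indices()
        cols.extend((name, int(j)) for j in idx)
        blocks.append(stacks[name].reshape(n, -1)[:, idx])
    return FeatureMatrix(values=np.concatenate(blocks, axis=1),
                         columns=cols, labels=labels)


def cross_validate(stacks: dict[str, np.ndarray], labels, mask: MaskVolume,
                   config: RunConfig) -> MetricsReport:
    """Run the outer CV loop over precomputed measure-map stacks.

    ``stacks`` maps measure name to an (n_subjects, X, Y, Z) array in
    manifest order.  Every supervised stage sees training rows only.
    """
    labels = np.asarray(labels, int)
    if min(np.bincount(labels, minlength=2)) < 2:
        raise ValueError("need at least 2 subjects per class")
    folds = make_folds(labels, kind=config.cv_kind,
                       k=config.cv_k or 10,
                       seed=substream_seed(config.rng_seed, "cv-split"))
    voxel_mm = np.linalg.norm(mask.affine[:3, :3], axis=0)

    if config.min_cluster_voxels is not None:
        min_cluster = config.min_cluster_voxels
    else:
        # depends only on mask/fwhm/alphas -> identical across folds
        min_cluster = alphasim_min_cluster(
            mask, config.fwhm_mm, voxel_mm,
            alpha_voxel=config.alpha_voxel,
            alpha_cluster=config.alpha_cluster,
            n_iter=config.alphasim_iters,
            seed=substream_seed(config.rng_seed, "alphasim"),
            connectivity=config.cluster_connectivity,
        )
    rule = ClusterRule(alpha_voxel=config.alpha_voxel,
                       alpha_cluster=config.alpha_cluster,
                       min_cluster_voxels=min_cluster,
                       connectivity=config.cluster_connectivity,
                       n_iter=config.alphasim_iters,
                       fwhm_mm=config.fwhm_mm)

    counts, artifacts = [], []
    for f, (train, test) in enumerate(folds):
        y_train = labels[train]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"fold {f}: a class is absent from training data")
        tmaps = {
            name: two_sample_t_map(stack[train][y_train == 0],
                                   stack[train][y_train == 1],
                                   mask, alpha_voxel=config.alpha_voxel)
            for name, stack in stacks.items()
        }
        sel_masks, report = univariate_mask(tmaps, mask, rule)
        fm = _fold_feature_matrix(stacks, sel_masks, labels)
        scaler = Standardizer.fit(fm.values[train])
        X_train = scaler.transform(fm.values[train])
        X_test = scaler.transform(fm.values[test])

        fold_seed = substream_seed(config.rng_seed, f"fold-{f}")
        sel_info: dict = {"univariate_voxels": report,
                          "min_cluster_voxels": min_cluster}
        if config.selector == "ttest+rfe":
            rank = svm_rfe_rank(X_train, y_train)
            sel = rfe_select_k(X_train, y_train, rank,
                               k_grid=config.rfe_k_grid,
                               inner_cv_folds=config.inner_cv_folds,
                               seed=fold_seed)
            keep = sel.kept
            sel_info.update(sel.params)
        elif config.selector == "ttest+lasso":
            _, sel = lasso_select(fm.values[train], y_train,
                                  inner_cv_folds=config.inner_cv_folds,
                                  seed=fold_seed,
                                  n_lambda=config.lasso_n_lambda)
            keep = sel.kept if sel.kept.size else np.arange(fm.q)
            sel_info.update(sel.params)
        else:
            keep = np.arange(fm.q)

        clf = train_classifier(
            X_train[:, keep], y_train, config.classifier,
            elm_l_grid=config.elm_l_grid, elm_repeats=config.elm_repeats,
            inner_cv_folds=config.inner_cv_folds, seed=fold_seed,
        )
        y_pred = clf.predict(X_test[:, keep])
        counts.append(ConfusionCounts.from_predictions(labels[test], y_pred))
        artifacts.append({
            "fold": f,
            "train_idx": train.tolist(),
            "test_idx": test.tolist(),
            "selection": sel_info,
            "kept_columns": [fm.columns[j] for j in np.asarray(keep)],
            "classifier": clf.params,
            "y_true": labels[test].tolist(),
            "y_pred": np.asarray(y_pred).tolist(),
        })
    return MetricsReport.from_folds(counts, artifacts)


# ---------------------------------------------------------------------------
# Permutation significance


def permutation_test(y_pred, y_true, P: int = 1000, seed: int = 0,
                     ) -> PermutationResult:
    """Permute pooled test labels against fixed predictions.

    The classification pipeline is *not* rerun; the null distribution is
    the accuracy of the fixed predictions against P random relabelings.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    y_pred = np.asarray(y_pred, int)
    y_true = np.asarray(y_true, int)
    observed = float(np.mean(y_pred == y_true))
    rng = substream(seed, "permutation")
    null = np.empty(P)
    for i in range(P):
        null[i] = np.mean(y_pred == rng.permutation(y_true))
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + P)
    return PermutationResult(observed_acc=observed, null_accs=null,
                             p_value=p, P=P, seed=seed)
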