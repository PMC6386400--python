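"""End-to-end experiment runner.

Stages: (a) per-subject measure extraction from a cohort manifest,
(b) outer CV split, (c) per-fold univariate + multivariate feature
selection, (d) classifier training, (e) held-out evaluation with a
permutation test — all reproducible bitwise from one master seed via
named substreams (cohort, alphasim, cv-split, fold-*, permutation).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import METRIC_NAMES, MetricsReport, cross_validate, permutation_test
from .io import (Bold4D, MaskVolume, RunConfig, read_bold4d, read_manifest,
                 read_mask, resolve_seed)
from .measures import (alff_falff_map, degree_centrality_map, reho_map,
                       seed_fc_map, DcParams)
from .preprocess import preprocess_bold, smooth_gaussian

__all__ = ["extract_measures", "run_experiment", "selected_voxel_recall",
           "write_metrics_csv"]


def extract_subject_measures(bold: Bold4D, mask: MaskVolume, config: RunConfig,
                             seeds: dict[str, MaskVolume] | None = None,
                             ) -> dict[str, np.ndarray]:
    """All configured measure maps for one subject.

    The cleanup chain runs first (detrend -> nuisance -> band-pass); ALFF
    and fALFF are computed on the detrended-but-unfiltered series (they
    need the full spectrum), everything else on the filtered series.
    Measure maps are computed on unsmoothed data, then each map is smoothed
    with the configured FWHM and z-scored across the mask for
    cross-subject comparability.
    """
    filtered, cleaned = preprocess_bold(
        bold, mask, band_hz=config.band_hz, drop_initial=config.drop_initial,
    )
    alff, falff = alff_falff_map(cleaned, mask, band_hz=config.band_hz)
    maps = {
        "ReHo": reho_map(filtered, mask, neighborhood=config.reho_neighborhood).data,
        "fALFF": falff.data,
        "ALFF": alff.data,
        "DC": degree_centrality_map(
            filtered, mask, DcParams(r_threshold=config.dc_r_threshold)
        ).data,
    }
    for name, seed_mask in (seeds or {}).items():
        maps[f"{name}-rsFC"] = seed_fc_map(filtered, mask, seed_mask, name=name).data

    voxel_mm = bold.voxel_size_mm
    out = {}
    for name, data in maps.items():
        if config.fwhm_mm > 0:
            data = smooth_gaussian(data, config.fwhm_mm, voxel_mm, mask=mask)
        vals = data[mask.data]
        sd = vals.std()
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
        zmap = np.zeros(mask.data.shape)
        zmap[mask.data] = z
        out[name] = zmap
    return out


def extract_measures(manifest: pd.DataFrame, mask: MaskVolume,
                     config: RunConfig) -> dict[str, np.ndarray]:
    """Measure-map stacks (n_subjects, X, Y, Z) in manifest order."""
    seeds = {
        s.name: resolve_seed(s, mask) for s in config.seeds
    }
    stacks: dict[str, list[np.ndarray]] = {}
    for _, row in manifest.iterrows():
        bold = read_bold4d(row["path"], subject_id=row["subject_id"],
                           tr_s=config.tr_s)
        maps = extract_subject_measures(bold, mask, config, seeds=seeds)
        for name, data in maps.items():
            stacks.setdefault(name, []).append(data)
    return {name: np.stack(arrs) for name, arrs in stacks.items()}


def write_metrics_csv(report: MetricsReport, perm_p: float, path) -> None:
    """Metrics summary mirroring the standard table columns, fixed format."""
    def fmt(v):
        return "NA" if v is None else f"{v:.4f}"

    lines = ["metric,mean,sd,pooled,n_undefined_folds"]
    for name in METRIC_NAMES:
        lines.append(",".join([
            name, fmt(report.mean[name]), fmt(report.sd[name]),
            fmt(report.pooled[name]), str(report.n_undefined[name]),
        ]))
    lines.append(f"permutation_p,{perm_p:.6f},,,")
    Path(path).write_text("\n".join(lines) + "\n")


def selected_voxel_recall(report: MetricsReport, truth_voxels) -> float:
    """Fraction of planted voxels referenced by any kept feature, any fold."""
    truth = set(int(v) for v in truth_voxels)
    if not truth:
        raise ValueError("empty ground-truth voxel set")
    found: set[int] = set()
    for art in report.fold_artifacts:
        found.update(int(v) for _, v in art["kept_columns"])
    return len(found & truth) / len(truth)


def run_experiment(config: RunConfig, manifest_path, mask_path, out_dir,
                   ) -> dict:
    """Run the full pipeline and write reports; returns the run record."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings = {}
    t0 = time.perf_counter()
    manifest = read_manifest(manifest_path)
    ref = read_bold4d(manifest.iloc[0]["path"], tr_s=config.tr_s)
    mask = read_mask(mask_path, reference=ref)

    stacks = extract_measures(manifest, mask, config)
    timings["extract_s"] = round(time.perf_counter() - t0, 3)

    t1 = time.perf_counter()
    labels = manifest["label"].to_numpy(int)
    report = cross_validate(stacks, labels, mask, config)
    timings["cv_s"] = round(time.perf_counter() - t1, 3)

    y_true = np.concatenate([a["y_true"] for a in report.fold_artifacts])
    y_pred = np.concatenate([a["y_pred"] for a in report.fold_artifacts])
    perm = permutation_test(y_pred, y_true, P=config.n_permutations,
                            seed=config.rng_seed)

    metrics_csv = out_dir / "metrics.csv"
    write_metrics_csv(report, perm.p_value, metrics_csv)
    record = {
        "config": config.to_dict(),
        "master_seed": config.rng_seed,
        "n_subjects": int(len(labels)),
        "measures": sorted(stacks),
        "timings_s": timings,
        "metrics_mean": report.mean,
        "metrics_sd": report.sd,
        "metrics_pooled": report.pooled,
        "permutation_p": perm.p_value,
        "folds": [
            {k: art[k] for k in
             ("fold", "train_idx", "test_idx", "selection", "classifier",
              "y_true", "y_pred")}
            for art in report.fold_artifacts
        ],
        "outputs": {"metrics_csv": str(metrics_csv)},
    }
    (out_dir / "run_record.json").write_text(
        json.dumps(record, indent=1, default=_json_default)
    )
    record["_report"] = report
    return record


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
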