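"""NIfTI and tabular I/O, seed resolution, and run configuration.

Volumes are exchanged as NIfTI-1 (gzipped accepted); cohorts as CSV
manifests with columns ``subject_id,label,path``; run configuration as a
YAML file mirroring :class:`RunConfig`.

Conventions: voxel indices are 0-based, mm coordinates follow the NIfTI
affine, and all neighborhood/cluster logic operates in voxel space.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("restmvpa")

__all__ = [
    "Bold4D",
    "MaskVolume",
    "SeedSpec",
    "RunConfig",
    "read_bold4d",
    "write_bold4d",
    "read_mask",
    "write_mask",
    "resolve_seed",
    "read_manifest",
    "write_manifest",
    "load_config",
]


@dataclass
class Bold4D:
    """A subject's 4-D BOLD grid with geometry and timing metadata."""

    data: np.ndarray          # (X, Y, Z, T) float array
    affine: np.ndarray        # 4x4 voxel -> mm map
    tr_s: float               # repetition time, seconds
    subject_id: str = ""
    voxel_size_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got {self.data.ndim}-D")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        if self.tr_s is None or self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.voxel_size_mm is None:
            self.voxel_size_mm = np.linalg.norm(self.affine[:3, :3], axis=0)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=np.float64)
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class MaskVolume:
    """A 3-D boolean mask sharing the geometry of the volumes it masks."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.data.any():
            raise ValueError("mask is empty (no true voxels)")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """Linear (C-order) indices of in-mask voxels."""
        return np.flatnonzero(self.data.ravel())


@dataclass
class SeedSpec:
    """A named seed region: an explicit mask, or a sphere around a point.

    Exactly one definition applies: ``mask`` (boolean volume), ``center_mm``
    with ``radius_mm``, or ``center_vox`` with ``radius_vox``.  Spheres
    include every voxel whose *center* lies within the radius.
    """

    name: str
    mask: np.ndarray | None = None
    center_mm: Sequence[float] | None = None
    radius_mm: float = 6.0
    center_vox: Sequence[float] | None = None
    radius_vox: float | None = None

    def __post_init__(self) -> None:
        n_defs = sum(
            x is not None for x in (self.mask, self.center_mm, self.center_vox)
        )
        if n_defs != 1:
            raise ValueError(
                f"seed {self.name!r}: exactly one of mask/center_mm/center_vox "
                f"must be given, got {n_defs}"
            )


def resolve_seed(spec: SeedSpec, mask: MaskVolume, affine: np.ndarray | None = None) -> MaskVolume:
    """Resolve a seed definition to an in-mask :class:`MaskVolume`.

    Sphere definitions include every voxel whose center lies within the
    radius of the given coordinate; the result is intersected with ``mask``.
    Raises ``ValueError`` when the resolved seed has no in-mask voxel.
    """
    if affine is None:
        affine = mask.affine
    shape = mask.data.shape
    if spec.mask is not None:
        seed = np.asarray(spec.mask).astype(bool)
        if seed.shape != shape:
            raise ValueError(
                f"seed {spec.name!r}: mask shape {seed.shape} != {shape}"
            )
    else:
        ii, jj, kk = np.meshgrid(
            np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
            indexing="ij",
        )
        vox = np.stack([ii, jj, kk], axis=-1).astype(float)
        if spec.center_mm is not None:
            centers_mm = vox @ affine[:3, :3].T + affine[:3, 3]
            d2 = np.sum((centers_mm - np.asarray(spec.center_mm, float)) ** 2, axis=-1)
            seed = d2 <= float(spec.radius_mm) ** 2 + 1e-9
        else:
            radius = spec.radius_vox if spec.radius_vox is not None else 0.0
            d2 = np.sum((vox - np.asarray(spec.center_vox, float)) ** 2, axis=-1)
            seed = d2 <= float(radius) ** 2 + 1e-9
    seed &= mask.data
    if not seed.any():
        raise ValueError(f"seed {spec.name!r} contains no in-mask voxel")
    return MaskVolume(data=seed, affine=mask.affine)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _tr_from_header(img: nib.Nifti1Image, path) -> float:
    zooms = img.header.get_zooms()
    if len(zooms) < 4:
        raise ValueError(f"{path}: header has no time-axis spacing (pixdim[4])")
    tr = float(zooms[3])
    if tr <= 0:
        raise ValueError(
            f"{path}: zero/absent TR in header field pixdim[4]; "
            "supply tr_s explicitly"
        )
    _, t_unit = img.header.get_xyzt_units()
    if t_unit == "msec":
        tr /= 1000.0
    elif t_unit == "usec":
        tr /= 1e6
    return tr


def read_bold4d(path, subject_id: str | None = None, tr_s: float | None = None) -> Bold4D:
    """Read a 4-D NIfTI file.

    TR is taken from the header time-axis spacing (``pixdim[4]``, converted
    to seconds from the header's time unit); an explicit ``tr_s`` argument
    overrides the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4-D image, got {data.ndim}-D")
    if tr_s is None:
        tr_s = _tr_from_header(img, path)
    return Bold4D(
        data=data.astype(np.float64),
        affine=img.affine,
        tr_s=tr_s,
        subject_id=subject_id or path.name.split(".")[0],
    )


def write_bold4d(bold: Bold4D, path) -> None:
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = bold.tr_s
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def read_mask(path, reference: Bold4D | None = None) -> MaskVolume:
    """Read a 3-D mask; nonzero voxels become True.

    With ``reference`` given, the spatial dims must match it.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D mask, got {data.ndim}-D")
    if reference is not None and data.shape != reference.shape[:3]:
        raise ValueError(
            f"{path}: mask dims {data.shape} do not match "
            f"reference {reference.shape[:3]}"
        )
    return MaskVolume(data=data != 0, affine=img.affine)


def write_mask(mask: MaskVolume, path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))


def write_map(data3d: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data3d, np.float32), affine), str(path))


# ---------------------------------------------------------------------------
# Cohort manifests


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "label", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Full run configuration; mirrors the YAML config schema."""

    band_hz: tuple[float, float] = (0.01, 0.08)
    fwhm_mm: float = 6.0
    drop_initial: int = 0
    alpha_voxel: float = 0.05
    alpha_cluster: float = 0.05
    min_cluster_voxels: int | None = None   # None -> Monte-Carlo estimate
    alphasim_iters: int = 1000
    cluster_connectivity: int = 26
    dc_r_threshold: float = 0.25
    reho_neighborhood: int = 27
    selector: str = "ttest"                 # ttest | ttest+rfe | ttest+lasso
    classifier: str = "elm"                 # elm | svm_linear | svm_rbf
    cv: str = "loo"                         # loo | kfold:<k>
    n_permutations: int = 1000
    rng_seed: int = 0
    tr_s: float | None = None               # overrides NIfTI header TR
    # selector / classifier knobs
    rfe_k_grid: tuple[int, ...] = (8, 16, 32, 64, 128, 256)
    lasso_n_lambda: int = 50
    elm_l_grid: tuple[int, ...] = tuple(range(1, 401))
    elm_repeats: int = 100
    inner_cv_folds: int = 5
    seeds: list = field(default_factory=list)  # list of SeedSpec

    def __post_init__(self) -> None:
        low, high = self.band_hz
        if not (0 < low < high):
            raise ValueError(f"invalid band {self.band_hz}")
        for name in ("alpha_voxel", "alpha_cluster"):
            a = getattr(self, name)
            if not (0 < a < 1):
                raise ValueError(f"{name}={a} not in (0,1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.selector not in ("ttest", "ttest+rfe", "ttest+lasso"):
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.classifier not in ("elm", "svm_linear", "svm_rbf"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if not (self.cv == "loo" or self.cv.startswith("kfold:")):
            raise ValueError(f"unknown cv scheme {self.cv!r}")

    @property
    def cv_kind(self) -> str:
        return "loo" if self.cv == "loo" else "kfold"

    @property
    def cv_k(self) -> int:
        return 0 if self.cv == "loo" else int(self.cv.split(":")[1])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seeds"] = [
            {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in dataclasses.asdict(s).items() if v is not None}
            if isinstance(s, SeedSpec) else s
            for s in self.seeds
        ]
        return d


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, with field-path error reporting."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seeds = [SeedSpec(**s) for s in raw.pop("seeds", [])]
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
    for tup_field in ("band_hz", "rfe_k_grid", "elm_l_grid"):
        if tup_field in raw and isinstance(raw[tup_field], list):
            raw[tup_field] = tuple(raw[tup_field])
    return RunConfig(seeds=seeds, **raw)
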