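"""Voxel-wise resting-state measures and feature-matrix assembly.

Five measure families are computed per subject from cleaned BOLD data:

* **ReHo** — Kendall's coefficient of concordance (W) between a voxel's
  time series and those of its nearest neighbours (7/19/27-voxel cluster);
* **ALFF / fALFF** — mean amplitude (square root of power) of the
  0.01-0.08 Hz band, and its fraction of the full-band amplitude sum;
* **Degree centrality (DC)** — per-voxel sum of supra-threshold (r > 0.25)
  correlations with every other in-mask voxel, z-scored over the mask;
* **Seed-based connectivity** — Fisher r-to-z of the correlation between a
  seed's mean series and every voxel.

Maps from all subjects are concatenated voxel-wise into a subjects x
features matrix with per-column (measure, voxel) provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .io import Bold4D, MaskVolume

logger = logging.getLogger("restmvpa")

__all__ = [
    "MeasureMap",
    "FeatureMatrix",
    "kcc",
    "reho_map",
    "alff_falff_map",
    "degree_centrality_map",
    "seed_fc_map",
    "build_feature_matrix",
    "MEASURE_ORDER",
]

#: canonical concatenation order; seed maps follow in their declared order
MEASURE_ORDER = ("ReHo", "fALFF", "ALFF", "DC")

_R_CLIP = 1.0 - 1e-7


@dataclass
class MeasureMap:
    """One 3-D measure image for one subject."""

    data: np.ndarray
    measure_name: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("measure map must be 3-D")


@dataclass
class FeatureMatrix:
    """Subjects x features matrix with per-column provenance."""

    values: np.ndarray                       # (n, q)
    columns: list[tuple[str, int]]           # (measure_name, voxel linear idx)
    labels: np.ndarray                       # (n,) in {0, 1}
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.labels = np.asarray(self.labels, int)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("row/label count mismatch")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column/provenance count mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate column provenance")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    def subset(self, col_idx) -> "FeatureMatrix":
        col_idx = np.asarray(col_idx, int)
        return FeatureMatrix(
            values=self.values[:, col_idx],
            columns=[self.columns[j] for j in col_idx],
            labels=self.labels,
            subject_ids=self.subject_ids,
        )


# ---------------------------------------------------------------------------
# Kendall's W


def kcc(block: np.ndarray) -> float:
    """Kendall's coefficient of concordance of a K x T series block.

    Each series is ranked over time with mid-ranks for ties; with rank sums
    ``R_t`` over the K series at each time point,

        W = 12 * sum_t (R_t - mean(R))^2 / (K^2 (T^3 - T)).

    No tie correction is applied (ties have measure zero on continuous
    data).
    """
    block = np.asarray(block, float)
    if block.ndim != 2:
        raise ValueError("block must be K x T")
    K, T = block.shape
    if K < 2:
        raise ValueError("need K >= 2 series")
    if T < 2:
        raise ValueError("need T >= 2 time points")
    ranks = rankdata(block, axis=1)
    R = ranks.sum(axis=0)
    S = float(np.sum((R - R.mean()) ** 2))
    return 12.0 * S / (K**2 * (T**3 - T))


_NEIGHBOR_KERNELS = {}


def _neighbor_kernel(neighborhood: int) -> np.ndarray:
    """3x3x3 kernel selecting the voxel plus its 6/18/26 neighbours."""
    if neighborhood not in (7, 19, 27):
        raise ValueError(f"neighborhood must be one of 7, 19, 27, got {neighborhood}")
    if neighborhood not in _NEIGHBOR_KERNELS:
        off = np.abs(np.indices((3, 3, 3)) - 1).sum(axis=0)  # city-block dist
        max_dist = {7: 1, 19: 2, 27: 3}[neighborhood]
        _NEIGHBOR_KERNELS[neighborhood] = (off <= max_dist).astype(float)
    return _NEIGHBOR_KERNELS[neighborhood]


def reho_map(bold: Bold4D, mask: MaskVolume, neighborhood: int = 27,
             strict: bool = False) -> MeasureMap:
    """Regional homogeneity: Kendall's W over each voxel's neighbourhood.

    Edge voxels use their available in-mask neighbours with K adjusted
    accordingly; ``strict=True`` instead zeroes voxels whose neighbourhood
    is incomplete (REST-compatible behaviour).
    """
    kernel = _neighbor_kernel(neighborhood)
    T = bold.n_volumes
    m = mask.data
    ranks = np.zeros_like(bold.data)
    ranks[m] = rankdata(bold.data[m], axis=1)
    # per-voxel neighbourhood rank sums at each time point
    S = ndimage.correlate(ranks, kernel[..., None], mode="constant")
    K = ndimage.correlate(m.astype(float), kernel, mode="constant")
    K = np.where(m, K, 1.0)
    mean_R = K * (T + 1) / 2.0
    var = np.sum((S - mean_R[..., None]) ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = 12.0 * var / (K**2 * (T**3 - T))
    W = np.where(m & (K >= 2), W, 0.0)
    if strict:
        W = np.where(K == neighborhood, W, 0.0)
    return MeasureMap(data=np.clip(W, 0.0, 1.0), measure_name="ReHo",
                      subject_id=bold.subject_id)


# ---------------------------------------------------------------------------
# ALFF / fALFF


def alff_falff_map(bold: Bold4D, mask: MaskVolume,
                   band_hz: tuple[float, float] = (0.01, 0.08),
                   full_band_hz: tuple[float, float] | None = None,
                   ) -> tuple[MeasureMap, MeasureMap]:
    """Low-frequency amplitude (ALFF) and its full-band fraction (fALFF).

    Expects detrended but **not** band-pass-filtered data (fALFF needs the
    full spectrum).  The one-sided amplitude spectrum is a(f) = sqrt(power);
    ALFF is the mean of a(f) over the band bins and fALFF the ratio of the
    band amplitude sum to the full-band sum.  The full band defaults to
    (0, Nyquist]; a lower cap may be supplied.  All-zero series get
    fALFF = 0 with a logged flag.
    """
    T = bold.n_volumes
    freqs = np.fft.rfftfreq(T, d=bold.tr_s)
    nyquist = 1.0 / (2.0 * bold.tr_s)
    low, high = band_hz
    band = (freqs >= low) & (freqs <= high)
    band[0] = False
    if not band.any():
        raise ValueError(f"no FFT bins in band {band_hz}")
    full_high = nyquist if full_band_hz is None else min(full_band_hz[1], nyquist)
    full = (freqs > 0) & (freqs <= full_high + 1e-12)

    series = bold.data[mask.data]
    amp = np.abs(np.fft.rfft(series, axis=1)) * (2.0 / T)  # one-sided amplitude
    alff_v = amp[:, band].mean(axis=1)
    denom = amp[:, full].sum(axis=1)
    zero = denom == 0
    if zero.any():
        logger.warning("fALFF: %d all-zero series set to 0", int(zero.sum()))
    falff_v = np.zeros_like(alff_v)
    np.divide(amp[:, band].sum(axis=1), denom, out=falff_v, where=~zero)

    alff = np.zeros(mask.data.shape)
    falff = np.zeros(mask.data.shape)
    alff[mask.data] = alff_v
    falff[mask.data] = falff_v
    return (
        MeasureMap(data=alff, measure_name="ALFF", subject_id=bold.subject_id),
        MeasureMap(data=falff, measure_name="fALFF", subject_id=bold.subject_id),
    )


# ---------------------------------------------------------------------------
# Degree centrality


@dataclass
class DcParams:
    r_threshold: float = 0.25
    weighted: bool = True

    def __post_init__(self) -> None:
        if not (-1.0 < self.r_threshold < 1.0):
            raise ValueError("r_threshold must be in (-1, 1)")


def degree_centrality_map(bold: Bold4D, mask: MaskVolume,
                          params: DcParams | None = None,
                          block_size: int = 1024) -> MeasureMap:
    """Weighted degree of the voxel-wise correlation graph, z-scored.

    DC(v) = sum over u != v of r_uv * [r_uv > threshold] (or the count if
    ``weighted=False``); the threshold applies to *signed* r, so
    anticorrelations never contribute.  The map is standardised to mean 0,
    SD 1 over the mask.  Constant series get zero correlations with a
    warning.  Computed blockwise so the full V x V matrix is never stored.
    """
    params = params or DcParams()
    series = bold.data[mask.data]
    V, T = series.shape
    if V < 3:
        raise ValueError("need at least 3 in-mask voxels")
    centered = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    if constant.any():
        logger.warning("DC: %d constant series; correlations set to 0",
                       int(constant.sum()))
    norms[constant] = 1.0
    Z = (centered / norms[:, None]).astype(np.float64)
    Z[constant] = 0.0

    dc = np.zeros(V)
    for start in range(0, V, block_size):
        stop = min(start + block_size, V)
        r = Z[start:stop] @ Z.T                       # (b, V)
        rows = np.arange(start, stop)
        r[np.arange(stop - start), rows] = 0.0        # exclude self
        supra = r > params.r_threshold
        dc[start:stop] = (r * supra).sum(axis=1) if params.weighted \
            else supra.sum(axis=1)

    sd = dc.std()
    z = (dc - dc.mean()) / sd if sd > 0 else np.zeros_like(dc)
    out = np.zeros(mask.data.shape)
    out[mask.data] = z
    return MeasureMap(data=out, measure_name="DC", subject_id=bold.subject_id)


# ---------------------------------------------------------------------------
# Seed-based connectivity


def seed_fc_map(bold: Bold4D, mask: MaskVolume, seed: MaskVolume,
                name: str = "seed") -> MeasureMap:
    """Fisher-z map of correlation with the seed's mean series.

    r is clipped to +/-(1 - 1e-7) before atanh so the map stays finite.
    """
    if not seed.data.any():
        raise ValueError("empty seed")
    if np.any(seed.data & ~mask.data):
        raise ValueError("seed extends outside the brain mask")
    seed_series = bold.data[seed.data].mean(axis=0)
    seed_c = seed_series - seed_series.mean()
    seed_norm = np.linalg.norm(seed_c)
    series = bold.data[mask.data]
    centered = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    denom = norms * seed_norm
    r = np.zeros(series.shape[0])
    np.divide(centered @ seed_c, denom, out=r, where=denom > 0)
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    out = np.zeros(mask.data.shape)
    out[mask.data] = z
    return MeasureMap(data=out, measure_name=f"{name}-rsFC",
                      subject_id=bold.subject_id)


# ---------------------------------------------------------------------------
# Feature concatenation


def build_feature_matrix(subject_maps: list[dict[str, MeasureMap]],
                         mask: MaskVolume | dict[str, MaskVolume],
                         labels,
                         subject_ids: list[str] | None = None,
                         measure_order: list[str] | None = None,
                         ) -> FeatureMatrix:
    """Concatenate per-subject measure maps into a subjects x features matrix.

    ``subject_maps`` is one dict (measure name -> map) per subject, all
    sharing dims and measure names.  ``mask`` is either one selection mask
    for all measures or a per-measure dict (each measure keeps its own
    surviving voxels).  Columns are ordered by the fixed measure order
    (ReHo, fALFF, ALFF, DC, then seed maps in declared order), then by
    voxel linear index; rows follow the input subject order.
    """
    if not subject_maps:
        raise ValueError("no subjects")
    names = set(subject_maps[0])
    for i, maps in enumerate(subject_maps):
        if set(maps) != names:
            raise ValueError(f"subject {i} missing measures {names - set(maps)}")
    if measure_order is None:
        fixed = [m for m in MEASURE_ORDER if m in names]
        seeds = sorted(n for n in names if n not in MEASURE_ORDER)
        measure_order = fixed + seeds
    cols: list[tuple[str, int]] = []
    blocks = []
    for name in measure_order:
        m = mask[name] if isinstance(mask, dict) else mask
        idx = m.indices()
        cols.extend((name, int(j)) for j in idx)
        blocks.append(np.stack(
            [maps[name].data.ravel()[idx] for maps in subject_maps]
        ))
    values = np.concatenate(blocks, axis=1) if blocks else np.zeros((len(subject_maps), 0))
    return FeatureMatrix(values=values, columns=cols,
                         labels=np.asarray(labels, int),
                         subject_ids=subject_ids or [m[measure_order[0]].subject_id
                                                     for m in subject_maps])
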