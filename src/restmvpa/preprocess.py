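"""Temporal cleanup for already-aligned BOLD volumes.

Covers the post-registration stages only: linear detrending, nuisance
regression, ideal (FFT-bin) band-pass filtering, and Gaussian spatial
smoothing.  The canonical order is detrend -> nuisance -> band-pass;
slice timing, realignment and normalisation are out of scope, and motion
regressors are accepted only as user-supplied confound columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import Bold4D, MaskVolume

__all__ = [
    "ConfoundTable",
    "detrend_linear",
    "bandpass",
    "regress_confounds",
    "smooth_gaussian",
    "fwhm_to_sigma_vox",
]

# FWHM = 2*sqrt(2 ln 2) * sigma for a Gaussian
_FWHM_OVER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class ConfoundTable:
    """T x C nuisance regressor matrix with column names."""

    values: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column-name count does not match matrix width")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("confounds contain non-finite values")

    @classmethod
    def from_tsv(cls, path) -> "ConfoundTable":
        df = pd.read_csv(path, sep="\t")
        return cls(values=df.to_numpy(float), columns=list(df.columns))


def _masked_series(bold: Bold4D, mask: MaskVolume) -> np.ndarray:
    return bold.data[mask.data]  # (V, T)


def _rebuild(bold: Bold4D, mask: MaskVolume, series: np.ndarray) -> Bold4D:
    out = np.zeros_like(bold.data)
    out[mask.data] = series
    return Bold4D(data=out, affine=bold.affine, tr_s=bold.tr_s,
                  subject_id=bold.subject_id)


def detrend_linear(bold: Bold4D, mask: MaskVolume) -> Bold4D:
    """Remove the least-squares line (intercept + slope) per in-mask voxel."""
    T = bold.n_volumes
    if T < 3:
        raise ValueError("need T >= 3 for linear detrending")
    t = np.arange(T, dtype=float)
    design = np.column_stack([np.ones(T), t])
    series = _masked_series(bold, mask)
    coef, *_ = np.linalg.lstsq(design, series.T, rcond=None)
    return _rebuild(bold, mask, series - (design @ coef).T)


def bandpass(bold: Bold4D, band_hz: tuple[float, float], mask: MaskVolume) -> Bold4D:
    """Ideal frequency-domain band-pass: rFFT bins outside [low, high] zeroed.

    The DC bin is always zeroed, so the output has exactly zero temporal
    mean per voxel.
    """
    low, high = band_hz
    T = bold.n_volumes
    nyquist = 1.0 / (2.0 * bold.tr_s)
    if not (0 < low < high <= nyquist + 1e-12):
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyquist:g})")
    freqs = np.fft.rfftfreq(T, d=bold.tr_s)
    keep = (freqs >= low) & (freqs <= high)
    keep[0] = False
    if not keep.any():
        raise ValueError(f"empty passband {band_hz} at T={T}, TR={bold.tr_s}s")
    series = _masked_series(bold, mask)
    spec = np.fft.rfft(series, axis=1)
    spec[:, ~keep] = 0
    return _rebuild(bold, mask, np.fft.irfft(spec, n=T, axis=1))


def regress_confounds(bold: Bold4D, confounds: ConfoundTable | None,
                      mask: MaskVolume) -> Bold4D:
    """OLS residual of each voxel series on [1, confound columns].

    With an empty confound set this reduces to demeaning.  A rank-deficient
    design raises an error naming the collinear columns.
    """
    T = bold.n_volumes
    if confounds is None or confounds.values.size == 0:
        design = np.ones((T, 1))
        names = ["intercept"]
    else:
        if confounds.values.shape[0] != T:
            raise ValueError(
                f"confound rows ({confounds.values.shape[0]}) != T ({T})"
            )
        design = np.column_stack([np.ones(T), confounds.values])
        names = ["intercept"] + confounds.columns
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that do not raise the rank
        bad = []
        kept = design[:, :1]
        for j in range(1, design.shape[1]):
            cand = np.column_stack([kept, design[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(names[j])
            else:
                kept = cand
        raise ValueError(f"rank-deficient confound design; collinear columns: {bad}")
    series = _masked_series(bold, mask)
    coef, *_ = np.linalg.lstsq(design, series.T, rcond=None)
    return _rebuild(bold, mask, series - (design @ coef).T)


def fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxels for a given FWHM in mm."""
    voxel_size_mm = np.atleast_1d(np.asarray(voxel_size_mm, float))
    return fwhm_mm / (voxel_size_mm * _FWHM_OVER_SIGMA)


def smooth_gaussian(data: np.ndarray, fwhm_mm: float, voxel_size_mm,
                    mask: MaskVolume | None = None) -> np.ndarray:
    """Separable 3-D Gaussian smoothing (zero-padded boundaries).

    Works on a 3-D map or a 4-D series (smoothing each volume).  With a
    mask, the result is restricted to the mask afterwards; ``fwhm_mm=0``
    is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    data = np.asarray(data, float)
    if fwhm_mm == 0:
        out = data.copy()
    else:
        sigma = np.broadcast_to(
            fwhm_to_sigma_vox(fwhm_mm, voxel_size_mm), (3,)
        ).astype(float)
        if data.ndim == 3:
            out = ndimage.gaussian_filter(data, sigma=sigma, mode="constant")
        elif data.ndim == 4:
            out = ndimage.gaussian_filter(
                data, sigma=(*sigma, 0.0), mode="constant"
            )
        else:
            raise ValueError("expected a 3-D map or 4-D series")
    if mask is not None:
        out = out * mask.data[(...,) + (None,) * (data.ndim - 3)]
    return out


def preprocess_bold(bold: Bold4D, mask: MaskVolume,
                    band_hz: tuple[float, float] = (0.01, 0.08),
                    confounds: ConfoundTable | None = None,
                    drop_initial: int = 0) -> tuple[Bold4D, Bold4D]:
    """Standard cleanup chain: drop initial volumes, detrend, regress, filter.

    Returns ``(filtered, detrended)``; the detrended-but-unfiltered volume
    is what amplitude-spectrum measures (ALFF/fALFF) consume, since they
    need the full spectrum.
    """
    if drop_initial:
        bold = Bold4D(data=bold.data[..., drop_initial:], affine=bold.affine,
                      tr_s=bold.tr_s, subject_id=bold.subject_id)
    detrended = detrend_linear(bold, mask)
    cleaned = regress_confounds(detrended, confounds, mask)
    filtered = bandpass(cleaned, band_hz, mask)
    return filtered, cleaned
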