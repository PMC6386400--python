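"""Synthetic two-group BOLD cohort generator.

Emulates resting-state acquisitions (TR = 3 s, ~80-140 volumes) as AR(1)
Gaussian voxel noise plus additive band-limited latent signals whose
amplitude differs between groups:

* ``coherence`` — one shared latent series added to every voxel of a
  region, raising within-region temporal coherence (Kendall-W regional
  homogeneity) and band-limited power;
* ``amplitude`` — an independent latent per voxel, raising low-frequency
  amplitude (ALFF/fALFF) without raising coherence;
* ``coupling``  — the same latent added to a region and a partner region,
  raising seed-based connectivity and degree centrality.

Effects are additive in signal space; the group difference is encoded
purely in the amplitude pair, which keeps planted effect sizes analytically
tractable (within a coherence region the expected pairwise correlation is
a^2/(a^2+sigma^2) for amplitude a over noise sd sigma).

No hemodynamic response, motion, physiological noise or scanner effects
are simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Bold4D, MaskVolume, SeedSpec, resolve_seed, write_bold4d, write_mask, write_manifest
from .rng import substream

__all__ = ["EffectSpec", "CohortSpec", "make_latent", "generate_cohort"]

_KINDS = ("coherence", "amplitude", "coupling")


@dataclass
class EffectSpec:
    """One planted group effect."""

    kind: str                              # coherence | amplitude | coupling
    region: SeedSpec
    group_amplitudes: tuple[float, float]  # (group 0, group 1)
    band_hz: tuple[float, float] = (0.01, 0.08)
    partner_region: SeedSpec | None = None  # coupling only

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if any(a < 0 for a in self.group_amplitudes):
            raise ValueError("amplitudes must be >= 0")
        if self.kind == "coupling" and self.partner_region is None:
            raise ValueError("coupling effect needs a partner_region")


@dataclass
class CohortSpec:
    """Geometry, noise model and planted effects for a synthetic cohort.

    Defaults are desk-scale: 24x24x24 grids of 3-mm voxels, 120 volumes at
    TR = 3 s, 20+20 subjects, AR(1) noise with phi = 0.3 and unit sd.
    """

    n_per_group: tuple[int, int] = (20, 20)
    dims: tuple[int, int, int] = (24, 24, 24)
    n_volumes: int = 120
    tr_s: float = 3.0
    voxel_size_mm: float = 3.0
    noise_ar1_phi: float = 0.3
    noise_sd: float = 1.0
    effects: list[EffectSpec] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_volumes < 32:
            raise ValueError("need at least 32 volumes")
        if not abs(self.noise_ar1_phi) < 1:
            raise ValueError("|phi| must be < 1 (stationary AR(1))")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff


def make_latent(band_hz: tuple[float, float], T: int, tr_s: float,
                rng: np.random.Generator) -> np.ndarray:
    """A unit-variance band-limited series built in the frequency domain.

    Complex Gaussian coefficients are drawn only at the rFFT bins whose
    frequency lies in ``[low, high]``; everything else (including DC) is
    zero, so spectral mass outside the band is nil up to the final exact
    variance normalisation.
    """
    low, high = band_hz
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0 < low < high <= nyquist + 1e-12):
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyquist:g}]")
    freqs = np.fft.rfftfreq(T, d=tr_s)
    in_band = (freqs >= low) & (freqs <= high)
    in_band[0] = False
    if not in_band.any():
        raise ValueError(
            f"no FFT bins in band {band_hz} at T={T}, TR={tr_s}s"
        )
    spec = np.zeros(len(freqs), dtype=complex)
    n = int(in_band.sum())
    spec[in_band] = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    x = np.fft.irfft(spec, n=T)
    x -= x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate latent draw (zero variance)")
    return x / sd


def _ar1_noise(shape_vox: tuple[int, ...], T: int, phi: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    n_vox = int(np.prod(shape_vox))
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    x = np.empty((n_vox, T))
    x[:, 0] = rng.standard_normal(n_vox) * sd
    for t in range(1, T):
        x[:, t] = phi * x[:, t - 1] + innov_sd * rng.standard_normal(n_vox)
    return x.reshape(*shape_vox, T)


def _check_overlaps(resolved: list[tuple[EffectSpec, np.ndarray]]) -> None:
    for i in range(len(resolved)):
        for j in range(i + 1, len(resolved)):
            ei, ri = resolved[i]
            ej, rj = resolved[j]
            if ei.kind != ej.kind:
                overlap = np.flatnonzero((ri & rj).ravel())
                if overlap.size:
                    raise ValueError(
                        f"effects {ei.kind!r} and {ej.kind!r} overlap at "
                        f"voxels {overlap[:20].tolist()}"
                        + ("..." if overlap.size > 20 else "")
                    )


def generate_cohort(spec: CohortSpec, out_dir) -> pd.DataFrame:
    """Write one NIfTI per subject plus manifest, mask and ground truth.

    Returns the manifest DataFrame (``subject_id,label,path``).  A JSON
    sidecar ``ground_truth.json`` records the resolved voxel sets of every
    effect for recovery scoring.  Bit-identical outputs for identical
    ``spec`` (including ``rng_seed``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = spec.affine
    mask = MaskVolume(data=np.ones(spec.dims, bool), affine=affine)
    resolved = [(e, resolve_seed(e.region, mask).data) for e in spec.effects]
    partners = {
        id(e): resolve_seed(e.partner_region, mask).data
        for e, _ in resolved if e.kind == "coupling"
    }
    _check_overlaps(resolved)

    write_mask(mask, out_dir / "mask.nii.gz")
    truth = {
        f"effect{k}_{e.kind}": sorted(
            np.flatnonzero(r.ravel()).tolist()
            + (np.flatnonzero(partners[id(e)].ravel()).tolist()
               if e.kind == "coupling" else [])
        )
        for k, (e, r) in enumerate(resolved)
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))

    rows = []
    n0, n1 = spec.n_per_group
    labels = [0] * n0 + [1] * n1
    for i, label in enumerate(labels):
        rng = substream(spec.rng_seed, f"subject-{i}")
        data = _ar1_noise(spec.dims, spec.n_volumes,
                          spec.noise_ar1_phi, spec.noise_sd, rng)
        for e, region in resolved:
            a = e.group_amplitudes[label]
            if e.kind == "coherence":
                latent = make_latent(e.band_hz, spec.n_volumes, spec.tr_s, rng)
                data[region] += a * latent
            elif e.kind == "amplitude":
                for idx in np.argwhere(region):
                    latent = make_latent(e.band_hz, spec.n_volumes, spec.tr_s, rng)
                    data[tuple(idx)] += a * latent
            else:  # coupling
                latent = make_latent(e.band_hz, spec.n_volumes, spec.tr_s, rng)
                data[region] += a * latent
                data[partners[id(e)]] += a * latent
        sid = f"sub-{i:03d}"
        path = out_dir / f"{sid}.nii.gz"
        write_bold4d(
            Bold4D(data=data, affine=affine, tr_s=spec.tr_s, subject_id=sid),
            path,
        )
        rows.append({"subject_id": sid, "label": label, "path": str(path)})

    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
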