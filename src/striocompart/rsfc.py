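"""Seed-based resting-state functional connectivity.

For each compartment-like seed mask the mean BOLD time course is correlated
(Pearson) with every non-striatal brain voxel; correlations are Fisher
z-transformed (z = atanh r) for group statistics. Each subject contributes
four maps: L-STR, L-MAT, R-STR, R-MAT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import BoldSeries

__all__ = ["ZMap", "seed_timecourse", "corr_map", "subject_maps",
           "restrict_to_rois", "SEED_NAMES", "Z_CAP"]

SEED_NAMES = ("L-STR", "L-MAT", "R-STR", "R-MAT")

# |r| = 1 (e.g. a voxel inside its own seed) would map to infinite z;
# correlations are clipped so z stays finite
R_CAP = 1.0 - 1e-7
Z_CAP = float(np.arctanh(R_CAP))


@dataclass
class ZMap:
    """Fisher-z connectivity volume for one seed; NaN where undefined
    (inside the excluded striatum, outside the brain, or zero variance)."""

    z: np.ndarray
    seed: str = ""
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    n_clipped: int = 0

    @property
    def defined(self):
        return np.isfinite(self.z)


def seed_timecourse(bold: BoldSeries, seed: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the BOLD signal over the seed voxels, per timepoint."""
    seed = np.asarray(seed, dtype=bool)
    if seed.shape != bold.data.shape[:3]:
        raise ValueError("seed mask and BOLD grid have different shapes")
    if not seed.any():
        raise ValueError("empty seed mask")
    if np.any(seed & ~bold.brain_mask):
        raise ValueError("seed mask extends outside the brain mask")
    return bold.data[seed].mean(axis=0, dtype=np.float64)


def corr_map(bold: BoldSeries, tc: np.ndarray, exclude: np.ndarray,
             seed_name: str = "", affine=None) -> ZMap:
    """Voxel-wise Pearson correlation with a seed time course, Fisher
    z-transformed; voxels in ``exclude`` and zero-variance voxels are NaN."""
    tc = np.asarray(tc, dtype=np.float64)
    if tc.ndim != 1 or tc.size != bold.data.shape[3]:
        raise ValueError("time course length must match the BOLD series")
    tc_c = tc - tc.mean()
    tc_norm = np.sqrt((tc_c ** 2).sum())
    if tc_norm == 0:
        raise ValueError("seed time course has zero variance")

    exclude = np.asarray(exclude, dtype=bool)
    target = bold.brain_mask & ~exclude
    z = np.full(bold.data.shape[:3], np.nan)
    n_clipped = 0
    if target.any():
        x = bold.data[target].astype(np.float64)
        x -= x.mean(axis=1, keepdims=True)
        norms = np.sqrt((x ** 2).sum(axis=1))
        ok = norms > 0
        r = np.full(norms.shape, np.nan)
        r[ok] = (x[ok] @ tc_c) / (norms[ok] * tc_norm)
        n_clipped = int(np.sum(np.abs(r[ok]) > R_CAP))
        r = np.clip(r, -R_CAP, R_CAP)
        z[target] = np.arctanh(r)
    return ZMap(z=z, seed=seed_name,
                affine=np.eye(4) if affine is None else np.asarray(affine),
                n_clipped=n_clipped)


def subject_maps(bold: BoldSeries, masks: dict, striatum: np.ndarray,
                 affine=None) -> dict:
    """The four per-subject connectivity maps (L-STR, L-MAT, R-STR, R-MAT).

    ``masks`` maps hemisphere ('L' / 'R') -> CompartmentMasks. All four maps
    exclude the striatum, so compartment contrasts never compare seed voxels
    with themselves.
    """
    striatum = np.asarray(striatum, dtype=bool)
    seeds = {}
    for side in ("L", "R"):
        if side not in masks:
            raise ValueError(f"missing compartment masks for hemisphere {side!r}")
        seeds[f"{side}-STR"] = masks[side].striosome_like
        seeds[f"{side}-MAT"] = masks[side].matrix_like
    out = {}
    for name in SEED_NAMES:
        tc = seed_timecourse(bold, seeds[name])
        out[name] = corr_map(bold, tc, exclude=striatum, seed_name=name,
                             affine=affine)
    return out


def restrict_to_rois(zmap: ZMap, roi_masks: dict) -> dict:
    """Mask a ZMap to each network ROI independently (no full-factorial
    analysis); returns name -> ZMap defined only inside that ROI."""
    out = {}
    for name, roi in roi_masks.items():
        roi = np.asarray(roi, dtype=bool)
        z = np.where(roi, zmap.z, np.nan)
        out[name] = ZMap(z=z, seed=f"{zmap.seed}|{name}", affine=zmap.affine)
    return out
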