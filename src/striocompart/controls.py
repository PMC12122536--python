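"""Negative controls: location jitter of seed masks and bundle-core overlap.

Compartment-specific connectivity should depend on the precise voxel
locations selected, not on the striatal neighborhood they occupy. Jittering
every seed voxel by up to +-3 voxels per axis (staying inside the striatum
and outside both original compartment masks) builds neighborhood-matched
control seeds; the Dice similarity coefficient between thresholded bundle
cores quantifies the segregation of compartment-seeded projections.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .parcellation import BiasMap, CompartmentMasks

__all__ = [
    "JitterSpec",
    "BundleCore",
    "jitter_mask",
    "mask_bias",
    "bundle_core",
    "dsc",
]


@dataclass(frozen=True)
class JitterSpec:
    max_shift: int = 3
    constraints: tuple = ("stay-in-striatum", "exclude-original-compartment-masks")
    rng_seed: int = 0
    max_attempts: int = 1000

    def validate(self):
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        known = {"stay-in-striatum", "exclude-original-compartment-masks"}
        bad = set(self.constraints) - known
        if bad:
            raise ValueError(f"unknown jitter constraints: {sorted(bad)}")
        return self


def jitter_mask(mask: np.ndarray, striatum: np.ndarray,
                originals: CompartmentMasks, spec: JitterSpec):
    """Shift every mask voxel by an independent uniform integer offset in
    [-max_shift, +max_shift] per axis.

    Constraints (per spec): shifted voxels stay inside the striatum and never
    land in either original compartment mask; collisions are resolved by
    rejection-resampling the later voxel in stable (flat index) order, up to
    ``max_attempts`` draws. The shifted mask always has the cardinality of
    the input mask.

    Returns ``(shifted_mask, stats)`` where stats holds the mean signed shift
    per axis, the mean per-voxel Euclidean shift, and the RMS shift.
    """
    spec.validate()
    mask = np.asarray(mask, dtype=bool)
    striatum = np.asarray(striatum, dtype=bool)
    rng = np.random.default_rng(spec.rng_seed)
    shape = np.asarray(mask.shape)

    stay_in = "stay-in-striatum" in spec.constraints
    exclude = "exclude-original-compartment-masks" in spec.constraints
    forbidden = np.zeros(mask.shape, dtype=bool)
    if exclude and originals is not None:
        forbidden = originals.striosome_like | originals.matrix_like

    taken = np.zeros(mask.shape, dtype=bool)
    shifts = []
    voxels = np.argwhere(mask)  # argwhere is in flat-index (C) order
    for vox in voxels:
        placed = False
        for _ in range(spec.max_attempts):
            shift = rng.integers(-spec.max_shift, spec.max_shift + 1, size=3)
            tgt = vox + shift
            if np.any(tgt < 0) or np.any(tgt >= shape):
                continue
            t = tuple(tgt)
            if stay_in and not striatum[t]:
                continue
            if forbidden[t] or taken[t]:
                continue
            taken[t] = True
            shifts.append(shift)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"no feasible jitter target for voxel {tuple(int(v) for v in vox)} "
                f"after {spec.max_attempts} attempts")

    shifts = np.asarray(shifts, dtype=float)
    dist = np.sqrt((shifts ** 2).sum(axis=1)) if len(shifts) else np.array([])
    stats = {
        "mean_signed_shift": shifts.mean(axis=0) if len(shifts) else np.zeros(3),
        "mean_euclidean_shift": float(dist.mean()) if len(dist) else 0.0,
        "rms_shift": float(np.sqrt((dist ** 2).mean())) if len(dist) else 0.0,
        "n_voxels": int(len(shifts)),
    }
    return taken, stats


def mask_bias(bias: BiasMap, mask: np.ndarray, cutoff: float = 0.55,
              toward: str = "striosome"):
    """Mean compartment bias within a mask and the fraction of voxels whose
    bias toward the stated compartment exceeds ``cutoff``.

    ``toward='striosome'`` assesses P; ``toward='matrix'`` assesses 1 - P.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask_bias: empty mask")
    sel = mask & bias.defined
    if not sel.any():
        raise ValueError("mask_bias: mask has no defined-bias voxels")
    q = bias.p_striosome[sel]
    if toward == "matrix":
        q = 1.0 - q
    elif toward != "striosome":
        raise ValueError(f"toward must be 'striosome' or 'matrix', got {toward!r}")
    return float(q.mean()), float((q > cutoff).mean())


@dataclass
class BundleCore:
    """Top-amplitude core of a tract-density bundle."""

    density: np.ndarray
    top_fraction: float
    core: np.ndarray = field(init=False)

    def __post_init__(self):
        density = np.asarray(self.density, dtype=float)
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        nz = np.flatnonzero(density.ravel())
        if nz.size == 0:
            raise ValueError("bundle density has no nonzero voxels")
        k = math.ceil(self.top_fraction * nz.size)
        amp = density.ravel()[nz]
        order = np.lexsort((nz, -amp))  # amplitude desc, flat index asc
        core = np.zeros(density.shape, dtype=bool)
        core.ravel()[nz[order[:k]]] = True
        self.core = core


def bundle_core(density: np.ndarray, top_fraction: float = 0.25) -> BundleCore:
    """Isolate a bundle's core: the uppermost ``top_fraction`` of its nonzero
    voxels by amplitude (count-based quantile; ties broken by flat index)."""
    return BundleCore(density=np.asarray(density, dtype=float),
                      top_fraction=top_fraction)


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 0 when both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / denom
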