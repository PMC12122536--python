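"""Connectivity-based parcellation of the striatum into compartment-like voxels.

Competing "bait" target regions with histologically established compartment
bias (five striosome-favoring, five matrix-favoring) yield per-voxel
streamline counts. At each striatal voxel the striosome bias probability is

    P = S / (S + M)

where S and M are the summed counts reaching striosome- and matrix-favoring
baits. Equal-volume seed masks take the most-biased 13% of each hemisphere's
striatal voxels from either end of the P distribution (the two-sided Gaussian
mass beyond 1.5 SD), guaranteeing striosome-like and matrix-like masks of
identical size per subject and hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TargetCountMaps",
    "BiasMap",
    "CompartmentMasks",
    "compute_bias",
    "equal_volume_masks",
    "gaussian_tail_fraction",
    "classify_voxels",
    "n1_parcellate",
    "STRIOSOME",
    "MATRIX",
    "INDETERMINATE",
    "UNDEFINED",
]

# label codes for classify_voxels
UNDEFINED = 0
STRIOSOME = 1
MATRIX = 2
INDETERMINATE = 3


@dataclass
class TargetCountMaps:
    """Per-bait-region streamline-count grids over one striatum.

    ``counts`` maps bait-region name -> 3-D non-negative count grid;
    ``favored`` maps bait-region name -> "striosome" | "matrix".
    Counts are zero outside ``striatum_mask``.
    """

    counts: dict
    favored: dict
    striatum_mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        shapes = {np.shape(c) for c in self.counts.values()}
        if len(shapes) > 1:
            raise ValueError(f"count grids have mismatched shapes: {shapes}")
        if shapes and next(iter(shapes)) != self.striatum_mask.shape:
            raise ValueError("count grids and striatum mask have different shapes")
        unknown = set(self.counts) - set(self.favored)
        if unknown:
            raise ValueError(f"bait regions without a favored class: {sorted(unknown)}")
        for name, grid in self.counts.items():
            if np.any(np.asarray(grid) < 0):
                raise ValueError(f"negative counts in bait region {name!r}")

    def regions(self, favored_class=None):
        names = sorted(self.counts)
        if favored_class is None:
            return names
        return [n for n in names if self.favored[n] == favored_class]

    def summed(self, favored_class):
        names = self.regions(favored_class)
        if not names:
            raise ValueError(f"no bait regions favoring {favored_class!r}")
        total = np.zeros(self.striatum_mask.shape, dtype=float)
        for n in names:
            total += np.asarray(self.counts[n], dtype=float)
        return total

    def without(self, leave_out):
        """Copy of this count set with one bait region removed (N-1)."""
        if leave_out not in self.counts:
            raise KeyError(f"unknown bait region {leave_out!r}")
        cls = self.favored[leave_out]
        remaining = [n for n in self.counts if n != leave_out and self.favored[n] == cls]
        if not remaining:
            raise ValueError(
                f"cannot remove {leave_out!r}: it is the last {cls}-favoring bait region"
            )
        counts = {n: c for n, c in self.counts.items() if n != leave_out}
        favored = {n: f for n, f in self.favored.items() if n != leave_out}
        return TargetCountMaps(counts, favored, self.striatum_mask, self.affine)


@dataclass
class BiasMap:
    """Per-voxel striosome bias probability P = S/(S+M); NaN where S+M = 0."""

    p_striosome: np.ndarray
    total_counts: np.ndarray = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def defined(self):
        return np.isfinite(self.p_striosome)


@dataclass
class CompartmentMasks:
    """Equal-volume most-biased masks for one subject and hemisphere."""

    striosome_like: np.ndarray
    matrix_like: np.ndarray
    thresholds_used: tuple
    target_fraction: float
    scope: str = ""

    def __post_init__(self):
        if np.any(self.striosome_like & self.matrix_like):
            raise ValueError("striosome-like and matrix-like masks overlap")
        if int(self.striosome_like.sum()) != int(self.matrix_like.sum()):
            raise ValueError("compartment masks must have equal volume")


def compute_bias(counts: TargetCountMaps) -> BiasMap:
    """Per-voxel striosome bias P = S/(S+M), undefined (NaN) where S+M = 0."""
    s = counts.summed("striosome")
    m = counts.summed("matrix")
    total = s + m
    p = np.full(total.shape, np.nan, dtype=float)
    nz = total > 0
    p[nz] = s[nz] / total[nz]
    return BiasMap(p_striosome=p, total_counts=total, affine=counts.affine)


def equal_volume_masks(bias: BiasMap, striatum_hemi: np.ndarray,
                       target_fraction: float = 0.13,
                       scope: str = "") -> CompartmentMasks:
    """Top-k most-striosome-biased and top-k most-matrix-biased voxels.

    k = round(target_fraction * hemisphere striatal volume). Selection walks
    from each end of the P distribution with the deterministic tie-break
    (bias desc, total count desc, flat index asc); the matrix-like mask is
    selected after excluding striosome-like voxels, so the two masks are
    always disjoint and exactly equal in volume.
    """
    striatum_hemi = np.asarray(striatum_hemi, dtype=bool)
    if striatum_hemi.shape != bias.p_striosome.shape:
        raise ValueError("striatum mask and bias map have different shapes")
    n_hemi = int(striatum_hemi.sum())
    k = int(round(target_fraction * n_hemi))
    if k == 0:
        raise ValueError(
            f"target fraction {target_fraction} of {n_hemi} voxels rounds to an empty mask"
        )
    eligible = striatum_hemi & bias.defined
    flat_elig = np.flatnonzero(eligible.ravel())
    if flat_elig.size < 2 * k:
        raise ValueError(
            f"need 2*k = {2 * k} defined-bias voxels to build equal-volume masks, "
            f"only {flat_elig.size} available"
        )

    p = bias.p_striosome.ravel()[flat_elig]
    tot = None if bias.total_counts is None else bias.total_counts.ravel()[flat_elig]

    idx_local = np.arange(p.size)
    counts = np.zeros(p.size) if tot is None else np.asarray(tot, dtype=float)
    # np.lexsort: last key is primary; negate for descending order
    order_s = np.lexsort((idx_local, -counts, -p))
    strio_local = order_s[:k]

    remaining = np.setdiff1d(idx_local, strio_local, assume_unique=False)
    pm = 1.0 - p[remaining]
    order_m = np.lexsort((remaining, -counts[remaining], -pm))
    matrix_local = remaining[order_m[:k]]

    strio = np.zeros(bias.p_striosome.shape, dtype=bool)
    matrix = np.zeros_like(strio)
    strio.ravel()[flat_elig[strio_local]] = True
    matrix.ravel()[flat_elig[matrix_local]] = True

    thr_s = float(p[strio_local].min())
    thr_m = float((1.0 - p[matrix_local]).min())
    return CompartmentMasks(
        striosome_like=strio,
        matrix_like=matrix,
        thresholds_used=(thr_s, thr_m),
        target_fraction=target_fraction,
        scope=scope,
    )


def gaussian_tail_fraction(k_sd: float) -> float:
    """Two-sided Gaussian mass beyond ``k_sd`` standard deviations.

    2*(1 - Phi(k_sd)); at k_sd = 1.5 this is 0.1336, i.e. 13% to the nearest
    percent — the equal-volume mask target fraction.
    """
    k = float(k_sd)
    if k < 0:
        raise ValueError(f"k_sd must be non-negative, got {k}")
    return float(2.0 * stats.norm.sf(k))


def classify_voxels(bias: BiasMap, cutoff: float = 0.55) -> np.ndarray:
    """Label voxels striosome-like (P > cutoff), matrix-like (1-P > cutoff),
    or indeterminate; undefined voxels (S+M = 0) stay 0.

    Requires cutoff in (0.5, 1] so the two classes cannot overlap.
    """
    if not 0.5 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0.5, 1], got {cutoff}")
    p = bias.p_striosome
    labels = np.zeros(p.shape, dtype=np.uint8)
    defined = bias.defined
    labels[defined & (p > cutoff)] = STRIOSOME
    labels[defined & ((1.0 - p) > cutoff)] = MATRIX
    labels[defined & (labels == 0)] = INDETERMINATE
    return labels


def n1_parcellate(counts: TargetCountMaps, leave_out: str) -> BiasMap:
    """Bias map recomputed with one bait region left out (N-1 parcellation)."""
    return compute_bias(counts.without(leave_out))
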