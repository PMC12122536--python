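"""Anatomical validation of compartment-like parcellations.

Checks whether parcellated voxels reproduce the histologic anatomy of the
striatal compartments: striosome-like voxels should be scarce, scattered in
small clusters, and shifted rostro-ventro-medially relative to matrix-like
voxels, whose volume dominates and forms large contiguous clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .cli_io import world_coordinates

__all__ = [
    "ClusterReport",
    "CentroidOffsets",
    "cluster_sizes",
    "centroid_offsets",
    "plane_profile",
    "connectivity_structure",
]


def connectivity_structure(connectivity: int = 26):
    """3-D binary structure for 6/18/26-connectivity component labeling."""
    ranks = {6: 1, 18: 2, 26: 3}
    if connectivity not in ranks:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, ranks[connectivity])


@dataclass
class ClusterReport:
    """Connected-component sizes of one mask, largest first."""

    sizes: list
    connectivity: int

    @property
    def largest(self):
        return self.sizes[0] if self.sizes else 0

    @property
    def total(self):
        return int(sum(self.sizes))


def cluster_sizes(mask: np.ndarray, connectivity: int = 26) -> ClusterReport:
    """Sizes of connected components of a boolean mask, sorted descending."""
    mask = np.asarray(mask, dtype=bool)
    labeled, n = ndimage.label(mask, structure=connectivity_structure(connectivity))
    if n == 0:
        return ClusterReport(sizes=[], connectivity=connectivity)
    sizes = np.bincount(labeled.ravel())[1:]
    return ClusterReport(sizes=sorted((int(s) for s in sizes), reverse=True),
                         connectivity=connectivity)


@dataclass
class CentroidOffsets:
    """Per-voxel world-mm offsets from the containing nucleus centroid."""

    offsets: dict        # nucleus name -> (n, 3) signed offsets in mm
    mean_offset: dict    # nucleus name -> (3,) mean signed offset
    rms_distance: dict   # nucleus name -> scalar RMS euclidean distance


def centroid_offsets(mask: np.ndarray, nucleus_masks: dict,
                     affine: np.ndarray) -> CentroidOffsets:
    """Signed (x, y, z) world-mm offsets of each mask voxel from the centroid
    of the nucleus containing it, with per-nucleus mean and RMS distance.

    RMS = sqrt(mean(x^2 + y^2 + z^2)) over the mask's voxels in that nucleus.
    """
    mask = np.asarray(mask, dtype=bool)
    world = world_coordinates(mask.shape, affine)
    covered = np.zeros(mask.shape, dtype=bool)
    offsets, means, rms = {}, {}, {}
    for name, nuc in nucleus_masks.items():
        nuc = np.asarray(nuc, dtype=bool)
        covered |= nuc
        centroid = world[nuc].mean(axis=0)
        sel = mask & nuc
        if not sel.any():
            continue
        off = world[sel] - centroid
        offsets[name] = off
        means[name] = off.mean(axis=0)
        rms[name] = float(np.sqrt((off ** 2).sum(axis=1).mean()))
    stray = mask & ~covered
    if stray.any():
        ij = tuple(int(v) for v in np.argwhere(stray)[0])
        raise ValueError(f"mask voxel {ij} lies outside every nucleus")
    return CentroidOffsets(offsets=offsets, mean_offset=means, rms_distance=rms)


def _plane_index(y_mm: np.ndarray, thickness: float) -> np.ndarray:
    """Half-open coronal bins [j*t, (j+1)*t) anchored at world y = 0."""
    return np.floor(np.asarray(y_mm) / thickness).astype(int)


def plane_profile(striosome_masks, matrix_masks, nucleus_masks, affine,
                  thickness: float = 2.0, alpha: float = 0.05,
                  method: str = "holm", min_coverage: float = 0.5) -> pd.DataFrame:
    """Compartment-like volume per 2-mm coronal plane, with per-plane tests.

    For every plane, per-subject striosome-like and matrix-like volumes (mm^3)
    are compared with an unequal-variance two-tailed t-test; p-values are
    family-wise corrected over planes (Holm by default). Planes in which
    fewer than ``min_coverage`` of subjects have any nucleus voxel are
    excluded before testing.

    Parameters are per-subject lists of equal length; ``nucleus_masks`` gives
    each subject's nucleus (caudate or putamen) mask, which defines plane
    coverage.
    """
    if thickness <= 0:
        raise ValueError(f"plane thickness must be > 0 mm, got {thickness}")
    n_sub = len(striosome_masks)
    if not (len(matrix_masks) == len(nucleus_masks) == n_sub):
        raise ValueError("per-subject mask lists must have equal length")
    if n_sub < 2:
        raise ValueError("plane-wise tests need a cohort of >= 2 subjects")

    shape = np.asarray(striosome_masks[0]).shape
    y = world_coordinates(shape, affine)[..., 1]
    plane_of_voxel = _plane_index(y, thickness)
    voxel_mm3 = float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))

    planes = np.unique(plane_of_voxel[np.any([np.asarray(m, bool) for m in nucleus_masks], axis=0)])
    rows = []
    for j in sorted(planes):
        in_plane = plane_of_voxel == j
        strio_vol = np.array([np.count_nonzero(np.asarray(s, bool) & in_plane)
                              for s in striosome_masks], dtype=float) * voxel_mm3
        mat_vol = np.array([np.count_nonzero(np.asarray(m, bool) & in_plane)
                            for m in matrix_masks], dtype=float) * voxel_mm3
        has_data = np.array([np.any(np.asarray(n, bool) & in_plane)
                             for n in nucleus_masks])
        rows.append({
            "plane_mm": float(j * thickness),
            "striosome_volume_mm3": float(strio_vol.mean()),
            "matrix_volume_mm3": float(mat_vol.mean()),
            "n_subjects_with_data": int(has_data.sum()),
            "_strio": strio_vol, "_mat": mat_vol,
        })

    table = pd.DataFrame(rows).sort_values("plane_mm").reset_index(drop=True)
    table["included"] = table["n_subjects_with_data"] >= min_coverage * n_sub

    t_vals, p_vals = [], []
    for _, row in table.iterrows():
        if not row["included"]:
            t_vals.append(np.nan)
            p_vals.append(np.nan)
            continue
        s, m = row["_strio"], row["_mat"]
        if np.allclose(s, m) or (s.std(ddof=1) == 0 and m.std(ddof=1) == 0):
            t_vals.append(0.0)
            p_vals.append(1.0)
            continue
        t, p = stats.ttest_ind(s, m, equal_var=False)
        t_vals.append(float(t))
        p_vals.append(float(p))
    table["t"] = t_vals
    table["p_uncorrected"] = p_vals

    tested = table["included"] & table["p_uncorrected"].notna()
    p_corr = np.full(len(table), np.nan)
    sig = np.zeros(len(table), dtype=bool)
    if tested.any():
        rej, adj, _, _ = multipletests(table.loc[tested, "p_uncorrected"],
                                       alpha=alpha, method=method)
        p_corr[np.flatnonzero(tested)] = adj
        sig[np.flatnonzero(tested)] = rej
    table["p_fwe"] = p_corr
    table["significant"] = sig
    return table.drop(columns=["_strio", "_mat"])
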