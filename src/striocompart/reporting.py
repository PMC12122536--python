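"""Summary metrics over significance masks and cluster tables.

Laterality (ipsilateral vs contralateral percentages of significant voxels),
total significant volumes, striosome:matrix fold ratios, and Dice overlap
between contrast maps, emitted as tidy tables and JSON-serializable dicts.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import controls
from .cli_io import world_coordinates

__all__ = ["laterality", "fold_ratio", "contrast_dsc", "laterality_table"]


def laterality(sig_mask: np.ndarray, seed_hemisphere: str, affine) -> dict:
    """Ipsilateral/contralateral split of a contrast's significant voxels.

    Ipsilateral voxels have a world-x sign matching the seed hemisphere
    (RAS: x < 0 left, x > 0 right). Voxels exactly on the midline count as
    ipsilateral; their number is reported. An empty mask yields a zero row
    with undefined (NaN) percentages.
    """
    if seed_hemisphere not in ("L", "R"):
        raise ValueError(f"seed_hemisphere must be 'L' or 'R', got {seed_hemisphere!r}")
    sig_mask = np.asarray(sig_mask, dtype=bool)
    voxel_mm3 = float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))
    total = int(sig_mask.sum())
    if total == 0:
        return {"seed_hemisphere": seed_hemisphere, "ipsilateral_pct": float("nan"),
                "contralateral_pct": float("nan"), "total_voxels": 0,
                "total_mm3": 0.0, "n_midline": 0}
    x = world_coordinates(sig_mask.shape, affine)[..., 0][sig_mask]
    midline = x == 0
    same_side = (x < 0) if seed_hemisphere == "L" else (x > 0)
    ipsi = int((same_side | midline).sum())
    return {
        "seed_hemisphere": seed_hemisphere,
        "ipsilateral_pct": 100.0 * ipsi / total,
        "contralateral_pct": 100.0 * (total - ipsi) / total,
        "total_voxels": total,
        "total_mm3": total * voxel_mm3,
        "n_midline": int(midline.sum()),
    }


def laterality_table(sig_masks: dict, affine) -> pd.DataFrame:
    """Laterality rows for a set of contrasts keyed by seed name
    (e.g. 'L-STR>L-MAT'); the seed hemisphere is the contrast's first
    character."""
    rows = []
    for name, mask in sig_masks.items():
        row = laterality(mask, name[0], affine)
        row = {"contrast": name, **row}
        rows.append(row)
    return pd.DataFrame(rows)


def fold_ratio(striosome_volumes, matrix_volumes) -> float:
    """Striosome:matrix dominance ratio from significant-cluster volumes.

    Sums each side (scalars or iterables accepted) and reports the quotient
    with the presentation convention: one decimal below 10, nearest integer
    at 10 or above. A zero denominator is reported as infinity.
    """
    s = float(np.sum(np.asarray(striosome_volumes, dtype=float)))
    m = float(np.sum(np.asarray(matrix_volumes, dtype=float)))
    if s < 0 or m < 0:
        raise ValueError("volumes must be non-negative")
    if m == 0:
        return math.inf
    ratio = s / m
    return float(round(ratio)) if ratio >= 10 else round(ratio, 1)


def contrast_dsc(mask_a: np.ndarray, mask_b: np.ndarray,
                 atlas: np.ndarray = None, atlas_names: dict = None):
    """Dice similarity coefficient between two contrast significance masks.

    Delegates to the controls module. With an integer atlas labeling and a
    code -> name map, also reports which named regions the overlap touches.
    """
    d = controls.dsc(mask_a, mask_b)
    if atlas is None:
        return d
    overlap = np.asarray(mask_a, bool) & np.asarray(mask_b, bool)
    codes = np.unique(np.asarray(atlas)[overlap])
    codes = [int(c) for c in codes if c != 0]
    names = [atlas_names.get(c, str(c)) for c in codes] if atlas_names else codes
    return d, names
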