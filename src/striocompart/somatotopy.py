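"""Leave-one-out (N-1) somatotopic mapping of bait-region contributions.

Re-parcellating the striatum with one bait region left out and subtracting
the cohort-averaged N-1 bias map from the full-bait-set average isolates
that region's contribution to compartment-like bias. A winner-take-all
segmentation of the ten contribution maps yields coarse somatotopic zones;
amplitude thresholding within each zone yields refined 50-100-voxel zones
whose left/right volumes are matched within a few voxels. A linear-model
ANOVA then tests whether the striosome-like volume fraction inside each
zone follows the zone's compartment class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellation import (MATRIX, STRIOSOME, TargetCountMaps, classify_voxels,
                           compute_bias, n1_parcellate)

__all__ = [
    "ContributionMap",
    "ZoneLabels",
    "contribution_maps",
    "segment_zones",
    "refine_zones",
    "fwhm_volume",
    "zone_bias_anova",
    "permute_zone_classes",
]


@dataclass
class ContributionMap:
    """Cohort-average full-set bias minus N-1 bias for one bait region.

    ``delta`` is stored signed (positive where removing the region lowered
    P); ``own_amplitude`` flips the sign for matrix-favoring regions so that
    positive always means "pushed bias toward the region's own class"."""

    region: str
    favored: str  # "striosome" | "matrix"
    delta: np.ndarray

    @property
    def own_amplitude(self):
        return self.delta if self.favored == "striosome" else -self.delta


@dataclass
class ZoneLabels:
    """Winner-take-all somatotopic zones.

    ``coarse`` holds 1-based region indices (0 = no positive contribution);
    ``regions`` maps index -> region name; ``refined`` maps (region,
    hemisphere) -> boolean mask."""

    coarse: np.ndarray
    regions: dict
    refined: dict = field(default_factory=dict)


def _cohort_average_bias(cohort_counts, leave_out=None):
    acc = None
    n = None
    for counts in cohort_counts:
        bias = (compute_bias(counts) if leave_out is None
                else n1_parcellate(counts, leave_out))
        p = bias.p_striosome
        if acc is None:
            acc = np.zeros(p.shape)
            n = np.zeros(p.shape)
        defined = np.isfinite(p)
        acc[defined] += p[defined]
        n += defined
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(n > 0, acc / np.maximum(n, 1), np.nan)
    return avg


def contribution_maps(cohort_counts: list, baits=None) -> dict:
    """One contribution map per bait region: Avg(P, all baits) - Avg(P, N-1).

    Cohort averaging happens before subtraction. ``baits`` may be a
    BaitRegionSet; by default the region list is taken from the first
    subject's count maps.
    """
    if not cohort_counts:
        raise ValueError("cohort must contain at least one subject")
    first: TargetCountMaps = cohort_counts[0]
    if baits is not None:
        names = list(baits.names)
        favored = dict(baits.favored)
    else:
        names = first.regions()
        favored = dict(first.favored)
    missing = set(names) - set(first.counts)
    if missing:
        raise ValueError(f"regions absent from count maps: {sorted(missing)}")

    full = _cohort_average_bias(cohort_counts)
    maps = {}
    for name in names:
        n1 = _cohort_average_bias(cohort_counts, leave_out=name)
        maps[name] = ContributionMap(region=name, favored=favored[name],
                                     delta=full - n1)
    return maps


def segment_zones(maps: dict) -> ZoneLabels:
    """Winner-take-all coarse zones: per voxel, the region whose own-class
    contribution amplitude is maximal (ties broken by region list order);
    0 where no region has a positive contribution."""
    if len(maps) < 2:
        raise ValueError("zone segmentation needs at least two contribution maps")
    names = list(maps)
    stack = np.stack([np.nan_to_num(maps[n].own_amplitude, nan=0.0)
                      for n in names])
    best = np.argmax(stack, axis=0)  # first max wins: region list order
    best_val = np.take_along_axis(stack, best[None], axis=0)[0]
    coarse = np.where(best_val > 0, best + 1, 0).astype(np.int16)
    return ZoneLabels(coarse=coarse,
                      regions={i + 1: n for i, n in enumerate(names)})


def _top_k_mask(amplitude, candidates, k):
    """Boolean mask of the k largest-amplitude candidate voxels
    (ties: flat index ascending)."""
    flat = np.flatnonzero(candidates.ravel())
    amp = amplitude.ravel()[flat]
    order = np.lexsort((flat, -amp))
    mask = np.zeros(amplitude.shape, dtype=bool)
    mask.ravel()[flat[order[:k]]] = True
    return mask


def refine_zones(maps: dict, labels: ZoneLabels, hemispheres: dict,
                 percentile: float = 50.0, target_size=(50, 100),
                 lr_tolerance: int = 3) -> ZoneLabels:
    """Refine each coarse zone to its most-contributing voxels.

    Within each coarse zone and hemisphere the initial cut keeps voxels whose
    own-class amplitude exceeds ``percentile`` % of the zone's maximum
    amplitude; the cut is then adjusted so the refined zone holds between
    ``target_size`` voxels (preferring the largest size in range — keep the
    top-k by amplitude). Left/right volumes are finally matched within
    ``lr_tolerance`` voxels by trimming the larger side's lowest-amplitude
    voxels. Zones that cannot reach the minimum size are dropped with a
    warning. No cluster-forming is applied.
    """
    lo, hi = target_size
    refined = {}
    for idx, region in labels.regions.items():
        amp = np.nan_to_num(maps[region].own_amplitude, nan=0.0)
        per_side = {}
        for side, hemi in hemispheres.items():
            zone = (labels.coarse == idx) & np.asarray(hemi, dtype=bool)
            positive = zone & (amp > 0)
            n_pos = int(positive.sum())
            if n_pos < lo:
                warnings.warn(
                    f"zone {region}/{side}: only {n_pos} positive-amplitude "
                    f"voxels (< {lo}); zone dropped")
                per_side = {}
                break
            cut = (percentile / 100.0) * float(amp[positive].max())
            supra = positive & (amp >= cut)
            n = int(supra.sum())
            if n > hi:
                supra = _top_k_mask(amp, positive, hi)
            elif n < lo:
                supra = _top_k_mask(amp, positive, min(hi, n_pos))
            per_side[side] = supra
        if not per_side:
            continue
        sizes = {s: int(m.sum()) for s, m in per_side.items()}
        if len(sizes) == 2:
            while abs(sizes["L"] - sizes["R"]) > lr_tolerance:
                big = "L" if sizes["L"] > sizes["R"] else "R"
                m = per_side[big]
                flat = np.flatnonzero(m.ravel())
                worst = flat[np.lexsort((flat, amp.ravel()[flat]))[0]]
                m.ravel()[worst] = False
                sizes[big] -= 1
        for side, m in per_side.items():
            refined[(region, side)] = m
    return ZoneLabels(coarse=labels.coarse, regions=labels.regions,
                      refined=refined)


def fwhm_volume(cmap: ContributionMap) -> int:
    """Full-width-at-half-maximum volume: voxels whose own-class amplitude
    exceeds half the map's maximum amplitude."""
    amp = np.nan_to_num(cmap.own_amplitude, nan=0.0)
    peak = float(amp.max())
    if peak <= 0:
        return 0
    return int(np.count_nonzero(amp > peak / 2.0))


def _zone_fraction_table(zones: ZoneLabels, subject_labels: list,
                         favored: dict) -> pd.DataFrame:
    rows = []
    for si, labels in enumerate(subject_labels):
        for (region, side), mask in zones.refined.items():
            in_zone = labels[mask]
            n_strio = int(np.sum(in_zone == STRIOSOME))
            n_mat = int(np.sum(in_zone == MATRIX))
            if n_strio + n_mat == 0:
                continue
            rows.append({
                "subject": f"s{si:03d}", "hemisphere": side, "region": region,
                "compartment": favored[region],
                "striosome_fraction": n_strio / (n_strio + n_mat),
            })
    if not rows:
        raise ValueError("all zones are empty of classified voxels")
    return pd.DataFrame(rows)


def _sum_coded(values, levels):
    """Sum-to-zero (deviation) coding: len(levels)-1 columns."""
    cols = []
    ref = levels[-1]
    for lev in levels[:-1]:
        c = np.where(values == lev, 1.0, 0.0) - np.where(values == ref, 1.0, 0.0)
        cols.append(c)
    return cols


def zone_bias_anova(zones: ZoneLabels, subject_labels: list, favored: dict):
    """ANOVA of striosome-like volume fraction within the refined zones.

    ``subject_labels`` holds per-subject compartment label grids from
    classify_voxels (P > 0.55). Explanatory factors are the zone's
    compartment class (the effect of interest), hemisphere, subject, and
    region; regions are nested within compartment classes, so the region
    nuisance is sum-coded *within* each class, leaving it orthogonal to the
    compartment contrast. The compartment F is the squared t of the
    compartment regressor against the residual. Returns ``(table, result)``
    with the per-observation fraction table and a dict holding F, dfs, p,
    and the model R^2.
    """
    import statsmodels.api as sm

    table = _zone_fraction_table(zones, subject_labels, favored)
    for factor in ("compartment", "hemisphere"):
        if table[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels")

    comp = np.where(table["compartment"] == "striosome", 0.5, -0.5)
    hemi = np.where(table["hemisphere"] == "L", 0.5, -0.5)
    cols = [np.ones(len(table)), comp, hemi]
    names = ["intercept", "compartment", "hemisphere"]
    subjects = sorted(table["subject"].unique())
    if len(subjects) > 1:
        for i, c in enumerate(_sum_coded(table["subject"].to_numpy(), subjects)):
            cols.append(c)
            names.append(f"subject[{subjects[i]}]")
    for cls in ("striosome", "matrix"):
        in_cls = table["compartment"] == cls
        regions = sorted(table.loc[in_cls, "region"].unique())
        if len(regions) > 1:
            coded = _sum_coded(table["region"].to_numpy(), regions)
            for i, c in enumerate(coded):
                cols.append(np.where(in_cls, c, 0.0))
                names.append(f"region[{cls}:{regions[i]}]")

    x = np.column_stack(cols)
    model = sm.OLS(table["striosome_fraction"].to_numpy(), x).fit()
    t_comp = float(model.tvalues[1])
    if not np.isfinite(t_comp) or model.ssr < 1e-18:
        # (numerically) zero residual variance: F is 0 for a null effect,
        # infinite otherwise
        t_comp = 0.0 if abs(float(model.params[1])) < 1e-8 else np.inf
    result = {
        "F": t_comp ** 2, "df_num": 1.0, "df_den": float(model.df_resid),
        "p": float(model.pvalues[1]), "r_squared": float(model.rsquared),
        "params": dict(zip(names, model.params)),
    }
    return table, result


def permute_zone_classes(zones: ZoneLabels, subject_labels: list,
                         favored: dict, n_perm: int = 200, seed: int = 0):
    """Null distribution of the compartment-effect F under random
    permutations of the region -> compartment-class assignment.

    Returns ``(observed_F, null_F_array, p_perm)``."""
    rng = np.random.default_rng(seed)
    regions = sorted({r for r, _ in zones.refined})
    classes = [favored[r] for r in regions]
    _, obs = zone_bias_anova(zones, subject_labels, favored)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(classes)
        fav_perm = dict(zip(regions, perm))
        try:
            _, res = zone_bias_anova(zones, subject_labels, fav_perm)
            null[i] = res["F"]
        except ValueError:  # a permutation collapsed a factor level
            null[i] = np.nan
    valid = null[np.isfinite(null)]
    p_perm = float((1 + np.sum(valid >= obs["F"])) / (1 + valid.size))
    return obs["F"], null, p_perm
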