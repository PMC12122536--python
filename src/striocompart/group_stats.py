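"""Group-level paired contrasts with cluster-level FWE by sign-flip permutation.

Per subject and hemisphere the paired difference map d = z_striosome -
z_matrix is regressed on an intercept plus mean-centered age and +-0.5-coded
sex; the intercept t statistic is the covariate-adjusted mean difference.
Supra-threshold voxels (one-sided, cluster-forming p = 0.001 by default) are
grouped into connected components, and the family-wise error rate of cluster
extent is controlled by the permutation distribution of the maximum cluster
size under random sign flips of the subject difference maps (exact under
exchangeability of d's sign; no smoothness estimation required).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .anatomy_metrics import connectivity_structure

__all__ = [
    "PairedDesign",
    "TMap",
    "Cluster",
    "voxelwise_t",
    "form_clusters",
    "permute_fwe",
    "contrast_suite",
    "T_CAP",
]

T_CAP = 1e6  # zero-residual voxels are capped here and flagged


@dataclass
class PairedDesign:
    """Per-subject difference maps with age/sex covariates.

    ``diffs`` is a list of 3-D arrays (one per subject, NaN where undefined);
    the analysis mask is the intersection of every subject's defined voxels.
    Age is mean-centered and sex coded +-0.5 internally, so the intercept
    stays the covariate-adjusted mean difference and is invariant to adding
    a constant to every subject's covariate.
    """

    diffs: list
    age: np.ndarray
    sex: np.ndarray  # 'F'/'M', 0/1, or +-0.5 — recoded internally
    mask: np.ndarray = field(init=False)
    d_matrix: np.ndarray = field(init=False)  # (n_subjects, n_voxels)
    design: np.ndarray = field(init=False)    # (n_subjects, 3)

    def __post_init__(self):
        n = len(self.diffs)
        if n == 0:
            raise ValueError("paired design needs at least one subject")
        age = np.asarray(self.age, dtype=float)
        sex = np.asarray(self.sex)
        if age.shape != (n,) or sex.shape != (n,):
            raise ValueError("covariate rows must align with subjects")
        if sex.dtype.kind in "USO":
            sex = np.where(np.char.upper(sex.astype(str)) == "F", 0.5, -0.5)
        else:
            sex = np.asarray(sex, dtype=float)
            uniq = np.unique(sex)
            if set(uniq) <= {0.0, 1.0}:
                sex = sex - 0.5
        shape = np.asarray(self.diffs[0]).shape
        stack = np.stack([np.asarray(d, dtype=float) for d in self.diffs])
        if stack.shape[1:] != shape:
            raise ValueError("difference maps have mismatched shapes")
        self.mask = np.all(np.isfinite(stack), axis=0)
        self.d_matrix = stack[:, self.mask]
        x = np.column_stack([np.ones(n), age - age.mean(), sex])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("rank-deficient design matrix (constant covariate?)")
        self.design = x

    @property
    def n_subjects(self):
        return len(self.diffs)

    @property
    def df(self):
        return self.n_subjects - self.design.shape[1]


@dataclass
class TMap:
    t: np.ndarray        # 3-D, NaN outside the analysis mask
    df: int
    mask: np.ndarray
    n_capped: int = 0


def _fit_intercept_t(x: np.ndarray, d: np.ndarray):
    """t statistic of the intercept for d ~ x, vectorized over voxels.

    ``d`` is (n_subjects, n_voxels). Returns (t, n_capped)."""
    n, p = x.shape
    dof = n - p
    if dof < 1:
        raise ValueError(f"need more subjects than regressors: n={n}, p={p}")
    xtx_inv = np.linalg.inv(x.T @ x)
    pinv = xtx_inv @ x.T
    beta = pinv @ d
    resid = d - x @ beta
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[0, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[0] / se
    capped = se == 0
    t[capped & (beta[0] > 0)] = T_CAP
    t[capped & (beta[0] < 0)] = -T_CAP
    t[capped & (beta[0] == 0)] = 0.0
    return t, int(np.count_nonzero(capped & (beta[0] != 0)))


def voxelwise_t(design: PairedDesign) -> TMap:
    """Intercept t map of d ~ 1 + age + sex (df = n - 3)."""
    t_flat, n_capped = _fit_intercept_t(design.design, design.d_matrix)
    t = np.full(design.mask.shape, np.nan)
    t[design.mask] = t_flat
    return TMap(t=t, df=design.df, mask=design.mask, n_capped=n_capped)


@dataclass
class Cluster:
    size: int
    indices: np.ndarray   # (size, 3) voxel indices
    peak_t: float
    peak_index: tuple


def form_clusters(tmap: TMap, p_unc: float = 0.001, connectivity: int = 26,
                  direction: str = "pos") -> list:
    """Group supra-threshold voxels into connected components.

    The cluster-forming threshold is the one-sided t critical value at
    ``p_unc`` for the map's df. ``direction='pos'`` tests t > t_crit,
    ``'neg'`` tests t < -t_crit.
    """
    if not 0 < p_unc < 1:
        raise ValueError(f"p_unc must be in (0, 1), got {p_unc}")
    if direction not in ("pos", "neg"):
        raise ValueError(f"direction must be 'pos' or 'neg', got {direction!r}")
    t_crit = float(stats.t.isf(p_unc, tmap.df))
    signed = tmap.t if direction == "pos" else -tmap.t
    supra = np.isfinite(signed) & (signed > t_crit)
    labeled, n = ndimage.label(supra, structure=connectivity_structure(connectivity))
    clusters = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labeled == lab)
        vals = signed[tuple(idx.T)]
        peak = idx[np.argmax(vals)]
        clusters.append(Cluster(size=int(idx.shape[0]), indices=idx,
                                peak_t=float(tmap.t[tuple(peak)]),
                                peak_index=tuple(int(v) for v in peak)))
    clusters.sort(key=lambda c: (-c.size, c.peak_index))
    return clusters


def _max_cluster_size(t_flat: np.ndarray, mask: np.ndarray, t_crit: float,
                      structure) -> int:
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = t_flat > t_crit
    if not supra.any():
        return 0
    labeled, n = ndimage.label(supra, structure=structure)
    return int(np.bincount(labeled.ravel())[1:].max())


def permute_fwe(design: PairedDesign, p_unc: float = 0.001,
                connectivity: int = 26, n_perm: int = 1000,
                alpha: float = 0.05, seed: int = 0,
                direction: str = "pos", contrast: str = "",
                affine=None) -> pd.DataFrame:
    """Cluster table with FWE p-values from the sign-flip permutation null.

    The null distribution of the maximum supra-threshold cluster size is
    built from ``n_perm`` random sign-flips of the subject difference maps
    (covariates refit each permutation); FWE p = (1 + #{perm max >= observed
    size}) / (1 + n_perm). Significant clusters satisfy p < alpha.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if (1.0 / (1 + n_perm)) > alpha:
        raise ValueError(
            f"n_perm={n_perm} cannot resolve alpha={alpha}: the smallest "
            f"attainable p is {1.0 / (1 + n_perm):.4f}")

    tmap = voxelwise_t(design)
    clusters = form_clusters(tmap, p_unc=p_unc, connectivity=connectivity,
                             direction=direction)
    t_crit = float(stats.t.isf(p_unc, tmap.df))
    structure = connectivity_structure(connectivity)

    rng = np.random.default_rng(seed)
    x = design.design
    d = design.d_matrix
    sign_of = 1.0 if direction == "pos" else -1.0
    null_max = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=design.n_subjects)
        t_flat, _ = _fit_intercept_t(x, d * flips[:, None])
        null_max[i] = _max_cluster_size(sign_of * t_flat, design.mask,
                                        t_crit, structure)

    voxel_mm3 = (float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))
                 if affine is not None else 1.0)
    rows = []
    for cid, c in enumerate(clusters, start=1):
        p_fwe = float((1 + np.sum(null_max >= c.size)) / (1 + n_perm))
        peak = np.asarray(c.peak_index, dtype=float)
        if affine is not None:
            peak = (np.asarray(affine)[:3, :3] @ peak) + np.asarray(affine)[:3, 3]
        rows.append({
            "contrast": contrast, "cluster_id": cid, "size_voxels": c.size,
            "volume_mm3": c.size * voxel_mm3, "peak_t": c.peak_t,
            "peak_x_mm": float(peak[0]), "peak_y_mm": float(peak[1]),
            "peak_z_mm": float(peak[2]),
            "p_fwe": p_fwe, "significant": p_fwe < alpha,
        })
    columns = ["contrast", "cluster_id", "size_voxels", "volume_mm3", "peak_t",
               "peak_x_mm", "peak_y_mm", "peak_z_mm", "p_fwe", "significant"]
    return pd.DataFrame(rows, columns=columns)


# the four directional contrasts and their seed-pair hemisphere
CONTRASTS = (
    ("L-STR>L-MAT", "L", "pos"), ("L-MAT>L-STR", "L", "neg"),
    ("R-STR>R-MAT", "R", "pos"), ("R-MAT>R-STR", "R", "neg"),
)


def contrast_suite(subject_zmaps: list, covariates: pd.DataFrame,
                   p_unc: float = 0.001, connectivity: int = 26,
                   n_perm: int = 1000, alpha: float = 0.05, seed: int = 0,
                   affine=None) -> dict:
    """All four directional compartment contrasts.

    ``subject_zmaps`` is a list (one entry per subject) of dicts mapping
    seed name (L-STR, L-MAT, R-STR, R-MAT) -> ZMap. Returns contrast name ->
    dict with the cluster table, the thresholded significance mask, the t
    map, and run metadata. Both directions of a hemisphere share one sign-
    flip null (the permutation engine is antisymmetric under d -> -d).
    """
    missing = [i for i, maps in enumerate(subject_zmaps)
               if not {"L-STR", "L-MAT", "R-STR", "R-MAT"} <= set(maps)]
    if missing:
        raise ValueError(f"subjects at positions {missing} lack one of the four seed maps")
    age = covariates["age"].to_numpy()
    sex = covariates["sex"].to_numpy()

    results = {}
    for hemi_i, side in enumerate(("L", "R")):
        diffs = [maps[f"{side}-STR"].z - maps[f"{side}-MAT"].z
                 for maps in subject_zmaps]
        design = PairedDesign(diffs=diffs, age=age, sex=sex)
        tmap = voxelwise_t(design)
        for name, s, direction in CONTRASTS:
            if s != side:
                continue
            table = permute_fwe(design, p_unc=p_unc, connectivity=connectivity,
                                n_perm=n_perm, alpha=alpha,
                                seed=seed + hemi_i, direction=direction,
                                contrast=name, affine=affine)
            sig_mask = np.zeros(design.mask.shape, dtype=bool)
            clusters = form_clusters(tmap, p_unc=p_unc,
                                     connectivity=connectivity,
                                     direction=direction)
            sig_ids = set(table.loc[table["significant"], "cluster_id"])
            for cid, c in enumerate(clusters, start=1):
                if cid in sig_ids:
                    sig_mask[tuple(c.indices.T)] = True
            results[name] = {
                "clusters": table, "sig_mask": sig_mask, "tmap": tmap,
                "meta": {"n_perm": n_perm, "alpha": alpha, "p_unc": p_unc,
                         "seed": seed + hemi_i, "engine": "sign-flip permutation",
                         "n_subjects": design.n_subjects},
            }
    return results
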