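"""Synthetic cohort generator with planted striosome/matrix ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable by recovery of planted truth:

* striatum geometry — two nuclei (caudate, putamen) per hemisphere on a
  common RAS grid, with an island-like striosome compartment occupying
  ~15% of striatal volume and enriched rostrally, ventrally and medially,
  embedded in one contiguous matrix per nucleus;
* streamline counts — per bait region, Poisson (or negative-binomial)
  counts whose class-summed expectation favors the voxel's true compartment
  by a fixed odds ratio, spatially mixed by a Gaussian partial-volume
  kernel, and modulated by bait-specific somatotopic envelopes that are
  mirror-symmetric between hemispheres;
* BOLD — striosome voxels share a latent time course with ipsilateral
  network nodes and matrix voxels with contralateral nodes, at configurable
  coupling amplitudes;
* covariates — age uniform on 22-36 years, sex Bernoulli(0.58 female).

All randomness flows from explicit integer seeds recorded in the cohort
manifest; identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .cli_io import world_coordinates, write_volume
from .parcellation import TargetCountMaps

__all__ = [
    "StriatumSpec",
    "GroundTruthStriatum",
    "BaitRegionSet",
    "CountModel",
    "BoldSpec",
    "BoldSeries",
    "NetworkNode",
    "SubjectData",
    "generate_striatum",
    "generate_counts",
    "generate_bold",
    "default_network_nodes",
    "simulate_subject",
    "write_cohort",
]

BACKGROUND = 0
CAUDATE_L, CAUDATE_R, PUTAMEN_L, PUTAMEN_R = 1, 2, 3, 4
NUCLEUS_NAMES = {
    CAUDATE_L: "caudate-L", CAUDATE_R: "caudate-R",
    PUTAMEN_L: "putamen-L", PUTAMEN_R: "putamen-R",
}
COMP_NONE, COMP_STRIOSOME, COMP_MATRIX = 0, 1, 2

# nucleus ellipsoids as fractions of the grid half-extent, left hemisphere
# (x mirrored for the right): center (cx, cy, cz) and semi-axes (ax, ay, az)
_NUCLEUS_GEOMETRY = {
    "caudate": ((-0.35, 0.20, 0.15), (0.22, 0.50, 0.32)),
    "putamen": ((-0.68, -0.05, -0.10), (0.24, 0.45, 0.34)),
}
_MIN_NUCLEUS_VOXELS = 40


@dataclass(frozen=True)
class StriatumSpec:
    grid_shape: tuple = (40, 50, 40)
    voxel_size: float = 1.25
    striosome_fraction: float = 0.15
    gradient_strength: float = 6.0
    island_radius: int = 2
    rng_seed: int = 0

    def validate(self):
        if not 0 < self.striosome_fraction < 1:
            raise ValueError(
                f"striosome_fraction must be in (0, 1), got {self.striosome_fraction}")
        if self.island_radius < 1:
            raise ValueError("island_radius must be a positive voxel count")
        if self.gradient_strength < 0:
            raise ValueError("gradient_strength must be >= 0")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0 mm")
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 4:
            raise ValueError(f"grid_shape must be 3-D, got {self.grid_shape}")
        return self

    @property
    def affine(self):
        """RAS affine centering the grid on the world origin (midline x = 0)."""
        shape = np.asarray(self.grid_shape, dtype=float)
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        aff[:3, 3] = -(shape - 1) / 2.0 * self.voxel_size
        return aff


@dataclass
class GroundTruthStriatum:
    """Labeled grids: nucleus identity and true compartment per voxel."""

    nucleus_labels: np.ndarray
    compartment_labels: np.ndarray
    affine: np.ndarray
    spec: StriatumSpec = None

    @property
    def striatum_mask(self):
        return self.nucleus_labels != BACKGROUND

    def hemisphere_mask(self, side):
        if side == "L":
            return np.isin(self.nucleus_labels, (CAUDATE_L, PUTAMEN_L))
        if side == "R":
            return np.isin(self.nucleus_labels, (CAUDATE_R, PUTAMEN_R))
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")

    def nucleus_mask(self, code):
        return self.nucleus_labels == code

    @property
    def striosome_mask(self):
        return self.compartment_labels == COMP_STRIOSOME

    @property
    def matrix_mask(self):
        return self.compartment_labels == COMP_MATRIX


@dataclass(frozen=True)
class BaitRegionSet:
    """Competing tractography targets with histologic compartment preference.

    ``dispersed`` marks regions whose somatotopic influence is deliberately
    broader than the rest (in tissue: basal operculum, basolateral amygdala).
    """

    regions: tuple = (
        ("pOFC", "striosome"), ("rIns", "striosome"), ("BLA", "striosome"),
        ("bOperc", "striosome"), ("pFus", "striosome"),
        ("SMA", "matrix"), ("M1", "matrix"), ("S1", "matrix"),
        ("SPC", "matrix"), ("IFGop", "matrix"),
    )
    dispersed: tuple = ("BLA", "bOperc")

    def __post_init__(self):
        names = [n for n, _ in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("bait region names must be unique")
        bad = {c for _, c in self.regions} - {"striosome", "matrix"}
        if bad:
            raise ValueError(f"invalid favored class(es): {sorted(bad)}")
        for cls in ("striosome", "matrix"):
            if not any(c == cls for _, c in self.regions):
                raise ValueError(f"no bait region favors {cls!r}")

    @property
    def names(self):
        return [n for n, _ in self.regions]

    @property
    def favored(self):
        return dict(self.regions)

    def by_class(self, cls):
        return [n for n, c in self.regions if c == cls]


@dataclass(frozen=True)
class CountModel:
    base_rate: float = 50.0
    bias_odds: float = 9.0
    partial_volume_sigma: float = 1.25  # mm; one diffusion voxel by default
    noise_family: str = "poisson"
    dispersion: float = 0.1
    zone_sigma_mm: float = 3.5
    zone_floor: float = 0.05
    dispersed_multiplier: float = 1.5

    def validate(self):
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if self.bias_odds < 1:
            raise ValueError("bias_odds must be >= 1")
        if self.partial_volume_sigma < 0:
            raise ValueError("partial_volume_sigma must be >= 0 mm")
        if self.noise_family not in ("poisson", "negative-binomial"):
            raise ValueError(f"unknown noise_family {self.noise_family!r}")
        if self.noise_family == "negative-binomial" and self.dispersion <= 0:
            raise ValueError("negative-binomial dispersion must be > 0")
        return self


@dataclass
class NetworkNode:
    mask: np.ndarray
    hemisphere: str  # 'L' or 'R'
    network: str     # 'DMN' | 'SN' | 'FPN'


@dataclass(frozen=True)
class BoldSpec:
    n_timepoints: int = 2400
    tr_seconds: float = 0.72
    network_nodes: dict = None  # name -> NetworkNode; None = defaults
    coupling: tuple = (
        (("striosome", "ipsi"), 0.5), (("striosome", "contra"), 0.0),
        (("matrix", "ipsi"), 0.0), (("matrix", "contra"), 0.5),
    )
    noise_sd: float = 1.0
    rng_seed: int = 0

    def coupling_dict(self):
        return dict(self.coupling)

    def validate(self):
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        c = self.coupling_dict()
        for comp in ("striosome", "matrix"):
            a_i = c.get((comp, "ipsi"), 0.0)
            a_c = c.get((comp, "contra"), 0.0)
            if not (0 <= a_i < 1 and 0 <= a_c < 1):
                raise ValueError("coupling amplitudes must be in [0, 1)")
            if a_i ** 2 + a_c ** 2 >= 1:
                raise ValueError(
                    f"coupling for {comp} yields an invalid (non-PSD) covariance: "
                    f"ipsi^2 + contra^2 = {a_i ** 2 + a_c ** 2:.3f} >= 1")
        return self


@dataclass
class BoldSeries:
    data: np.ndarray        # 4-D (x, y, z, t), float32
    tr_seconds: float
    brain_mask: np.ndarray  # 3-D boolean

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4-D, got {self.data.ndim}-D")
        if self.data.shape[3] < 3:
            raise ValueError("BOLD series needs at least 3 timepoints")


# ---------------------------------------------------------------------------
# striatum geometry
# ---------------------------------------------------------------------------

def _nucleus_label_grid(spec: StriatumSpec):
    """Assign voxels to the four nuclei by smallest normalized ellipsoid
    coordinate, which keeps nuclei disjoint even if ellipsoids touch."""
    world = world_coordinates(spec.grid_shape, spec.affine)
    half = (np.asarray(spec.grid_shape, dtype=float) - 1) / 2.0 * spec.voxel_size
    best = np.full(spec.grid_shape, np.inf)
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    codes = {("caudate", "L"): CAUDATE_L, ("caudate", "R"): CAUDATE_R,
             ("putamen", "L"): PUTAMEN_L, ("putamen", "R"): PUTAMEN_R}
    for nucleus, (center_f, semi_f) in _NUCLEUS_GEOMETRY.items():
        for side, sign in (("L", 1.0), ("R", -1.0)):
            center = np.array(center_f) * half
            center[0] *= sign
            semi = np.array(semi_f) * half
            d2 = np.sum(((world - center) / semi) ** 2, axis=-1)
            inside = d2 <= 1.0
            take = inside & (d2 < best)
            labels[take] = codes[(nucleus, side)]
            best[take] = d2[take]
    return labels


def _location_score(coords, hemisphere_sign):
    """Rostro-ventro-medial enrichment score in [0, 1] within one nucleus.

    The rostral and ventral axes dominate (the nuclei are elongated along
    them, leaving room for enrichment); the medio-lateral gradient is
    weaker, as it is in tissue."""
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    medial = -hemisphere_sign * x  # larger toward the midline
    parts = []
    for v in (y, -z, medial):      # rostral, ventral, medial
        span = v.max() - v.min()
        parts.append((v - v.min()) / span if span > 0 else np.zeros_like(v))
    w = np.array([0.5, 0.3, 0.2])
    return np.tensordot(w, np.asarray(parts), axes=1)


def generate_striatum(spec: StriatumSpec) -> GroundTruthStriatum:
    """Plant striosome islands in a two-nuclei-per-hemisphere striatum.

    Island centers are drawn from a spatial intensity increasing rostrally,
    ventrally and medially (weight exp(gradient_strength * score)); each
    island is a ball of ``island_radius`` voxels, the last one filled
    partially (nearest voxels first) so the per-nucleus striosome count hits
    round(striosome_fraction * nucleus volume) exactly.
    """
    spec.validate()
    labels = _nucleus_label_grid(spec)
    for code, name in NUCLEUS_NAMES.items():
        n = int((labels == code).sum())
        if n < _MIN_NUCLEUS_VOXELS:
            raise ValueError(
                f"grid {spec.grid_shape} too small to place both nuclei per "
                f"hemisphere: nucleus {name} has {n} voxels "
                f"(< {_MIN_NUCLEUS_VOXELS})")

    rng = np.random.default_rng(spec.rng_seed)
    world = world_coordinates(spec.grid_shape, spec.affine)
    compartments = np.zeros(spec.grid_shape, dtype=np.uint8)
    compartments[labels != BACKGROUND] = COMP_MATRIX

    def _ball(radius):
        offs = [(di, dj, dk)
                for di in range(-radius, radius + 1)
                for dj in range(-radius, radius + 1)
                for dk in range(-radius, radius + 1)
                if di * di + dj * dj + dk * dk <= radius * radius]
        offs.sort(key=lambda d: (d[0] ** 2 + d[1] ** 2 + d[2] ** 2, d))
        return np.array(offs)

    balls = {radius: _ball(radius) for radius in range(1, spec.island_radius + 1)}

    n_bins = 5
    cap_fraction = 0.30  # max striosome occupancy of one score bin

    for code in NUCLEUS_NAMES:
        nucleus = labels == code
        vox = np.argwhere(nucleus)
        coords = world[nucleus]
        sign = 1.0 if code in (CAUDATE_R, PUTAMEN_R) else -1.0
        score = _location_score(coords, sign)
        target = int(round(spec.striosome_fraction * vox.shape[0]))

        # density gradient by quota: split the nucleus into score-quantile
        # bins and allot striosome volume proportional to exp(g * score),
        # capped by local packing capacity (hard island spacing would
        # otherwise flatten any placement-probability gradient)
        order = np.argsort(np.argsort(score, kind="stable"), kind="stable")
        bin_of = np.minimum((order * n_bins) // vox.shape[0], n_bins - 1)
        bin_sizes = np.bincount(bin_of, minlength=n_bins).astype(float)
        w_bin = np.array([
            np.exp(spec.gradient_strength * score[bin_of == b].mean())
            if bin_sizes[b] else 0.0 for b in range(n_bins)])
        quota = target * (w_bin * bin_sizes) / (w_bin * bin_sizes).sum()
        cap = cap_fraction * bin_sizes
        for _ in range(20):  # redistribute overflow above the capacity cap
            over = np.maximum(quota - cap, 0.0)
            if over.sum() < 0.5:
                break
            quota = np.minimum(quota, cap)
            room = np.maximum(cap - quota, 0.0)
            if room.sum() == 0:
                break
            quota += over.sum() * room / room.sum()
        deficit = quota.copy()

        placed = 0
        centers = []   # (index triple, radius)
        while placed < target:
            avail = compartments[tuple(vox.T)] == COMP_MATRIX
            if not avail.any():  # nucleus saturated; unreachable for fraction < 1
                break
            # shrink the island until a site with a >= 2-voxel gap to every
            # existing island exists (gap 2 keeps islands disconnected even
            # under 26-connectivity); at radius 1 fall back to any site
            for radius in range(spec.island_radius, 0, -1):
                if centers:
                    cvox = np.array([c for c, _ in centers])
                    cr = np.array([cradius for _, cradius in centers])
                    d2 = ((vox[:, None, :] - cvox[None, :, :]) ** 2).sum(-1)
                    spaced = avail & np.all(d2 >= (cr + radius + 2) ** 2, axis=1)
                else:
                    spaced = avail
                if spaced.any():
                    pool = spaced
                    break
            else:
                radius, pool = 1, avail
            # aim at the score bin furthest behind its quota; fall back to
            # any admissible site if that bin is exhausted
            bin_order = np.argsort(-deficit, kind="stable")
            w = np.zeros(vox.shape[0])
            for b in bin_order:
                in_bin = pool & (bin_of == b)
                if in_bin.any():
                    w[in_bin] = 1.0
                    break
            if not w.any():
                w = pool.astype(float)
            center = vox[rng.choice(vox.shape[0], p=w / w.sum())]
            centers.append((center, radius))
            cand = center + balls[radius]
            ok = np.all((cand >= 0) & (cand < np.array(spec.grid_shape)), axis=1)
            cand = cand[ok]
            cand = cand[labels[tuple(cand.T)] == code]
            cand = cand[compartments[tuple(cand.T)] == COMP_MATRIX]
            take = cand[: target - placed]
            compartments[tuple(take.T)] = COMP_STRIOSOME
            placed += take.shape[0]
            if take.shape[0]:
                taken_flat = {tuple(t) for t in take}
                sel = np.fromiter((tuple(v) in taken_flat for v in vox),
                                  dtype=bool, count=vox.shape[0])
                np.subtract.at(deficit, bin_of[sel], 1.0)

    return GroundTruthStriatum(
        nucleus_labels=labels, compartment_labels=compartments,
        affine=spec.affine, spec=spec)


# ---------------------------------------------------------------------------
# streamline counts
# ---------------------------------------------------------------------------

def _bait_envelopes(gt: GroundTruthStriatum, baits: BaitRegionSet,
                    model: CountModel):
    """Per-bait somatotopic envelopes, normalized so each class sums to 1 at
    every striatal voxel (the class-level bias ratio is then exactly
    ``bias_odds`` regardless of location)."""
    world = world_coordinates(gt.nucleus_labels.shape, gt.affine)
    env = {}
    for side in ("L", "R"):
        hemi = gt.hemisphere_mask(side)
        if not hemi.any():
            continue
        coords = world[hemi]
        y = coords[:, 1]
        x, z = coords[:, 0], coords[:, 2]
        medial_q = 0.8 if side == "L" else 0.2  # toward x = 0 from either side
        n_per_class = {cls: max(len(baits.by_class(cls)), 1)
                       for cls in ("striosome", "matrix")}
        class_rank = {cls: 0 for cls in ("striosome", "matrix")}
        for name, cls in baits.regions:
            # anchors interleave the two classes along the rostro-caudal
            # axis (same-class anchors stay well separated), mirrored L/R;
            # striosome-favoring anchors sit ventro-medially (where the
            # striosome gradient concentrates), matrix-favoring dorso-laterally
            i = class_rank[cls]
            class_rank[cls] += 1
            offset = 0.5 if cls == "striosome" else 1.5
            q = 0.15 + 0.7 * (2 * i + offset) / (2 * n_per_class[cls])
            if cls == "striosome":
                x_anchor = np.quantile(x, medial_q)
                z_anchor = np.quantile(z, 0.3)
            else:
                x_anchor = np.quantile(x, 1.0 - medial_q)
                z_anchor = np.quantile(z, 0.7)
            anchor = np.array([x_anchor, np.quantile(y, q), z_anchor])
            sigma = model.zone_sigma_mm
            if name in baits.dispersed:
                sigma *= model.dispersed_multiplier
            d2 = ((coords - anchor) ** 2).sum(axis=1)
            e = model.zone_floor + (1 - model.zone_floor) * np.exp(-d2 / (2 * sigma ** 2))
            grid = env.setdefault(name, np.zeros(gt.nucleus_labels.shape))
            grid[hemi] = e
    # normalize within each favored class
    for cls in ("striosome", "matrix"):
        names = baits.by_class(cls)
        total = sum(env[n] for n in names)
        for n in names:
            with np.errstate(invalid="ignore", divide="ignore"):
                env[n] = np.where(total > 0, env[n] / total, 0.0)
    return env


def generate_counts(gt: GroundTruthStriatum, baits: BaitRegionSet,
                    model: CountModel, seed: int) -> TargetCountMaps:
    """Simulate per-bait streamline-count grids over the striatum.

    Expected class-summed counts at a pure voxel favor the voxel's true
    compartment by ``bias_odds``; expectations are blurred by a Gaussian
    kernel of ``partial_volume_sigma`` mm before sampling, emulating
    partial-volume dilution at compartment borders.
    """
    model.validate()
    rng = np.random.default_rng(seed)
    striatum = gt.striatum_mask
    env = _bait_envelopes(gt, baits, model)
    sigma_vox = model.partial_volume_sigma / (gt.spec.voxel_size if gt.spec else 1.25)

    counts = {}
    for name, cls in baits.regions:
        n_class = len(baits.by_class(cls))
        favored_here = (gt.compartment_labels == (COMP_STRIOSOME if cls == "striosome"
                                                  else COMP_MATRIX))
        factor = np.where(favored_here, 1.0, 1.0 / model.bias_odds)
        lam = np.where(striatum, model.base_rate * n_class * env[name] * factor, 0.0)
        if sigma_vox > 0:
            # normalized convolution: mixing acts only within the striatum,
            # so edge voxels are not drained toward the zero exterior
            blurred = ndimage.gaussian_filter(lam, sigma=sigma_vox)
            support = ndimage.gaussian_filter(striatum.astype(float), sigma=sigma_vox)
            with np.errstate(invalid="ignore", divide="ignore"):
                lam = np.where(striatum, blurred / np.maximum(support, 1e-12), 0.0)
        lam = np.where(striatum, np.maximum(lam, 0.0), 0.0)
        if model.noise_family == "poisson":
            grid = rng.poisson(lam)
        else:
            shape = 1.0 / model.dispersion
            mixed = np.where(lam > 0, rng.gamma(shape, 1.0) * model.dispersion * lam, 0.0)
            grid = rng.poisson(mixed)
        counts[name] = grid.astype(np.int64)

    return TargetCountMaps(counts=counts, favored=baits.favored,
                           striatum_mask=striatum, affine=gt.affine)


def simulate_bundle_density(seed_mask: np.ndarray, sigma_mm: float = 3.0,
                            voxel_size: float = 1.25, amplitude: float = 100.0,
                            noise_sd: float = 1.0, seed: int = 0) -> np.ndarray:
    """Toy tract-density map for a seed mask: a Gaussian-spread copy of the
    seed (streamlines fanning out from their origin) plus positive noise.

    Deliberately minimal — it only reproduces the property that bundles
    seeded from nearby voxels occupy overlapping territory while bundles
    from distinct territories stay segregated.
    """
    seed_mask = np.asarray(seed_mask, dtype=float)
    if not seed_mask.any():
        raise ValueError("empty seed mask")
    rng = np.random.default_rng(seed)
    density = amplitude * ndimage.gaussian_filter(seed_mask, sigma_mm / voxel_size)
    density += noise_sd * np.abs(rng.standard_normal(seed_mask.shape))
    density[density < noise_sd] = 0.0
    return density


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

# default network node positions as fractions of the grid half-extent
# (left hemisphere; x mirrored for right)
_NODE_GEOMETRY = {
    "DMN": (-0.30, -0.75, 0.60),
    "SN": (-0.55, 0.70, 0.55),
    "FPN": (-0.45, -0.20, 0.80),
}


def default_network_nodes(gt: GroundTruthStriatum, half_width: int = 1) -> dict:
    """One cubic node per network and hemisphere, clear of the striatum."""
    shape = np.asarray(gt.nucleus_labels.shape)
    half = (shape - 1) / 2.0
    nodes = {}
    for network, (fx, fy, fz) in _NODE_GEOMETRY.items():
        for side, sign in (("L", 1.0), ("R", -1.0)):
            center = np.round(half + np.array([sign * fx, fy, fz]) * half).astype(int)
            lo = np.maximum(center - half_width, 0)
            hi = np.minimum(center + half_width + 1, shape)
            mask = np.zeros(tuple(shape), dtype=bool)
            mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
            if (mask & gt.striatum_mask).any():
                raise ValueError(
                    f"default node {network}-{side} overlaps the striatum; "
                    "provide explicit network_nodes for this grid")
            nodes[f"{network}-{side}"] = NetworkNode(mask=mask, hemisphere=side,
                                                     network=network)
    return nodes


def generate_bold(gt: GroundTruthStriatum, spec: BoldSpec):
    """Simulate compartment-coupled BOLD on the ground-truth grid.

    Each hemisphere carries one latent N(0,1) time course shared by its
    network nodes. A striatal voxel of compartment c in hemisphere h follows

        a_ipsi * L_h + a_contra * L_h' + sqrt(1 - a_ipsi^2 - a_contra^2) * eps

    so its expected correlation with the ipsilateral (contralateral) node
    time course equals the configured coupling amplitude. All other brain
    voxels are independent noise; every series has zero temporal mean.

    Returns ``(BoldSeries, nodes)`` where nodes maps name -> NetworkNode.
    """
    spec.validate()
    nodes = spec.network_nodes or default_network_nodes(gt)
    for name, node in nodes.items():
        if (node.mask & gt.striatum_mask).any():
            raise ValueError(f"network node {name!r} overlaps the striatum")

    rng = np.random.default_rng(spec.rng_seed)
    shape = gt.nucleus_labels.shape
    t = spec.n_timepoints
    latent = {"L": rng.standard_normal(t), "R": rng.standard_normal(t)}

    data = rng.standard_normal(shape + (t,), dtype=np.float32)
    data *= np.float32(spec.noise_sd)

    c = spec.coupling_dict()
    other = {"L": "R", "R": "L"}
    for side in ("L", "R"):
        hemi = gt.hemisphere_mask(side)
        for comp, code in (("striosome", COMP_STRIOSOME), ("matrix", COMP_MATRIX)):
            sel = hemi & (gt.compartment_labels == code)
            if not sel.any():
                continue
            a_i = c.get((comp, "ipsi"), 0.0)
            a_c = c.get((comp, "contra"), 0.0)
            resid = np.sqrt(max(1.0 - a_i ** 2 - a_c ** 2, 0.0))
            shared = a_i * latent[side] + a_c * latent[other[side]]
            n_sel = int(sel.sum())
            noise = rng.standard_normal((n_sel, t), dtype=np.float32)
            data[sel] = spec.noise_sd * (
                shared.astype(np.float32)[None, :]
                + np.float32(resid) * noise)

    for name, node in nodes.items():
        data[node.mask] = (spec.noise_sd * latent[node.hemisphere]).astype(np.float32)

    data -= data.mean(axis=3, keepdims=True)
    brain = np.ones(shape, dtype=bool)
    return BoldSeries(data=data, tr_seconds=spec.tr_seconds, brain_mask=brain), nodes


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    subject_id: str
    gt: GroundTruthStriatum
    counts: TargetCountMaps
    bold: BoldSeries
    nodes: dict
    age: int
    sex: str
    seed: int


def _subject_seeds(seed, n_subjects):
    """Independent per-subject sub-seeds (< 2^31) from one cohort seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_subjects)]


def simulate_subject(subject_id, seed, striatum_spec=None, baits=None,
                     count_model=None, bold_spec=None,
                     with_bold=True) -> SubjectData:
    """Generate one subject's ground truth, counts, BOLD and covariates."""
    striatum_spec = striatum_spec or StriatumSpec()
    baits = baits or BaitRegionSet()
    count_model = count_model or CountModel()
    bold_spec = bold_spec or BoldSpec()

    sub = np.random.SeedSequence(int(seed))
    s_geo, s_cnt, s_bold, s_cov = (int(c.generate_state(1)[0] % (2 ** 31))
                                   for c in sub.spawn(4))
    gt = generate_striatum(dataclasses.replace(striatum_spec, rng_seed=s_geo))
    counts = generate_counts(gt, baits, count_model, seed=s_cnt)
    bold, nodes = (None, None)
    if with_bold:
        bold, nodes = generate_bold(gt, dataclasses.replace(bold_spec, rng_seed=s_bold))
    rng = np.random.default_rng(s_cov)
    age = int(rng.integers(22, 37))
    sex = "F" if rng.random() < 0.58 else "M"
    return SubjectData(subject_id=str(subject_id), gt=gt, counts=counts,
                       bold=bold, nodes=nodes, age=age, sex=sex, seed=int(seed))


def write_cohort(n_subjects, out_dir, striatum_spec=None, baits=None,
                 count_model=None, bold_spec=None, seed=0):
    """Write a synthetic cohort to disk: per-subject NIfTI volumes, a TSV
    covariate table, and a JSON manifest of files and seeds."""
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    baits = baits or BaitRegionSet()

    manifest = {"seed": int(seed), "n_subjects": int(n_subjects), "subjects": []}
    covars = []
    node_files = {}
    for i, sub_seed in enumerate(_subject_seeds(seed, n_subjects)):
        sid = f"sub-{i + 1:03d}"
        subj = simulate_subject(sid, sub_seed, striatum_spec, baits,
                                count_model, bold_spec)
        files = {}
        files["labels"] = str(write_volume(
            out / f"{sid}_labels.nii.gz", subj.gt.nucleus_labels.astype(np.uint8),
            subj.gt.affine))
        files["truth"] = str(write_volume(
            out / f"{sid}_truth.nii.gz", subj.gt.compartment_labels.astype(np.uint8),
            subj.gt.affine))
        files["counts"] = {}
        for name, grid in subj.counts.counts.items():
            files["counts"][name] = str(write_volume(
                out / f"{sid}_count-{name}.nii.gz", grid.astype(np.int32),
                subj.gt.affine))
        files["bold"] = str(write_volume(
            out / f"{sid}_bold.nii.gz", subj.bold.data, subj.gt.affine,
            tr_seconds=subj.bold.tr_seconds))
        if not node_files:
            for name, node in subj.nodes.items():
                node_files[name] = str(write_volume(
                    out / f"node-{name}.nii.gz", node.mask.astype(np.uint8),
                    subj.gt.affine))
        covars.append({"subject_id": sid, "age": subj.age, "sex": subj.sex})
        manifest["subjects"].append({"subject_id": sid, "seed": subj.seed,
                                     "files": files})

    import pandas as pd

    from .cli_io import write_table
    write_table(out / "covariates.tsv", pd.DataFrame(covars))
    manifest["covariates"] = str(out / "covariates.tsv")
    manifest["nodes"] = node_files
    manifest["baits"] = {"regions": list(baits.regions),
                         "dispersed": list(baits.dispersed)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out / "manifest.json"
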