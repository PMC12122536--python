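# Methods

## The analysis this package implements

The striatum contains two interdigitated tissue compartments: the
**striosome** (~15% of striatal volume, mu-opioid-receptor-rich,
limbic-connected, arranged as islands) and the **matrix** (~85%,
calbindin-rich, sensorimotor-connected, spatially contiguous). The two
cannot be told apart in vivo by image contrast, but they can be inferred
from *differential structural connectivity*: a set of cortical/subcortical
"bait" regions is known from tract-tracing studies to project
preferentially to one compartment, so the relative number of tractography
streamlines from a striatal voxel that reach striosome-favoring versus
matrix-favoring baits indicates which compartment dominates that voxel.

The chain implemented here:

1. **Parcellation.** With summed streamline counts S (striosome-favoring
   baits) and M (matrix-favoring baits) per voxel, the striosome bias
   probability is `P = S / (S + M)` (undefined where `S + M = 0`). For
   every subject and hemisphere, the equal-volume seed masks take the k
   most striosome-biased and the k most matrix-biased voxels, with
   `k = round(0.13 * hemisphere striatal volume)` — 13% being the
   two-sided Gaussian mass beyond 1.5 standard deviations (`2*(1-Φ(1.5))
   = 0.1336`). Exactly equal mask volumes are enforced (the stricter,
   testable reading of "matched"); ties are broken by (bias desc, total
   count desc, flat voxel index asc), with the matrix-like mask chosen
   after excluding striosome-like voxels so the two are always disjoint.
2. **Anatomical validation.** Abundance at bias cutoffs P > 0.87 and
   P > 0.55, connected-component sizes (26-connectivity by default, the
   FSL face+edge+corner rule), per-voxel world-mm offsets from the
   containing nucleus centroid, and compartment volumes in 2-mm coronal
   planes (half-open bins anchored at world y = 0; planes covered by
   < 50% of the cohort are dropped; Welch t-tests with Holm family-wise
   correction).
3. **Negative controls.** Each seed voxel is jittered by an independent
   uniform integer shift in −3..+3 per axis, constrained to stay in the
   striatum and to avoid both original compartment masks; collisions are
   rejection-resampled in stable voxel order (cap 1000 draws). Bundle
   cores keep the top 25% of a density map's nonzero voxels by amplitude
   (a count quantile, not an amplitude fraction); overlap is measured by
   the Dice similarity coefficient `2|A∩B|/(|A|+|B|)` (defined 0 when both
   masks are empty).
4. **Seed-based rsFC.** The mean BOLD time course over a seed mask is
   Pearson-correlated with every non-striatal brain voxel and transformed
   to Fisher z (`z = atanh r`, with |r| clipped at 1−1e−7 so z stays
   finite). Each subject contributes four maps: L-STR, L-MAT, R-STR,
   R-MAT. Triple-network analyses mask the z maps with each network ROI
   independently.
5. **Group statistics.** Per hemisphere, the paired difference
   `d = z_striosome − z_matrix` is regressed voxel-wise on an intercept,
   mean-centered age, and sex coded ±0.5; the intercept t (df = n−3) is
   the covariate-adjusted mean difference, so it is invariant to constant
   shifts of the covariates. One-sided supra-threshold voxels (cluster-
   forming p = 0.001) form 26-connected clusters; cluster-extent FWE
   p-values come from the permutation distribution of the maximum cluster
   size under random sign flips of d (covariates refit per permutation),
   `p = (1 + #{perm max ≥ observed}) / (1 + n_perm)`. Sign-flip
   permutation replaces parametric random-field cluster inference: it is
   exact under sign exchangeability and needs no smoothness estimate.
   On small grids the max-cluster-size statistic is discrete, which makes
   the test conservative (empirical type-I ≈ 0.005–0.03 at nominal 0.05);
   it never exceeds the nominal level.
6. **Somatotopy (N-1 mapping).** For each bait region, the cohort-average
   bias map of the reduced (N-1) bait set is subtracted from the
   full-set average; the signed difference is that region's contribution.
   "Strength" is compared on the contribution toward the region's own
   class. Winner-take-all segmentation yields coarse zones (ties: region
   list order); refined zones threshold each coarse zone at 50% of its
   peak amplitude, adjust to 50–100 voxels per hemisphere (keep-top-k by
   amplitude), and match left/right volumes within 3 voxels by trimming
   the larger side's weakest voxels; no cluster-forming is applied. Zones
   that cannot reach 50 voxels are dropped with a warning. Dispersion is
   summarized as the FWHM volume (voxels above half the peak amplitude).
7. **Zone ANOVA.** Striosome-like volume fraction (of supra-threshold
   voxels at P > 0.55) per (subject, hemisphere, zone) is modeled by OLS
   on compartment class (±0.5), hemisphere (±0.5), subject (sum-coded),
   and region sum-coded *within* its class. Because regions are nested in
   classes, the within-class coding is the estimable form of a
   compartment-by-region nuisance and is orthogonal to the compartment
   contrast; the compartment F is the squared t of that regressor. A
   label-permutation helper re-assigns region→class at random to
   calibrate F against its null.
8. **Reporting.** Laterality = percentage of a contrast's significant
   voxels whose world-x sign matches the seed hemisphere (midline x = 0
   voxels count as ipsilateral and are tallied). Fold ratios divide summed
   striosome-contrast volume by summed matrix-contrast volume, printed to
   one decimal below 10 and to the nearest integer above (zero
   denominators are reported as infinite).

## The synthetic cohort

Real compartment mapping needs diffusion and functional MRI plus
tractography, none of which is reproducible at desk scale, so the package
ships a generator that plants known ground truth with the statistical
structure the analysis assumes. Testing is then recovery of planted truth.

**Geometry.** Two nuclei per hemisphere (caudate, putamen) are ellipsoids
on a common RAS grid (default 40×50×40 voxels at 1.25 mm, the diffusion
resolution of the source data; grid centered on the midline so hemispheres
are x < 0 / x > 0). Striosome islands are balls of radius 2 voxels whose
centers keep a ≥2-voxel gap (disconnected even at 26-connectivity); the
rostro-ventro-medial enrichment is enforced through per-score-quantile
quotas proportional to `exp(gradient_strength * score)` with
`score = 0.5*rostral + 0.3*ventral + 0.2*medial` (the nuclei are elongated
rostro-caudally, so that axis carries most of the gradient, as in tissue)
and a 30% local-occupancy cap — hard island spacing would otherwise
flatten any placement-probability gradient. The per-nucleus striosome
count is hit exactly (default fraction 0.15); the last island is filled
nearest-voxel-first. With ~7 discrete islands per nucleus the per-nucleus
compartment centroid offsets are sub-millimeter and noisy across seeds;
location tests therefore aggregate over seeds and nuclei.

**Counts.** Each bait has a somatotopic envelope (Gaussian around an
anchor; anchors interleave the two classes along the rostro-caudal axis,
mirrored between hemispheres, striosome anchors ventro-medial and matrix
anchors dorso-lateral; two "dispersed" baits — basolateral amygdala and
basal operculum — get 1.5× the envelope width). Envelopes are normalized
within each class so that the class-summed expected count at a pure voxel
favors the true compartment by exactly `bias_odds` (default 9) regardless
of location. Expected rates are mixed by a Gaussian partial-volume kernel
(default 1.25 mm = one voxel) using normalized convolution, so mixing acts
only within the striatum and edge voxels are not drained toward the empty
exterior. Sampling is Poisson (negative-binomial optional, gamma-mixture
parameterization). Defaults: base rate 50 streamlines per bait per voxel;
envelope width 3.5 mm; envelope floor 0.05.

**BOLD.** One latent N(0,1) time course per hemisphere, shared by that
hemisphere's network nodes (default: one cubic node per network DMN/SN/FPN
and hemisphere, placed off-striatum). A striatal voxel of compartment c in
hemisphere h follows `a_i L_h + a_c L_h' + sqrt(1 − a_i² − a_c²) ε`, so
its expected correlation with a node equals the coupling amplitude;
defaults couple striosome↔ipsilateral and matrix↔contralateral at 0.5
(requiring `a_i² + a_c² < 1`, otherwise the covariance is rejected). All
other voxels are white noise; every series has zero temporal mean. The
timepoint default (2400 at TR 0.72 s) matches the source acquisitions;
pipeline-scale runs use shorter series (see problem sizes). BOLD noise has
no spatial autocorrelation — its smoothness is not specified by any prior
here, and white noise is the conservative choice for cluster inference.

**Covariates.** Age uniform integers 22–36; sex Bernoulli with 58%
female — matching the demographic mix the method is aimed at. All
randomness descends from one cohort seed through `numpy` seed sequences;
per-subject seeds are recorded in the cohort manifest, and identical
spec + seed reproduces volumes bit-identically.

**What the generator does not emulate.** Realistic diffusion signal or
tractography (counts are sampled directly from a rate model), MRI
artifacts and physiological noise, spatially autocorrelated BOLD noise,
registration error (all volumes share one grid and affine; no resampling
is ever performed), and the anatomy of real network ROIs. Passing
recovery tests therefore shows the *inference chain* is correct under its
own assumptions, not that those assumptions hold in scanner data.

## Numerical choices and degenerate inputs

- Voxels with `S + M = 0` are excluded from selection, classification and
  bias statistics (bias undefined).
- Equal-volume selection, bundle cores, zone refinement and winner-take-
  all segmentation all break ties deterministically (amplitude, then
  count, then flat voxel index / region list order), so outputs are
  reproducible bit-for-bit.
- `r = ±1` maps to `z = atanh(1 − 1e−7)`; zero-variance voxels and the
  excluded striatum are NaN in z maps; the group mask is the intersection
  of all subjects' defined voxels.
- Zero-residual voxels in the t map are capped at ±1e6 and counted;
  a zero-residual zone ANOVA reports F = 0 (null effect) or infinity.
- The permutation engine refuses `n_perm` too small to resolve the
  requested alpha (`1/(1+n_perm) > alpha`).
- Jitter placement failures (no admissible target after 1000 draws) raise
  with the offending voxel. At high mask densities the stable-order
  collision resampling can bias mean shifts slightly; at the 13%-of-
  striatum densities used here the effect is negligible.

## Problem sizes used by the test suite and acceptance script

Unit tests run on 24×30×24 grids; recovery-style tests use the full
40×50×40 study grid. The acceptance script simulates 10 subjects at the
study grid with 300-timepoint BOLD series and 200 sign-flip permutations,
and calibrates the cluster-FWE engine on 200 null cohorts of 20 subjects
on an 8×8×8 mask with 100 permutations; these sizes were chosen so the
whole analysis reruns from scratch in about a minute on one CPU while
keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

- The equal-volume rule fixes striosome-like and matrix-like masks to the
  same size even though the true compartments are 15:85; the masks are
  therefore "most-biased exemplars", not segmentations.
- Cluster-extent FWE by sign-flip permutation is conservative on small
  grids (discrete max-cluster-size null).
- The refined-zone size window (50–100 voxels per hemisphere) may be
  unreachable for regions squeezed between dispersed neighbors; such
  zones are dropped rather than padded.
- Laterality is computed voxel-wise; the package does not distinguish
  "significant clusters" from "significant voxels" beyond reporting both
  counts and mm³.
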