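# striocompart

Connectivity-based parcellation of the human striatum into **striosome-like**
and **matrix-like** voxels, and analysis of the resting-state functional
networks seeded by each compartment.

The striatum is built from two interdigitated tissue compartments — the
striosome (~15% of volume, limbic-connected islands) and the matrix (~85%,
sensorimotor-connected, contiguous) — that are indistinguishable by image
contrast in vivo. They *can* be told apart by differential structural
connectivity: with five striosome-favoring and five matrix-favoring "bait"
target regions, the per-voxel streamline counts S and M reaching each class
give a striosome bias probability

```
P = S / (S + M)
```

and taking the most-biased 13% of each hemisphere's striatal voxels from
either end of the P distribution (13% = the two-sided Gaussian mass beyond
1.5 SD) yields equal-volume striosome-like and matrix-like seed masks per
subject. The package then: validates the parcellation against histologic
anatomy (abundance, clustering, intra-striatal location, coronal plane
profiles); runs location-jitter and bundle-core Dice negative controls;
computes seed-based resting-state functional connectivity maps (mean seed
time course → voxel-wise Pearson r → Fisher z, striatum excluded); contrasts
striosome- vs matrix-seeded maps with paired tests (age/sex covariates) and
cluster-level family-wise-error control by sign-flip permutation; maps each
bait region's somatotopic contribution with leave-one-out (N-1)
parcellations and a zone-level ANOVA; and reports laterality percentages,
significant volumes, fold ratios, and Dice overlaps.

It is aimed at researchers studying compartment-specific striatal circuitry
who want a tested, reproducible reference implementation of this analysis
chain. Because the real analysis requires diffusion + functional MRI and
probabilistic tractography, the package includes a first-class synthetic
cohort generator that plants known compartment geometry, compartment-biased
streamline counts, and compartment-coupled BOLD, so every stage is verified
by recovery of planted truth.

## Worked example

```python
from striocompart import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_timepoints=300, n_perm=200)   # desk-scale BOLD/permutations
res = run_pipeline("out", config=cfg, n_subjects=10, seed=1)

masks = res["masks"]["sub-001"]["L"]
print(masks.striosome_like.sum(), masks.matrix_like.sum())
print(res["jitter_table"].groupby("compartment")["bias_drop"].mean())
print(res["laterality"][["contrast", "ipsilateral_pct"]])
print(res["anova"]["F"], res["anova"]["p"])
```

prints (seed 1):

```
360 360
compartment
matrix       0.086672
striosome    0.332444
Name: bias_drop, dtype: float64
      contrast  ipsilateral_pct
0  L-STR>L-MAT            100.0
1  L-MAT>L-STR              0.0
2  R-STR>R-MAT            100.0
3  R-MAT>R-STR              0.0
33.75603058313719 3.250777568186684e-08
```

Reading this output: each hemisphere's two seed masks hold exactly 360
voxels (13% of that hemisphere's striatum). Randomly jittering seed voxels
by up to ±3 voxels erases far more striosome bias (−0.33) than matrix bias
(−0.087) — compartment identity lives at precise voxel locations, and the
scarce striosome is the fragile one. Striosome-seeded contrasts are
entirely ipsilateral and matrix-seeded contrasts entirely contralateral,
recovering the planted coupling. The zone ANOVA confirms that
striosome-favoring bait regions dominate zones enriched in striosome-like
voxels (F ≈ 34, p ≈ 2e-8).

A command-line interface mirrors the library
(`striocompart simulate|parcellate|jitter|dsc|gaussian-tail|run`), e.g.:

```bash
striocompart simulate --out cohort --n-subjects 3 --seed 1 --n-timepoints 50
striocompart parcellate --cohort cohort/manifest.json --out parcels
striocompart dsc parcels/sub-001_L-STR.nii.gz parcels/sub-001_L-MAT.nii.gz
```

See `docs/methods.md` for the model, parameter defaults, and what the
synthetic cohort does and does not emulate.

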