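"""End-to-end driver: simulate (or load) a cohort, parcellate, validate
anatomy, run jitter controls, map rsFC, run group statistics, map
somatotopic zones, and emit summary reports.

Every stage is a pure function of its inputs and the seeds recorded in the
run metadata, so re-running with the same configuration reproduces outputs
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import anatomy_metrics, controls, group_stats, reporting, rsfc, somatotopy
from .cli_io import PipelineConfig, _StageTimer, read_table, read_volume, write_table, write_volume
from .parcellation import (BiasMap, classify_voxels, compute_bias,
                           equal_volume_masks, n1_parcellate)
from .synthetic_data import (BaitRegionSet, BoldSeries, BoldSpec, CountModel,
                             GroundTruthStriatum, NetworkNode, StriatumSpec,
                             SubjectData, simulate_subject, write_cohort,
                             _subject_seeds)

__all__ = ["simulate_cohort", "load_cohort", "parcellate_subject", "run_pipeline"]


def simulate_cohort(n_subjects, seed, striatum_spec=None, baits=None,
                    count_model=None, bold_spec=None, with_bold=True):
    """Generate an in-memory synthetic cohort (list of SubjectData)."""
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    return [
        simulate_subject(f"sub-{i + 1:03d}", s, striatum_spec, baits,
                         count_model, bold_spec, with_bold=with_bold)
        for i, s in enumerate(_subject_seeds(seed, n_subjects))
    ]


def load_cohort(manifest_path, with_bold=True):
    """Reconstruct a cohort from a manifest written by write_cohort."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    covars = read_table(manifest["covariates"]).set_index("subject_id")
    baits = BaitRegionSet(
        regions=tuple(tuple(r) for r in manifest["baits"]["regions"]),
        dispersed=tuple(manifest["baits"]["dispersed"]))

    from .parcellation import TargetCountMaps

    subjects = []
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        files = entry["files"]
        labels, affine = read_volume(files["labels"], expect_ndim=3)
        truth, _ = read_volume(files["truth"], expect_ndim=3)
        gt = GroundTruthStriatum(nucleus_labels=labels.astype(np.uint8),
                                 compartment_labels=truth.astype(np.uint8),
                                 affine=affine)
        counts = {}
        for name, path in files["counts"].items():
            grid, _ = read_volume(path, expect_ndim=3)
            counts[name] = grid
        tcm = TargetCountMaps(counts=counts, favored=baits.favored,
                              striatum_mask=gt.striatum_mask, affine=affine)
        bold = None
        nodes = None
        if with_bold:
            data, _, tr = read_volume(files["bold"], expect_ndim=4)
            bold = BoldSeries(data=np.asarray(data, dtype=np.float32),
                              tr_seconds=tr,
                              brain_mask=np.ones(labels.shape, dtype=bool))
            nodes = {}
            for name, path in manifest["nodes"].items():
                mask, _ = read_volume(path, expect_ndim=3)
                network, side = name.rsplit("-", 1)
                nodes[name] = NetworkNode(mask=mask.astype(bool),
                                          hemisphere=side, network=network)
        row = covars.loc[sid]
        subjects.append(SubjectData(subject_id=sid, gt=gt, counts=tcm,
                                    bold=bold, nodes=nodes,
                                    age=int(row["age"]), sex=str(row["sex"]),
                                    seed=int(entry["seed"])))
    return subjects, baits


def parcellate_subject(subj: SubjectData, target_fraction: float = 0.13,
                       leave_out: str = None):
    """Bias map plus equal-volume masks for both hemispheres of one subject."""
    bias = (compute_bias(subj.counts) if leave_out is None
            else n1_parcellate(subj.counts, leave_out))
    masks = {}
    for side in ("L", "R"):
        hemi = subj.gt.hemisphere_mask(side)
        masks[side] = equal_volume_masks(
            bias, hemi, target_fraction=target_fraction,
            scope=f"{subj.subject_id}/{side}")
    return bias, masks


def _stage(results_dir, name, config_hash):
    return _StageTimer(f"{name}", config_hash)


def run_pipeline(out_dir, config: PipelineConfig = None, n_subjects: int = 6,
                 seed: int = None, striatum_spec: StriatumSpec = None,
                 count_model: CountModel = None, baits: BaitRegionSet = None,
                 cohort=None):
    """Run the full analysis chain on a synthetic (or preloaded) cohort.

    Configuration is validated before any compute. Returns a dict of
    in-memory stage results; all tables, masks and metadata are written
    under ``out_dir``. A rerun with identical arguments reproduces every
    output bit-identically.
    """
    config = (config or PipelineConfig()).validate()
    if seed is None:
        seed = config.seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    baits = baits or BaitRegionSet()

    bold_spec = BoldSpec(n_timepoints=config.n_timepoints,
                         tr_seconds=config.tr_seconds)

    # --- simulate (or accept a preloaded cohort) -------------------------
    with _stage(out, "simulate", chash):
        if cohort is None:
            cohort = simulate_cohort(n_subjects, seed, striatum_spec, baits,
                                     count_model, bold_spec)
        affine = cohort[0].gt.affine

    # --- parcellate ------------------------------------------------------
    biases, masks = {}, {}
    with _stage(out, "parcellate", chash):
        for subj in cohort:
            try:
                biases[subj.subject_id], masks[subj.subject_id] = \
                    parcellate_subject(subj, config.target_fraction)
            except Exception as exc:
                raise RuntimeError(
                    f"stage parcellate failed for subject {subj.subject_id}: {exc}"
                ) from exc

    # --- anatomy ---------------------------------------------------------
    with _stage(out, "anatomy", chash):
        cluster_rows = []
        for subj in cohort:
            bias = biases[subj.subject_id]
            labels = classify_voxels(bias, cutoff=config.bias_cutoff_low)
            high = classify_voxels(bias, cutoff=config.bias_cutoff_high)
            for comp, code in (("striosome-like", 1), ("matrix-like", 2)):
                rep = anatomy_metrics.cluster_sizes(
                    high == code, connectivity=config.connectivity)
                cluster_rows.append({
                    "subject": subj.subject_id, "compartment": comp,
                    "largest_cluster_voxels": rep.largest,
                    "n_clusters": len(rep.sizes),
                    "total_voxels": rep.total})
        cluster_table = pd.DataFrame(cluster_rows)
        write_table(out / "cluster_sizes.tsv", cluster_table)

        from .synthetic_data import CAUDATE_L, CAUDATE_R, PUTAMEN_L, PUTAMEN_R
        plane_tables = {}
        for nucleus, codes in (("caudate", (CAUDATE_L, CAUDATE_R)),
                               ("putamen", (PUTAMEN_L, PUTAMEN_R))):
            strio, matr, nuc = [], [], []
            for subj in cohort:
                labels = classify_voxels(biases[subj.subject_id],
                                         cutoff=config.bias_cutoff_low)
                nmask = np.isin(subj.gt.nucleus_labels, codes)
                strio.append((labels == 1) & nmask)
                matr.append((labels == 2) & nmask)
                nuc.append(nmask)
            if len(cohort) >= 2:
                plane_tables[nucleus] = anatomy_metrics.plane_profile(
                    strio, matr, nuc, affine,
                    thickness=config.plane_thickness_mm)
                write_table(out / f"plane_profile_{nucleus}.tsv",
                            plane_tables[nucleus])

    # --- jitter control --------------------------------------------------
    with _stage(out, "jitter", chash):
        jitter_rows = []
        for i, subj in enumerate(cohort):
            bias = biases[subj.subject_id]
            for side in ("L", "R"):
                cm = masks[subj.subject_id][side]
                striatum = subj.gt.striatum_mask
                spec = controls.JitterSpec(max_shift=config.jitter_max_shift,
                                           rng_seed=seed + 7919 * i)
                for comp, m in (("striosome", cm.striosome_like),
                                ("matrix", cm.matrix_like)):
                    shifted, jstats = controls.jitter_mask(m, striatum, cm, spec)
                    b0, f0 = controls.mask_bias(bias, m,
                                                cutoff=config.bias_cutoff_low,
                                                toward=comp)
                    b1, f1 = controls.mask_bias(bias, shifted,
                                                cutoff=config.bias_cutoff_low,
                                                toward=comp)
                    jitter_rows.append({
                        "subject": subj.subject_id, "hemisphere": side,
                        "compartment": comp, "bias_original": b0,
                        "bias_shifted": b1, "bias_drop": b0 - b1,
                        "frac_biased_original": f0, "frac_biased_shifted": f1,
                        "rms_shift_voxels": jstats["rms_shift"]})
        jitter_table = pd.DataFrame(jitter_rows)
        write_table(out / "jitter_bias.tsv", jitter_table)

    # --- rsfc ------------------------------------------------------------
    with _stage(out, "rsfc", chash):
        subject_zmaps = []
        for subj in cohort:
            try:
                zmaps = rsfc.subject_maps(subj.bold, masks[subj.subject_id],
                                          subj.gt.striatum_mask, affine=affine)
            except Exception as exc:
                raise RuntimeError(
                    f"stage rsfc failed for subject {subj.subject_id}: {exc}"
                ) from exc
            subject_zmaps.append(zmaps)

    # --- group statistics ------------------------------------------------
    with _stage(out, "groupstats", chash):
        covariates = pd.DataFrame({
            "subject_id": [s.subject_id for s in cohort],
            "age": [s.age for s in cohort],
            "sex": [s.sex for s in cohort]})
        contrasts = group_stats.contrast_suite(
            subject_zmaps, covariates, p_unc=config.p_unc,
            connectivity=config.connectivity, n_perm=config.n_perm,
            alpha=config.alpha, seed=seed, affine=affine)
        all_clusters = pd.concat([r["clusters"] for r in contrasts.values()],
                                 ignore_index=True)
        write_table(out / "cluster_table.tsv", all_clusters)
        for name, r in contrasts.items():
            write_volume(out / f"sig_{name.replace('>', '_gt_')}.nii.gz",
                         r["sig_mask"].astype(np.uint8), affine)

    # --- somatotopy ------------------------------------------------------
    with _stage(out, "somatotopy", chash):
        cmap = somatotopy.contribution_maps([s.counts for s in cohort], baits)
        zones = somatotopy.segment_zones(cmap)
        hemis = {side: cohort[0].gt.hemisphere_mask(side) for side in ("L", "R")}
        lo, hi = config.zone_size_range
        zones = somatotopy.refine_zones(cmap, zones, hemis,
                                        percentile=config.zone_percentile,
                                        target_size=(lo, hi))
        anova_out = None
        if zones.refined:
            subject_labels = [classify_voxels(biases[s.subject_id],
                                              cutoff=config.bias_cutoff_low)
                              for s in cohort]
            try:
                table, anova_out = somatotopy.zone_bias_anova(
                    zones, subject_labels, baits.favored)
                write_table(out / "zone_fractions.tsv", table)
            except ValueError:
                anova_out = None

    # --- reporting -------------------------------------------------------
    with _stage(out, "report", chash):
        sig_masks = {name: r["sig_mask"] for name, r in contrasts.items()}
        lat = reporting.laterality_table(sig_masks, affine)
        write_table(out / "laterality.tsv", lat)

        def vol(name):
            t = all_clusters
            sel = t[(t["contrast"] == name) & t["significant"]]
            return float(sel["volume_mm3"].sum())

        summary = {
            "fold_ratio_whole_brain": reporting.fold_ratio(
                [vol("L-STR>L-MAT"), vol("R-STR>R-MAT")],
                [vol("L-MAT>L-STR"), vol("R-MAT>R-STR")]),
            "anova_compartment_F": (anova_out or {}).get("F"),
            "anova_compartment_p": (anova_out or {}).get("p"),
        }
        meta = {"config_hash": chash, "seed": int(seed),
                "n_subjects": len(cohort),
                "config": json.loads(config.to_json()),
                "subject_seeds": [s.seed for s in cohort]}
        (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))
        (out / "summary.json").write_text(json.dumps(
            {k: (None if v is None else float(v)) if not isinstance(v, str) else v
             for k, v in summary.items()}, indent=2, default=float))

    return {"cohort": cohort, "biases": biases, "masks": masks,
            "anatomy_clusters": cluster_table, "cluster_table": all_clusters,
            "plane_tables": plane_tables,
            "jitter_table": jitter_table, "contrasts": contrasts,
            "zones": zones, "anova": anova_out, "laterality": lat,
            "summary": summary, "affine": affine}
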