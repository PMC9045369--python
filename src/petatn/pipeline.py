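"""End-to-end pipeline: simulate -> templates -> SUVR -> classify -> compare.

Each stage reads/writes self-describing artifacts (NIfTI volumes, TSV
tables with headers, JSON sidecars) under one output directory, so any
stage can be rerun in isolation.  All randomness flows from the single
config seed; a run report records versions, seeds, per-stage timings and
warnings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import AtlasLabelMap, generate_atlas_phantom
from .biomarkers import (
    assign_atn_group,
    build_profile,
    fdg_single_subject,
    loocv_accuracy,
    youden_cutoff,
)
from .groupstats import cluster_extent_inference, compare_groups_atlas, summarize_cluster
from .spatial import TemplatePair, build_template, gaussian_smooth, select_adaptive_template
from .suvr import AMYLOID_GLOBAL_VOIS, GLOBAL_VOI, MetaVOISet, SUVRTable, compute_suvr_row, global_suvr
from .synthetic import FDG_HYPO_LOBES, Cohort, CohortSpec, generate_cohort, write_cohort
from .volumes import BrainVolume

logger = logging.getLogger(__name__)

STAGES = ("simulate", "template", "suvr", "classify", "compare")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclasses.dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with defaults encoding the printed
    constants of the emulated study."""

    output_dir: str = "petatn_run"
    # phantom / cohort
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    n_per_group: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"AD": 7, "SNAP": 10, "BN": 6}
    )
    noise_sd: float = 0.02
    blur_fwhm_mm: float = 4.0
    misalign_max: tuple[float, float] = (0.0, 0.0)
    # thresholds
    ab42_cutoff: float = 600.0  # ng/L
    ttau_cutoff: float = 450.0  # ng/L
    gm_threshold: float = 0.5
    voxel_p: float = 0.01
    cluster_alpha: float = 0.05
    k_min: int = 100
    smoothing_fwhm_mm: float = 8.0
    borderline_pct: float = 10.0
    fdg_voxel_p: float = 0.05
    fdg_k_min: int = 100
    n_permutations: int = 1000
    n_controls: int = 24
    seed: int = 0
    stages: dict[str, bool] = dataclasses.field(
        default_factory=lambda: {s: True for s in STAGES}
    )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        cfg.grid_shape = tuple(cfg.grid_shape)
        cfg.misalign_max = tuple(cfg.misalign_max)
        return cfg


def validate_config(config: PipelineConfig) -> tuple[list[str], list[str]]:
    """Return (errors, warnings); errors are blocking."""
    errors, warnings = [], []
    for name, lo, hi in (
        ("voxel_p", 0.0, 1.0),
        ("cluster_alpha", 0.0, 1.0),
        ("fdg_voxel_p", 0.0, 1.0),
        ("gm_threshold", 0.0, 1.0),
    ):
        v = getattr(config, name)
        if not (lo < v <= hi) and not (name == "gm_threshold" and 0 <= v <= 1):
            errors.append(f"{name}={v} outside ({lo}, {hi}]")
    for name in ("ab42_cutoff", "ttau_cutoff", "smoothing_fwhm_mm", "borderline_pct"):
        if getattr(config, name) < 0:
            errors.append(f"{name} must be non-negative")
    if config.k_min < 0 or config.fdg_k_min < 0:
        errors.append("cluster extents must be non-negative")
    if config.n_permutations < 100:
        errors.append("n_permutations must be at least 100")
    elif config.n_permutations < 1000:
        warnings.append(f"n_permutations={config.n_permutations} < 1000; corrected p resolution is coarse")
    if config.n_controls < 20:
        errors.append("n_controls must be at least 20")
    if min(config.grid_shape) < 32:
        errors.append("grid_shape extents must be at least 32")
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        errors.append(f"unknown stages {sorted(unknown)}")
    return errors, warnings


# -- stage implementations -------------------------------------------------


def _stage_simulate(config: PipelineConfig, outdir: Path):
    atlas = generate_atlas_phantom(config.grid_shape, config.voxel_size_mm, seed=config.seed)
    spec = CohortSpec(
        n_per_group=dict(config.n_per_group),
        noise_sd=config.noise_sd,
        blur_fwhm_mm=config.blur_fwhm_mm,
        misalign_max=config.misalign_max,
        seed=config.seed,
    )
    cohort = generate_cohort(spec, atlas)
    write_cohort(cohort, outdir / "cohort")
    return atlas, cohort


def _stage_template(config: PipelineConfig, outdir: Path, atlas: AtlasLabelMap, cohort: Cohort):
    """Positive/negative PIB templates from the cohort's amyloid-true split."""
    gt = cohort.ground_truth.set_index("patient_id")
    pos_ids = [p for p, m in cohort.volumes.items() if "PIB" in m and gt.loc[p, "true_A"]]
    neg_ids = [p for p, m in cohort.volumes.items() if "PIB" in m and not gt.loc[p, "true_A"]]
    if not pos_ids or not neg_ids:
        raise PipelineStageError("template", "no_subjects", "need PIB scans in both amyloid classes")
    tdir = outdir / "templates"
    tdir.mkdir(parents=True, exist_ok=True)
    templates = {}
    for tag, ids in (("positive", pos_ids), ("negative", neg_ids)):
        tmpl, medians = build_template(
            [cohort.volumes[p]["PIB"] for p in ids], atlas, config.gm_threshold
        )
        tmpl.to_nifti(tdir / f"pib_template_{tag}.nii.gz")
        (tdir / f"pib_template_{tag}.json").write_text(
            json.dumps(
                {
                    "source_subjects": ids,
                    "reference_region_ids": sorted(atlas.reference_ids),
                    "scaling_medians": medians,
                },
                indent=2,
            )
        )
        templates[tag] = tmpl
    return TemplatePair(templates["positive"], templates["negative"], atlas.brain_mask)


def _stage_suvr(config: PipelineConfig, outdir: Path, atlas: AtlasLabelMap, cohort: Cohort,
                templates: TemplatePair | None):
    metavois = MetaVOISet.from_atlas(atlas)
    rows = {}
    selections = {}
    for pid, mods in cohort.volumes.items():
        for modality, vol in mods.items():
            rows[(pid, modality)] = compute_suvr_row(vol, atlas, metavois, config.gm_threshold)
            if modality == "PIB" and templates is not None:
                sel, ncc_p, ncc_n = select_adaptive_template(vol, templates)
                selections[pid] = {
                    "selection": sel,
                    "ncc_positive": ncc_p.aggregate,
                    "ncc_negative": ncc_n.aggregate,
                }
    table = SUVRTable.from_rows(rows)
    table.to_tsv(outdir / "suvr.tsv")
    # amyloid composite global per PIB scan
    amyloid = {
        pid: global_suvr(rows[(pid, "PIB")], AMYLOID_GLOBAL_VOIS)
        for pid, mods in cohort.volumes.items()
        if "PIB" in mods
    }
    pd.DataFrame(
        [{"patient_id": p, "global_pib_suvr": v} for p, v in amyloid.items()]
    ).to_csv(outdir / "global_pib_suvr.tsv", sep="\t", index=False)
    (outdir / "template_selection.json").write_text(json.dumps(selections, indent=2))
    return table, amyloid, selections, metavois


def _simulate_fdg_controls(config: PipelineConfig, atlas: AtlasLabelMap):
    """Healthy-control FDG set (normal cortical uptake) for the
    single-subject analysis; ages/sexes drawn to mimic a screening cohort."""
    from .synthetic import FDG_NORMAL_LEVEL, generate_pet_volume, _lobe_to_region_uptake
    from .atlas import CORTICAL_LOBES

    rng = np.random.default_rng(config.seed + 101)
    controls, ages, sexes = [], [], []
    for _ in range(config.n_controls):
        means = {
            lobe: max(0.05, rng.normal(*FDG_NORMAL_LEVEL)) for lobe in CORTICAL_LOBES
        }
        controls.append(
            generate_pet_volume(
                atlas,
                _lobe_to_region_uptake(atlas, means),
                config.noise_sd,
                config.blur_fwhm_mm,
                seed=int(rng.integers(0, 2**31 - 1)),
                modality="FDG",
            )
        )
        ages.append(float(rng.uniform(56, 76)))
        sexes.append(int(rng.integers(0, 2)))
    return controls, ages, sexes


def _stage_classify(config: PipelineConfig, outdir: Path, atlas: AtlasLabelMap, cohort: Cohort,
                    amyloid: dict[str, float], selections: dict):
    # ROC/Youden amyloid cutoff: template selection stands in for the
    # scan-level visual read as the gold standard
    scores = [(amyloid[p], selections[p]["selection"] == "positive") for p in amyloid]
    cutoff = youden_cutoff(scores)
    cutoff.loocv_accuracy = loocv_accuracy(scores)

    # single-subject FDG hypometabolism
    controls, c_ages, c_sexes = _simulate_fdg_controls(config, atlas)
    controls_s = [gaussian_smooth(c, config.smoothing_fwhm_mm) for c in controls]
    susceptible = np.isin(
        atlas.labels,
        [rid for lobe in FDG_HYPO_LOBES for rid in atlas.region_ids(lobe)],
    )
    rng = np.random.default_rng(config.seed + 202)
    fdg_status: dict[str, str] = {}
    for pid, mods in cohort.volumes.items():
        if "FDG" not in mods:
            continue
        patient = gaussian_smooth(mods["FDG"], config.smoothing_fwhm_mm)
        status, _ = fdg_single_subject(
            patient,
            controls_s,
            patient_age=float(rng.uniform(52, 76)),
            patient_sex=int(rng.integers(0, 2)),
            control_ages=c_ages,
            control_sexes=c_sexes,
            susceptible_mask=susceptible,
            brain_mask=atlas.brain_mask,
            voxel_p=config.fdg_voxel_p,
            k_min=config.fdg_k_min,
        )
        fdg_status[pid] = status

    csf = cohort.csf.set_index("patient_id")
    profiles = {}
    groups = {}
    records = []
    for pid in cohort.patient_ids:
        prof = build_profile(
            pid,
            csf_ab42=_opt(csf.loc[pid, "csf_ab42"]),
            csf_ttau=_opt(csf.loc[pid, "csf_ttau"]),
            global_pib_suvr=amyloid.get(pid),
            pib_cutoff=cutoff.cutoff,
            fdg_status=fdg_status.get(pid),
            ab42_cutoff=config.ab42_cutoff,
            ttau_cutoff=config.ttau_cutoff,
            borderline_pct=config.borderline_pct,
        )
        profiles[pid] = prof
        groups[pid] = assign_atn_group(prof).value
        records.append(
            {
                "patient_id": pid,
                "A_status": prof.A_status,
                "A_source": prof.A_source or "",
                "N_status": prof.N_status,
                "N_source": prof.N_source or "",
                "csf_ab42": prof.csf_ab42,
                "csf_ttau": prof.csf_ttau,
                "global_pib_suvr": prof.global_pib_suvr,
                "atn_group": groups[pid],
                "borderline_flags": ";".join(prof.borderline_flags),
            }
        )
    pd.DataFrame(records).to_csv(outdir / "biomarkers.tsv", sep="\t", index=False)
    (outdir / "cutoff_report.json").write_text(
        json.dumps(
            {
                "cutoff": cutoff.cutoff,
                "sensitivity": cutoff.sensitivity,
                "specificity": cutoff.specificity,
                "youden_j": cutoff.youden_j,
                "auc": cutoff.auc,
                "loocv_accuracy": cutoff.loocv_accuracy,
                "roc_points": cutoff.roc_points,
            },
            indent=2,
        )
    )
    return profiles, groups, cutoff


def _opt(x):
    return None if pd.isna(x) else float(x)


def _stage_compare(config: PipelineConfig, outdir: Path, atlas: AtlasLabelMap, cohort: Cohort,
                   table: SUVRTable, groups: dict[str, str]):
    metavois = MetaVOISet.from_atlas(atlas)
    comparable = {p: g for p, g in groups.items() if g != "UNCLASSIFIABLE"}
    result = compare_groups_atlas(
        table, comparable, list(metavois.vois) + [GLOBAL_VOI], config.cluster_alpha
    )
    result.to_frame().to_csv(outdir / "atlas_comparison.tsv", sep="\t", index=False)

    # voxel-wise AD continuum > BN on reference-scaled tau volumes
    suvr_vols = {}
    for pid, mods in cohort.volumes.items():
        vol = mods["PBB3"]
        from .suvr import voi_median

        ref, _ = voi_median(vol, atlas, atlas.reference_ids, config.gm_threshold)
        suvr_vols[pid] = vol.with_data(vol.data / ref)
    ad = [suvr_vols[p] for p, g in comparable.items() if g == "AD_CONTINUUM"]
    bn = [suvr_vols[p] for p, g in comparable.items() if g == "BN"]
    cluster_rows = []
    if len(ad) >= 2 and len(bn) >= 2:
        gm_mask = atlas.gm_prob >= config.gm_threshold
        res = cluster_extent_inference(
            ad, bn, gm_mask,
            voxel_p=config.voxel_p,
            k_min=config.k_min,
            cluster_alpha=config.cluster_alpha,
            n_permutations=config.n_permutations,
            seed=config.seed + 303,
        )
        BrainVolume(res.t_map, atlas.affine, "template", "PBB3").to_nifti(
            outdir / "tmap_ad_vs_bn.nii.gz"
        )
        label_grid = np.zeros(atlas.shape)
        for i, cl in enumerate(res.clusters, start=1):
            label_grid[cl.voxels] = i
            summary = summarize_cluster(
                cl.voxels,
                {p: suvr_vols[p] for p, g in comparable.items() if g in ("AD_CONTINUUM", "BN")},
                comparable,
            )
            for _, row in summary.iterrows():
                cluster_rows.append(
                    {"cluster": i, "k": cl.size, "peak_t": cl.peak_t,
                     "corrected_p": cl.corrected_p, **row.to_dict()}
                )
        BrainVolume(label_grid, atlas.affine, "template", "PBB3").to_nifti(
            outdir / "clusters_ad_vs_bn.nii.gz"
        )
    pd.DataFrame(cluster_rows).to_csv(outdir / "cluster_comparison.tsv", sep="\t", index=False)
    return result, cluster_rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages in dependency order; returns the run report."""
    errors, warnings = validate_config(config)
    if errors:
        raise PipelineStageError("config", "invalid", "; ".join(errors))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "warnings": list(warnings),
        "stages": {},
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    enabled = {s: config.stages.get(s, True) for s in STAGES}

    state: dict = {}

    def run_stage(name, fn, *args):
        if not enabled[name]:
            report["stages"][name] = {"skipped": True}
            return None
        t0 = time.perf_counter()
        try:
            out = fn(config, outdir, *args)
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001 — annotate with the stage
            raise PipelineStageError(name, type(exc).__name__, str(exc)) from exc
        report["stages"][name] = {"skipped": False, "seconds": round(time.perf_counter() - t0, 3)}
        return out

    sim = run_stage("simulate", lambda cfg, od: _stage_simulate(cfg, od))
    if sim is None:
        raise PipelineStageError("simulate", "required", "later stages need the simulate stage")
    atlas, cohort = sim
    templates = run_stage("template", _stage_template, atlas, cohort)
    suvr_out = run_stage("suvr", _stage_suvr, atlas, cohort, templates)
    if suvr_out is not None:
        table, amyloid, selections, _ = suvr_out
        classify_out = run_stage("classify", _stage_classify, atlas, cohort, amyloid, selections)
        if classify_out is not None:
            _, groups, cutoff = classify_out
            report["cutoff"] = cutoff.cutoff
            report["loocv_accuracy"] = cutoff.loocv_accuracy
            report["group_sizes"] = {
                g: sum(1 for v in groups.values() if v == g) for g in set(groups.values())
            }
            run_stage("compare", _stage_compare, atlas, cohort, table, groups)
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
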