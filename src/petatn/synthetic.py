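"""Synthetic multi-tracer PET cohorts with known ground truth.

Generates cohorts of PBB3 (tau), PIB (amyloid) and FDG (glucose metabolism)
volumes on a shared atlas phantom, plus a CSF biomarker table.  The default
parameters reproduce the structure of the study cohort this pipeline
emulates: 7 AD-continuum-like subjects (2 N-, 5 N+), 10 SNAP-like (A-N+)
and 6 biomarker-negative-like (A-N-), with per-group regional tau uptake,
global amyloid load and CSF concentrations matching the printed cohort
tables (medians/IQRs converted to normal means/sds via sd = IQR/1.349).

Each subject's PET volume is piecewise-constant regional uptake (relative
to a cerebellar reference fixed at 1) plus voxel-wise Gaussian noise,
Gaussian blur emulating scanner resolution, and an optional small rigid
misalignment.  Modality availability follows the printed per-group counts,
arranged so that every subject carries an amyloid and a neurodegeneration
biomarker from either PET or CSF.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import CORTICAL_LOBES, AtlasLabelMap
from .spatial import gaussian_smooth
from .volumes import BrainVolume, resample_rigid

GROUPS = ("AD", "SNAP", "BN")

_IQR_TO_SD = 1.0 / 1.349

#: per-group PBB3 uptake by lobe: (median, IQR) relative to cerebellum
PBB3_UPTAKE_DEFAULTS = {
    "AD": {
        "medial_temporal": (1.00, 0.06),
        "temporal": (1.11, 0.03),
        "frontal": (1.07, 0.05),
        "parietal": (1.05, 0.08),
        "occipital": (1.11, 0.07),
        "anterior_cingulate": (1.09, 0.07),
        "posterior_cingulate": (1.18, 0.14),
    },
    "BN": {
        "medial_temporal": (0.96, 0.06),
        "temporal": (0.95, 0.04),
        "frontal": (0.87, 0.06),
        "parietal": (0.92, 0.01),
        "occipital": (0.98, 0.04),
        "anterior_cingulate": (0.89, 0.06),
        "posterior_cingulate": (0.98, 0.08),
    },
    "SNAP": {
        "medial_temporal": (0.93, 0.10),
        "temporal": (0.94, 0.15),
        "frontal": (0.88, 0.18),
        "parietal": (0.91, 0.16),
        "occipital": (0.99, 0.13),
        "anterior_cingulate": (0.90, 0.17),
        "posterior_cingulate": (0.97, 0.14),
    },
}

#: per-group global PIB cortical load: (mean, sd)
PIB_GLOBAL_DEFAULTS = {"AD": (2.21, 0.25), "SNAP": (1.30, 0.17), "BN": (1.36, 0.06)}

#: FDG cortical uptake: lobes suppressed in neurodegeneration-positive subjects
FDG_NORMAL_LEVEL = (1.0, 0.05)
FDG_HYPO_LEVEL = (0.70, 0.05)
FDG_HYPO_LOBES = ("temporal", "parietal", "posterior_cingulate")

#: per-group CSF (mean, sd) in ng/L
CSF_DEFAULTS = {
    "AD": {"ab42": (499.0, 169.0), "ttau": (440.0, 230.0)},
    "SNAP": {"ab42": (1065.0, 588.0), "ttau": (462.0, 213.0)},
    "BN": {"ab42": (841.0, 218.0), "ttau": (267.0, 51.0)},
}

#: per-group modality availability (number of subjects, from the front for
#: PET and from the back for CSF, so PET+CSF cover every subject)
AVAILABILITY_DEFAULTS = {
    "pib": {"AD": 7, "SNAP": 6, "BN": 4},
    "fdg": {"AD": 4, "SNAP": 9, "BN": 3},
    "csf": {"AD": 3, "SNAP": 4, "BN": 4},
}

AB42_CUTOFF = 600.0
TTAU_CUTOFF = 450.0


@dataclasses.dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults mirror the printed cohort."""

    n_per_group: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"AD": 7, "SNAP": 10, "BN": 6}
    )
    n_ad_n_negative: int = 2  # leading AD-continuum subjects without neurodegeneration
    pbb3_uptake: dict = dataclasses.field(
        default_factory=lambda: {g: dict(v) for g, v in PBB3_UPTAKE_DEFAULTS.items()}
    )
    pib_global: dict = dataclasses.field(default_factory=lambda: dict(PIB_GLOBAL_DEFAULTS))
    csf_params: dict = dataclasses.field(
        default_factory=lambda: {g: dict(v) for g, v in CSF_DEFAULTS.items()}
    )
    availability: dict = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in AVAILABILITY_DEFAULTS.items()}
    )
    noise_sd: float = 0.02
    blur_fwhm_mm: float = 4.0
    misalign_max: tuple[float, float] = (0.0, 0.0)  # (mm translation, deg rotation)
    seed: int = 0

    def validate(self, atlas: AtlasLabelMap) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError(f"negative count for group {g}")
        if self.noise_sd < 0 or self.blur_fwhm_mm < 0:
            raise ValueError("noise_sd and blur_fwhm_mm must be non-negative")
        lobes = set(CORTICAL_LOBES)
        for g, profile in self.pbb3_uptake.items():
            unknown = set(profile) - lobes
            if unknown:
                raise ValueError(f"uptake profile {g} references unknown lobes {unknown}")

    @property
    def n_total(self) -> int:
        return sum(self.n_per_group.values())


def generate_pet_volume(
    atlas: AtlasLabelMap,
    uptake: dict[int, float],
    noise_sd: float = 0.0,
    blur_fwhm_mm: float = 0.0,
    misalign: tuple = ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
    seed: int = 0,
    modality: str = "PBB3",
) -> BrainVolume:
    """Render one PET volume from per-region mean uptake.

    Voxel value = region mean + N(0, noise_sd) inside labelled voxels, then
    Gaussian blur, then resampling under the rigid misalignment; background
    stays near zero.  Deterministic for a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    missing_ref = atlas.reference_ids - set(uptake)
    if missing_ref:
        raise ValueError(f"uptake does not cover reference regions {sorted(missing_ref)}")
    rng = np.random.default_rng(seed)
    data = np.zeros(atlas.shape, dtype=np.float64)
    for rid, mean in uptake.items():
        data[atlas.labels == rid] = float(mean)
    if noise_sd > 0:
        brain = atlas.brain_mask
        data[brain] += rng.normal(0.0, noise_sd, int(brain.sum()))
    vol = BrainVolume(data, atlas.affine.copy(), "template", modality)
    if blur_fwhm_mm > 0:
        vol = gaussian_smooth(vol, blur_fwhm_mm)
    translation, rotation = misalign
    if np.any(np.asarray(translation) != 0) or np.any(np.asarray(rotation) != 0):
        vol = resample_rigid(vol, vol, translation, rotation)
        vol.space = "native"
    return vol


def _truncnorm_sample(rng, mean, sd, lower=0.0, upper=np.inf) -> float:
    a, b = (lower - mean) / sd, (upper - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b))
    return float(mean + sd * stats.norm.ppf(u))


def _lobe_to_region_uptake(atlas: AtlasLabelMap, lobe_means: dict[str, float]) -> dict[int, float]:
    uptake = {rid: 1.0 for rid in atlas.reference_ids}
    for lobe, mean in lobe_means.items():
        for rid in atlas.region_ids(lobe):
            uptake[rid] = mean
    return uptake


@dataclasses.dataclass
class Cohort:
    """Generated cohort: volumes, CSF table and ground truth."""

    volumes: dict[str, dict[str, BrainVolume]]  # patient_id -> modality -> volume
    csf: pd.DataFrame  # patient_id, csf_ab42, csf_ttau (NaN when unavailable)
    ground_truth: pd.DataFrame
    atlas: AtlasLabelMap
    spec: CohortSpec

    @property
    def patient_ids(self) -> list[str]:
        return list(self.volumes)


def generate_cohort(spec: CohortSpec, atlas: AtlasLabelMap) -> Cohort:
    """Sample a full multi-tracer cohort with per-subject ground truth.

    Every subject gets a PBB3 volume; PIB/FDG/CSF follow the availability
    counts.  CSF values are drawn from truncated normals conditioned on the
    subject's true biomarker side of the 600/450 ng/L cutoffs, so recorded
    ground truth always agrees with the thresholds applied to the values.
    """
    spec.validate(atlas)
    master = np.random.default_rng(spec.seed)
    records = []
    volumes: dict[str, dict[str, BrainVolume]] = {}
    csf_rows = []
    idx = 0
    for group in GROUPS:
        n = spec.n_per_group.get(group, 0)
        for j in range(n):
            pid = f"sub-{idx + 1:03d}"
            idx += 1
            rng = np.random.default_rng(master.integers(0, 2**31 - 1))
            true_a = group == "AD"
            if group == "AD":
                true_n = j >= spec.n_ad_n_negative
            else:
                true_n = group == "SNAP"
            has_pib = j < spec.availability["pib"].get(group, 0)
            has_fdg = j < spec.availability["fdg"].get(group, 0)
            has_csf = j >= n - spec.availability["csf"].get(group, 0)

            # --- PBB3 (always present): per-subject lobe means around the
            # group medians, between-subject sd = IQR/1.349
            lobe_means = {
                lobe: max(0.05, rng.normal(med, iqr * _IQR_TO_SD))
                for lobe, (med, iqr) in spec.pbb3_uptake[group].items()
            }
            subj_vols: dict[str, BrainVolume] = {}
            mis = _draw_misalign(rng, spec.misalign_max)
            subj_vols["PBB3"] = generate_pet_volume(
                atlas,
                _lobe_to_region_uptake(atlas, lobe_means),
                spec.noise_sd,
                spec.blur_fwhm_mm,
                mis,
                seed=int(rng.integers(0, 2**31 - 1)),
                modality="PBB3",
            )

            pib_load = np.nan
            if has_pib:
                mu, sd = spec.pib_global[group]
                pib_load = _truncnorm_sample(rng, mu, sd, lower=0.05)
                subj_vols["PIB"] = generate_pet_volume(
                    atlas,
                    _lobe_to_region_uptake(atlas, {lb: pib_load for lb in CORTICAL_LOBES}),
                    spec.noise_sd,
                    spec.blur_fwhm_mm,
                    _draw_misalign(rng, spec.misalign_max),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    modality="PIB",
                )
            if has_fdg:
                fdg_means = {}
                for lobe in CORTICAL_LOBES:
                    mu, sd = (
                        FDG_HYPO_LEVEL
                        if (true_n and lobe in FDG_HYPO_LOBES)
                        else FDG_NORMAL_LEVEL
                    )
                    fdg_means[lobe] = max(0.05, rng.normal(mu, sd))
                subj_vols["FDG"] = generate_pet_volume(
                    atlas,
                    _lobe_to_region_uptake(atlas, fdg_means),
                    spec.noise_sd,
                    spec.blur_fwhm_mm,
                    _draw_misalign(rng, spec.misalign_max),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    modality="FDG",
                )

            ab42 = ttau = np.nan
            if has_csf:
                p = spec.csf_params[group]
                ab42 = (
                    _truncnorm_sample(rng, *p["ab42"], lower=0.0, upper=AB42_CUTOFF - 1e-9)
                    if true_a
                    else _truncnorm_sample(rng, *p["ab42"], lower=AB42_CUTOFF)
                )
                ttau = (
                    _truncnorm_sample(rng, *p["ttau"], lower=TTAU_CUTOFF + 1e-9)
                    if true_n
                    else _truncnorm_sample(rng, *p["ttau"], lower=0.0, upper=TTAU_CUTOFF)
                )
            csf_rows.append({"patient_id": pid, "csf_ab42": ab42, "csf_ttau": ttau})

            volumes[pid] = subj_vols
            rec = {
                "patient_id": pid,
                "group": group,
                "true_A": true_a,
                "true_N": true_n,
                "pib_global_true": pib_load,
            }
            rec.update({f"pbb3_{lobe}": m for lobe, m in lobe_means.items()})
            records.append(rec)

    return Cohort(
        volumes=volumes,
        csf=pd.DataFrame(csf_rows),
        ground_truth=pd.DataFrame(records),
        atlas=atlas,
        spec=spec,
    )


def _draw_misalign(rng, misalign_max):
    t_max, r_max = misalign_max
    if t_max == 0 and r_max == 0:
        return ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
    return (
        tuple(rng.uniform(-t_max, t_max, 3)),
        tuple(rng.uniform(-r_max, r_max, 3)),
    )


# -- on-disk layout --------------------------------------------------------


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write NIfTI volumes, CSF/ground-truth TSVs and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vols_dir = outdir / "volumes"
    vols_dir.mkdir(exist_ok=True)
    manifest: dict = {"subjects": {}, "files": {}}
    for pid, mods in cohort.volumes.items():
        manifest["subjects"][pid] = {}
        for modality, vol in mods.items():
            path = vols_dir / f"{pid}_{modality}.nii.gz"
            vol.to_nifti(path)
            manifest["subjects"][pid][modality] = str(path.relative_to(outdir))
    cohort.csf.to_csv(outdir / "csf.tsv", sep="\t", index=False)
    cohort.ground_truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    BrainVolume(
        cohort.atlas.labels.astype(float), cohort.atlas.affine, "template", "atlas"
    ).to_nifti(outdir / "atlas_labels.nii.gz")
    BrainVolume(cohort.atlas.gm_prob, cohort.atlas.affine, "template", "gm_prob").to_nifti(
        outdir / "atlas_gm_prob.nii.gz"
    )
    manifest["files"] = {
        "csf": "csf.tsv",
        "ground_truth": "ground_truth.tsv",
        "atlas_labels": "atlas_labels.nii.gz",
        "atlas_gm_prob": "atlas_gm_prob.nii.gz",
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_cohort_volumes(manifest_path: str | Path) -> dict[str, dict[str, BrainVolume]]:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    out: dict[str, dict[str, BrainVolume]] = {}
    for pid, mods in manifest["subjects"].items():
        out[pid] = {
            modality: BrainVolume.from_nifti(root / rel, modality=modality)
            for modality, rel in mods.items()
        }
    return out
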