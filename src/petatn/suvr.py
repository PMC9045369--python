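"""Atlas-based SUVR quantification.

SUVR (standardized uptake value ratio) is the median tracer uptake in a
grey-matter-masked volume of interest divided by the median uptake in
cerebellar crus grey matter.  Meta-VOIs merge several atlas regions (e.g.
both temporal lobes); a global cortical SUVR is the volume-weighted average
of the meta-VOI SUVRs.  The amyloid composite used for PIB positivity and
the tau global span different VOI lists and are kept as separate
configurations.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import CORTICAL_LOBES, AtlasLabelMap
from .volumes import BrainVolume

GM_THRESHOLD_DEFAULT = 0.5

#: meta-VOIs entering the tau global cortical SUVR (all seven)
TAU_GLOBAL_VOIS = (
    "medial_temporal",
    "temporal",
    "frontal",
    "occipital",
    "parietal",
    "anterior_cingulate",
    "posterior_cingulate",
)
#: composite for global amyloid retention: frontal, precuneus/posterior
#: cingulate, anterior cingulate, superior parietal and lateral temporal
AMYLOID_GLOBAL_VOIS = (
    "frontal",
    "posterior_cingulate",
    "anterior_cingulate",
    "parietal",
    "temporal",
)

GLOBAL_VOI = "global"


class EmptyVOIError(ValueError):
    """A VOI contains no qualifying voxels."""


@dataclasses.dataclass(frozen=True)
class MetaVOISet:
    """Named groups of atlas region ids, plus the two global composites."""

    vois: dict[str, frozenset]
    amyloid_global: tuple[str, ...] = AMYLOID_GLOBAL_VOIS
    tau_global: tuple[str, ...] = TAU_GLOBAL_VOIS

    def validate(self, atlas: AtlasLabelMap) -> None:
        for name, ids in self.vois.items():
            unknown = set(ids) - set(atlas.region_table)
            if unknown:
                raise ValueError(f"meta-VOI {name} references unknown regions {sorted(unknown)}")
            overlap = set(ids) & atlas.reference_ids
            if overlap:
                raise ValueError(f"meta-VOI {name} contains reference regions {sorted(overlap)}")

    @classmethod
    def from_atlas(cls, atlas: AtlasLabelMap) -> "MetaVOISet":
        """Group cortical regions by lobe tag (both hemispheres merged)."""
        vois = {
            lobe: frozenset(atlas.region_ids(lobe)) for lobe in CORTICAL_LOBES
        }
        obj = cls(vois=vois)
        obj.validate(atlas)
        return obj


def voi_median(
    volume: BrainVolume,
    atlas: AtlasLabelMap,
    region_ids: Iterable[int],
    gm_threshold: float = GM_THRESHOLD_DEFAULT,
) -> tuple[float, int]:
    """Median voxel value over a grey-matter-masked set of regions.

    Returns ``(median, n_voxels)``; the median of an even count is the
    midpoint of the two central values (numpy convention).
    """
    region_ids = set(region_ids)
    if volume.shape != atlas.shape:
        raise ValueError("volume not on the atlas grid")
    mask = np.isin(atlas.labels, list(region_ids)) & (atlas.gm_prob >= gm_threshold)
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise EmptyVOIError(f"no qualifying voxels for regions {sorted(region_ids)}")
    return float(np.median(volume.data[mask])), n


def compute_suvr_row(
    volume: BrainVolume,
    atlas: AtlasLabelMap,
    metavois: MetaVOISet,
    gm_threshold: float = GM_THRESHOLD_DEFAULT,
) -> dict[str, dict[str, float]]:
    """Per-meta-VOI SUVRs for one scan, plus the global cortical SUVR.

    SUVR(v) = median(v) / median(reference); the global is the
    volume-weighted average over ``metavois.tau_global``.
    """
    ref_median, _ = voi_median(volume, atlas, atlas.reference_ids, gm_threshold)
    if ref_median <= 0:
        raise ValueError(f"reference region median is non-positive ({ref_median:g})")
    vox_mm3 = atlas.voxel_volume_mm3
    row: dict[str, dict[str, float]] = {}
    for name, ids in metavois.vois.items():
        med, n = voi_median(volume, atlas, ids, gm_threshold)
        row[name] = {
            "suvr": med / ref_median,
            "n_voxels": n,
            "volume_mm3": n * vox_mm3,
        }
    g = global_suvr(row, metavois.tau_global)
    n_tot = sum(row[v]["n_voxels"] for v in metavois.tau_global)
    row[GLOBAL_VOI] = {"suvr": g, "n_voxels": n_tot, "volume_mm3": n_tot * vox_mm3}
    return row


def global_suvr(row: dict[str, dict[str, float]], voi_names: Iterable[str]) -> float:
    """Volume-weighted average SUVR over the named VOIs."""
    voi_names = list(voi_names)
    missing = [v for v in voi_names if v not in row]
    if missing:
        raise KeyError(f"VOIs missing from the SUVR row: {missing}")
    w = np.array([row[v]["volume_mm3"] for v in voi_names], dtype=float)
    s = np.array([row[v]["suvr"] for v in voi_names], dtype=float)
    return float(np.sum(w * s) / np.sum(w))


class SUVRTable:
    """Long-format table of per-patient, per-VOI SUVR values.

    Columns: patient_id, modality, voi, suvr, n_voxels, volume_mm3; one
    ``global`` row per patient/modality.
    """

    COLUMNS = ["patient_id", "modality", "voi", "suvr", "n_voxels", "volume_mm3"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"SUVR table missing columns {sorted(missing)}")
        if (frame["suvr"] <= 0).any():
            raise ValueError("SUVR values must be positive")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_rows(
        cls, rows: dict[tuple[str, str], dict[str, dict[str, float]]]
    ) -> "SUVRTable":
        records = []
        for (pid, modality), row in rows.items():
            for voi, vals in row.items():
                records.append(
                    {
                        "patient_id": pid,
                        "modality": modality,
                        "voi": voi,
                        "suvr": vals["suvr"],
                        "n_voxels": int(vals["n_voxels"]),
                        "volume_mm3": vals["volume_mm3"],
                    }
                )
        return cls(pd.DataFrame.from_records(records, columns=cls.COLUMNS))

    def pivot(self, modality: str = "PBB3") -> pd.DataFrame:
        """patient_id x voi matrix of SUVR values for one modality."""
        sub = self.frame[self.frame["modality"] == modality]
        return sub.pivot(index="patient_id", columns="voi", values="suvr")

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SUVRTable":
        return cls(pd.read_csv(path, sep="\t"))
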