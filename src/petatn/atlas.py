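"""Synthetic brain atlas: an integer label map with a region table, a
grey-matter probability map and a cerebellar reference region.

The phantom stands in for a probabilistic anatomical atlas.  Anatomical
realism is a non-goal: regions are contiguous blocks carved out of an
ellipsoidal brain mask, which is all the downstream quantification needs —
label bookkeeping, a reference region disjoint from cortex, and controllable
per-region uptake.  Region ids are stable so a real labelled atlas can be
dropped in through the same container.
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: lobe tag -> (left id, right id); cortical regions
CORTICAL_LOBES = {
    "medial_temporal": (1, 2),
    "temporal": (3, 4),
    "frontal": (5, 6),
    "occipital": (7, 8),
    "parietal": (9, 10),
    "anterior_cingulate": (11, 12),
    "posterior_cingulate": (13, 14),
}
#: cerebellar crus grey matter (left, right) — the SUVR reference
REFERENCE_IDS = (100, 101)

MIN_GRID_EXTENT = 32
_MIN_REGION_VOXELS = 10


class AtlasSizingError(ValueError):
    """Grid too small to place every region."""


@dataclasses.dataclass
class AtlasLabelMap:
    """Integer-labelled brain volume plus region metadata.

    Attributes
    ----------
    labels : ndarray of int
        0 = background; nonzero ids listed in ``region_table``.
    region_table : dict
        region id -> (name, lobe, hemisphere).
    gm_prob : ndarray of float in [0, 1]
        Grey-matter probability per voxel.
    reference_ids : frozenset of int
        Region ids forming cerebellar crus grey matter.
    affine : ndarray (4, 4)
        Voxel-to-world map shared by all cohort volumes.
    """

    labels: np.ndarray
    region_table: dict[int, tuple[str, str, str]]
    gm_prob: np.ndarray
    reference_ids: frozenset
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.reference_ids = frozenset(self.reference_ids)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.region_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from region_table")
        if self.gm_prob.min() < 0 or self.gm_prob.max() > 1:
            raise ValueError("gm_prob outside [0, 1]")
        if not self.reference_ids:
            raise ValueError("reference_ids is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def region_ids(self, lobe: str | None = None) -> list[int]:
        ids = [
            rid
            for rid, (_, lb, _) in sorted(self.region_table.items())
            if lobe is None or lb == lobe
        ]
        return ids

    @property
    def cortical_ids(self) -> list[int]:
        return [rid for rid in self.region_ids() if rid not in self.reference_ids]


def generate_atlas_phantom(
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_mm: float = 2.0,
    seed: int = 0,
) -> AtlasLabelMap:
    """Build a deterministic block-region atlas inside an ellipsoidal brain.

    The supratentorial brain is partitioned exhaustively into 14 cortical
    regions (7 lobes x 2 hemispheres) by anterior/posterior, superior/inferior
    and medial/lateral index rules; everything below the tentorium plane is the
    cerebellar reference (left/right).  ``seed`` only perturbs the grey-matter
    probability map; the label grid is a pure function of the geometry.

    Raises
    ------
    AtlasSizingError
        If any extent is below 32 voxels or a region ends up under-filled.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3:
        raise ValueError("grid_shape must have three extents")
    if voxel_size_mm <= 0:
        raise ValueError("voxel_size_mm must be positive")
    if min(grid_shape) < MIN_GRID_EXTENT:
        raise AtlasSizingError(
            f"grid {grid_shape} too small to place all regions; "
            f"smallest feasible extent is {MIN_GRID_EXTENT} voxels per axis"
        )
    nx, ny, nz = grid_shape
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    brain = (
        ((ix - cx) / (0.44 * nx)) ** 2
        + ((iy - cy) / (0.46 * ny)) ** 2
        + ((iz - cz) / (0.42 * nz)) ** 2
    ) <= 1.0

    z0, z1, z2 = 0.33 * nz, 0.52 * nz, 0.68 * nz  # tentorium / mid / vertex planes
    y1, y2 = 0.38 * ny, 0.62 * ny  # posterior / anterior planes
    medial_cing = np.abs(ix - cx) < 0.10 * nx
    medial_mt = np.abs(ix - cx) < 0.16 * nx
    left = ix < cx

    labels = np.zeros(grid_shape, dtype=np.int32)
    infra = brain & (iz < z0)
    supra = brain & ~infra
    anterior, posterior = iy >= y2, iy < y1
    middle = ~anterior & ~posterior

    lobe_masks = {
        "anterior_cingulate": supra & anterior & (iz >= z1) & medial_cing,
        "frontal": supra & anterior & ~((iz >= z1) & medial_cing),
        "occipital": supra & posterior,
        "parietal": supra & middle & (iz >= z2),
        "posterior_cingulate": supra & middle & (iz >= z1) & (iz < z2) & medial_cing,
        "temporal": supra
        & middle
        & (iz < z2)
        & ~((iz >= z1) & medial_cing)
        & ~((iz < z1) & medial_mt),
        "medial_temporal": supra & middle & (iz < z1) & medial_mt,
    }

    region_table: dict[int, tuple[str, str, str]] = {}
    for lobe, (lid, rid) in CORTICAL_LOBES.items():
        mask = lobe_masks[lobe]
        labels[mask & left] = lid
        labels[mask & ~left] = rid
        region_table[lid] = (f"{lobe}_L", lobe, "L")
        region_table[rid] = (f"{lobe}_R", lobe, "R")
    labels[infra & left] = REFERENCE_IDS[0]
    labels[infra & ~left] = REFERENCE_IDS[1]
    region_table[REFERENCE_IDS[0]] = ("cerebellum_crus_L", "cerebellum", "L")
    region_table[REFERENCE_IDS[1]] = ("cerebellum_crus_R", "cerebellum", "R")

    for rid_, (name, _, _) in region_table.items():
        n = int(np.count_nonzero(labels == rid_))
        if n < _MIN_REGION_VOXELS:
            raise AtlasSizingError(
                f"region {name} received only {n} voxels on grid {grid_shape}; "
                f"use extents of at least {MIN_GRID_EXTENT} voxels"
            )

    rng = np.random.default_rng(seed)
    gm_prob = np.where(labels > 0, 0.9, 0.0)
    gm_prob = np.clip(gm_prob + rng.normal(0.0, 0.02, grid_shape) * (labels > 0), 0.0, 1.0)

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * np.array([cx, cy, cz])
    return AtlasLabelMap(labels, region_table, gm_prob, frozenset(REFERENCE_IDS), affine)
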