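"""Spatial imaging operations: Gaussian smoothing, rigid registration,
template construction and adaptive template selection by slice-wise
normalized cross-correlation (NCC).

The adaptive template method normalizes each amyloid scan against both a
positive and a negative template and keeps the one with the higher NCC.
NCC is computed per axial slice z as

    NCC_z = (1/n) * sum_{x,y} (I - Ibar)(T - Tbar) / (sigma_I * sigma_T)

over in-mask pixels of the slice, with means and population standard
deviations taken over the same pixels — i.e. NCC_z is exactly the Pearson
correlation of the slice's in-mask intensities.  Slices are combined by an
unweighted mean over usable slices.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage, optimize

from .atlas import AtlasLabelMap
from .suvr import GM_THRESHOLD_DEFAULT, voi_median
from .volumes import BrainVolume, resample_rigid

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))
MIN_SLICE_VOXELS = 50


class EmptyOverlapError(ValueError):
    """No axial slice has enough in-mask voxels with nonzero variance."""


class RegistrationError(RuntimeError):
    pass


def gaussian_smooth(volume: BrainVolume, fwhm_mm: float) -> BrainVolume:
    """Isotropic Gaussian smoothing specified by FWHM in world millimetres.

    sigma_mm = fwhm / sqrt(8 ln 2); converted to per-axis voxel units via the
    (axis-aligned) affine.  Reflect boundary handling avoids edge dimming
    inside the brain.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return volume.with_data(volume.data.copy())
    scales = volume.require_axis_aligned()
    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / scales
    return volume.with_data(ndimage.gaussian_filter(volume.data, sigma_vox, mode="reflect"))


# -- templates -------------------------------------------------------------


@dataclasses.dataclass
class TemplatePair:
    """Positive and negative tracer templates sharing one grid."""

    positive: BrainVolume
    negative: BrainVolume
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        if not self.positive.same_grid(self.negative):
            raise ValueError("positive and negative templates are on different grids")
        if self.brain_mask.shape != self.positive.shape:
            raise ValueError("brain_mask shape mismatch")
        self.brain_mask = self.brain_mask.astype(bool)


@dataclasses.dataclass
class NCCResult:
    """Slice-wise NCC audit record."""

    per_slice: dict[int, float]
    aggregate: float
    n_slices_used: int
    n_slices_skipped: int = 0


def build_template(
    volumes: list[BrainVolume],
    atlas: AtlasLabelMap,
    gm_threshold: float = GM_THRESHOLD_DEFAULT,
) -> tuple[BrainVolume, list[float]]:
    """Scale each volume to unit reference-region median, then average.

    Returns the template and the per-subject scaling medians (for the
    sidecar record).  The reference is the atlas's cerebellar grey matter.
    """
    if not volumes:
        raise ValueError("need at least one volume")
    first = volumes[0]
    medians = []
    acc = np.zeros(first.shape, dtype=np.float64)
    for i, vol in enumerate(volumes):
        if not vol.same_grid(first):
            raise ValueError(f"volume {i} is not on the common grid")
        med, _ = voi_median(vol, atlas, atlas.reference_ids, gm_threshold)
        if med <= 0:
            raise ValueError(f"subject {i}: reference median {med:g} is non-positive")
        medians.append(med)
        acc += vol.data / med
    acc /= len(volumes)
    return BrainVolume(acc, first.affine.copy(), first.space, first.modality), medians


def ncc_slicewise(
    image: BrainVolume,
    template: BrainVolume,
    brain_mask: np.ndarray | None = None,
    min_voxels: int = MIN_SLICE_VOXELS,
) -> NCCResult:
    """Slice-wise NCC between an image and a template.

    Axial slices run along the third voxel axis.  A slice contributes when it
    has at least ``min_voxels`` in-mask pixels and nonzero variance in both
    image and template; the aggregate is the unweighted mean over
    contributing slices.  ``brain_mask=None`` uses every pixel.
    """
    if image.shape != template.shape:
        raise ValueError("image and template shapes differ")
    if brain_mask is None:
        brain_mask = np.ones(image.shape, dtype=bool)
    if brain_mask.shape != image.shape:
        raise ValueError("mask shape differs from image")
    per_slice: dict[int, float] = {}
    skipped = 0
    for z in range(image.shape[2]):
        m = brain_mask[:, :, z]
        n = int(np.count_nonzero(m))
        if n < min_voxels:
            skipped += 1
            continue
        i = image.data[:, :, z][m]
        t = template.data[:, :, z][m]
        di, dt = i - i.mean(), t - t.mean()
        si = np.sqrt(np.mean(di * di))
        st = np.sqrt(np.mean(dt * dt))
        if si == 0.0 or st == 0.0:
            skipped += 1
            continue
        per_slice[z] = float(np.mean(di * dt) / (si * st))
    if not per_slice:
        raise EmptyOverlapError("no axial slice has enough usable in-mask voxels")
    vals = np.fromiter(per_slice.values(), dtype=float)
    return NCCResult(per_slice, float(vals.mean()), len(per_slice), skipped)


def select_adaptive_template(
    image: BrainVolume,
    templates: TemplatePair,
    min_voxels: int = MIN_SLICE_VOXELS,
    use_mask: bool = True,
) -> tuple[str, NCCResult, NCCResult]:
    """Pick the template (positive vs negative) with the higher aggregate NCC.

    Ties break toward ``negative`` to avoid inflating amyloid-positive calls
    on uninformative images.  Both NCC results are returned for audit.
    """
    mask = templates.brain_mask if use_mask else None
    ncc_pos = ncc_slicewise(image, templates.positive, mask, min_voxels)
    ncc_neg = ncc_slicewise(image, templates.negative, mask, min_voxels)
    selection = "positive" if ncc_pos.aggregate > ncc_neg.aggregate else "negative"
    return selection, ncc_pos, ncc_neg


# -- rigid registration ----------------------------------------------------


def _neg_ncc(params: np.ndarray, moving: BrainVolume, fixed: BrainVolume, mask: np.ndarray) -> float:
    resampled = resample_rigid(moving, fixed, params[:3], params[3:])
    a = resampled.data[mask]
    b = fixed.data[mask]
    da, db = a - a.mean(), b - b.mean()
    denom = np.sqrt(np.sum(da * da) * np.sum(db * db))
    if denom == 0:
        return 0.0
    return -float(np.sum(da * db) / denom)


def rigid_register(
    moving: BrainVolume,
    fixed: BrainVolume,
    presmooth_fwhm_mm: float = 8.0,
    xtol: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the rigid transform aligning ``moving`` to ``fixed``.

    Maximizes normalized correlation over 3 translations (mm) and 3 rotations
    (degrees, about the fixed grid centre) with a Powell search started at the
    identity; both inputs are pre-smoothed to widen the capture range.
    Returns ``(translation_mm, rotation_deg)``; apply with
    :func:`petatn.volumes.resample_rigid`.
    """
    vs_m, vs_f = moving.voxel_sizes, fixed.voxel_sizes
    if np.any(np.abs(vs_m - vs_f) > 0.1 * vs_f):
        raise ValueError("moving and fixed voxel sizes differ by more than 10%")
    mov_s = gaussian_smooth(moving, presmooth_fwhm_mm)
    fix_s = gaussian_smooth(fixed, presmooth_fwhm_mm)
    mask = fix_s.data > (0.05 * fix_s.data.max())
    if not mask.any():
        raise RegistrationError("fixed volume is empty")
    res = optimize.minimize(
        _neg_ncc,
        np.zeros(6),
        args=(mov_s, fix_s, mask),
        method="Powell",
        options={"xtol": xtol, "ftol": 1e-8, "maxiter": 2000},
    )
    if not res.success and -res.fun < 0.5:
        raise RegistrationError(
            f"rigid registration failed to converge (final NCC {-res.fun:.3f})"
        )
    logger.debug("rigid_register: params=%s, NCC=%.4f", res.x, -res.fun)
    return res.x[:3].copy(), res.x[3:].copy()
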