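"""Nonparametric group comparison and voxel-wise cluster-extent inference.

Atlas-based: per meta-VOI, a Kruskal-Wallis omnibus test across the three
A/T/N groups followed by pairwise two-sided rank-sum tests with Bonferroni
adjustment, plus Cliff's delta effect sizes with the conventional magnitude
bands (|delta| < 0.33 small, 0.33-0.47 medium, > 0.47 large).

Voxel-wise: Welch two-sample t-maps (unequal variances, per-voxel
Satterthwaite df) thresholded at an uncorrected voxel p, with family-wise
error control at the cluster level by a max-cluster-size permutation null
and an additional extent filter k > k_min.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .suvr import SUVRTable
from .volumes import BrainVolume

logger = logging.getLogger(__name__)

DELTA_SMALL, DELTA_MEDIUM = 0.33, 0.47


def delta_magnitude(delta: float) -> str:
    """Magnitude band of a Cliff's delta value."""
    a = abs(delta)
    if a < DELTA_SMALL:
        return "small"
    if a <= DELTA_MEDIUM:
        return "medium"
    return "large"


def cliffs_delta(x, y) -> tuple[float, str]:
    """Cliff's delta: P(x > y) - P(x < y) over all cross-group pairs.

    Ranges over [-1, 1]; +1/-1 is perfect separation, 0 complete overlap.
    Ties contribute zero.  Positive delta means ``x`` stochastically larger.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    diff = x[:, None] - y[None, :]
    delta = float((np.sign(diff)).sum() / (x.size * y.size))
    return delta, delta_magnitude(delta)


@dataclasses.dataclass
class PairwiseContrast:
    group_a: str
    group_b: str
    p_raw: float
    p_adjusted: float
    delta: float
    magnitude: str


@dataclasses.dataclass
class VOIComparison:
    voi: str
    medians: dict[str, float]
    iqrs: dict[str, float]
    n: dict[str, int]
    omnibus_p: float
    contrasts: list[PairwiseContrast]


@dataclasses.dataclass
class GroupComparisonResult:
    vois: dict[str, VOIComparison]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per VOI x pairwise contrast."""
        rows = []
        for voi, cmp_ in self.vois.items():
            for c in cmp_.contrasts:
                rows.append(
                    {
                        "voi": voi,
                        "contrast": f"{c.group_a}_vs_{c.group_b}",
                        "omnibus_p": cmp_.omnibus_p,
                        "p_raw": c.p_raw,
                        "p_adjusted": c.p_adjusted,
                        "delta": c.delta,
                        "magnitude": c.magnitude,
                        **{f"median_{g}": m for g, m in cmp_.medians.items()},
                        **{f"iqr_{g}": v for g, v in cmp_.iqrs.items()},
                    }
                )
        return pd.DataFrame(rows)


def compare_groups_atlas(
    suvr: SUVRTable,
    groups: dict[str, str],
    metavois: list[str] | None = None,
    alpha: float = 0.05,
    modality: str = "PBB3",
) -> GroupComparisonResult:
    """Compare meta-VOI SUVRs between A/T/N groups.

    Per VOI: Kruskal-Wallis omnibus over all groups, then pairwise two-sided
    Mann-Whitney tests Bonferroni-adjusted by the number of pairs, with
    Cliff's delta, group medians and IQRs.  Every group needs >= 2 members.
    """
    pivot = suvr.pivot(modality)
    pivot = pivot.loc[[p for p in pivot.index if p in groups]]
    group_names = sorted(set(groups[p] for p in pivot.index))
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    members = {g: [p for p in pivot.index if groups[p] == g] for g in group_names}
    for g, m in members.items():
        if len(m) < 2:
            raise ValueError(f"group {g} has fewer than 2 members")
    if metavois is None:
        metavois = [c for c in pivot.columns]
    pairs = list(itertools.combinations(group_names, 2))
    out: dict[str, VOIComparison] = {}
    for voi in metavois:
        samples = {g: pivot.loc[members[g], voi].to_numpy() for g in group_names}
        omni_p = float(stats.kruskal(*samples.values()).pvalue)
        contrasts = []
        for ga, gb in pairs:
            p_raw = float(
                stats.mannwhitneyu(samples[ga], samples[gb], alternative="two-sided").pvalue
            )
            delta, mag = cliffs_delta(samples[ga], samples[gb])
            contrasts.append(
                PairwiseContrast(ga, gb, p_raw, min(1.0, p_raw * len(pairs)), delta, mag)
            )
        out[voi] = VOIComparison(
            voi=voi,
            medians={g: float(np.median(s)) for g, s in samples.items()},
            iqrs={g: float(np.subtract(*np.percentile(s, [75, 25]))) for g, s in samples.items()},
            n={g: int(s.size) for g, s in samples.items()},
            omnibus_p=omni_p,
            contrasts=contrasts,
        )
    return GroupComparisonResult(out, alpha)


# -- voxel-wise ------------------------------------------------------------


def voxelwise_welch_t(
    group_a: list[BrainVolume],
    group_b: list[BrainVolume],
    mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch t-map (A minus B) with per-voxel Satterthwaite df.

    Returns ``(t_map, df_map, zero_variance_flags)``; voxels with zero
    variance in both groups get t = 0 and are flagged.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 volumes")
    shape = group_a[0].shape
    for v in group_a + group_b:
        if v.shape != shape:
            raise ValueError("volume shape mismatch")
    A = np.stack([v.data for v in group_a])
    B = np.stack([v.data for v in group_b])
    return _welch_arrays(A, B, mask)


def _welch_arrays(A: np.ndarray, B: np.ndarray, mask: np.ndarray):
    na, nb = A.shape[0], B.shape[0]
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va = A.var(axis=0, ddof=1) / na
    vb = B.var(axis=0, ddof=1) / nb
    denom2 = va + vb
    zero = denom2 <= 0
    t = np.zeros(ma.shape)
    df = np.full(ma.shape, float(na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, (ma - mb) / np.sqrt(np.where(zero, 1.0, denom2)))
        df_num = denom2**2
        df_den = va**2 / (na - 1) + vb**2 / (nb - 1)
        df = np.where(zero, na + nb - 2, df_num / np.where(df_den <= 0, 1.0, df_den))
    t = np.where(mask, t, 0.0)
    return t, df, zero & mask


@dataclasses.dataclass
class Cluster:
    voxels: np.ndarray  # boolean grid
    size: int
    peak_t: float
    corrected_p: float


@dataclasses.dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    threshold_map: np.ndarray  # per-voxel t threshold (df-dependent)
    n_permutations: int
    seed: int | None
    max_size_null: np.ndarray
    exhaustive: bool = False


def _connectivity(conn: int) -> np.ndarray:
    if conn == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if conn == 18:
        s = np.ones((3, 3, 3), dtype=bool)
        for dx, dy, dz in itertools.product((0, 2), repeat=3):
            s[dx, dy, dz] = False
        return s
    if conn == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6, 18 or 26")


def _suprathreshold(t, df, mask, voxel_p):
    """Two-tailed voxel threshold in the A > B direction."""
    t_crit = stats.t.ppf(1.0 - voxel_p / 2.0, df)
    return mask & (t > t_crit), t_crit


def _max_cluster_size(sig: np.ndarray, structure: np.ndarray) -> int:
    labelled, n = ndimage.label(sig, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labelled.ravel())[1:].max())


def cluster_extent_inference(
    group_a: list[BrainVolume],
    group_b: list[BrainVolume],
    mask: np.ndarray,
    voxel_p: float = 0.01,
    k_min: int = 100,
    cluster_alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int | None = 0,
    connectivity: int = 26,
) -> ClusterResult:
    """Cluster-level FWE by a max-cluster-size permutation null.

    Suprathreshold voxels (two-tailed p < ``voxel_p``, direction A > B) are
    grouped by 26-connectivity.  The null distribution of the maximum
    cluster size is built by randomly relabelling subjects and re-running
    the t + threshold step; a cluster's corrected p is
    ``(1 + #{perm max >= size}) / (1 + n_perm)``.  Reported clusters need
    corrected p < ``cluster_alpha`` and size > ``k_min``.  When fewer
    distinct relabellings exist than ``n_permutations``, all of them are
    enumerated instead.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    na, nb = len(group_a), len(group_b)
    A = np.stack([v.data for v in group_a])
    B = np.stack([v.data for v in group_b])
    structure = _connectivity(connectivity)

    t_obs, df_obs, _ = _welch_arrays(A, B, mask)
    sig_obs, thr_map = _suprathreshold(t_obs, df_obs, mask, voxel_p)
    labelled, n_comp = ndimage.label(sig_obs, structure=structure)

    pool = np.concatenate([A, B])
    n_total = na + nb
    total_relabelings = math.comb(n_total, na)
    rng = np.random.default_rng(seed)
    exhaustive = total_relabelings <= n_permutations
    if exhaustive:
        logger.info(
            "only %d distinct relabelings; enumerating all instead of sampling %d",
            total_relabelings, n_permutations,
        )
        assignments = itertools.combinations(range(n_total), na)
        n_perm = total_relabelings
    else:
        assignments = (
            tuple(rng.permutation(n_total)[:na]) for _ in range(n_permutations)
        )
        n_perm = n_permutations

    null_sizes = np.empty(n_perm, dtype=int)
    for i, idx_a in enumerate(assignments):
        sel = np.zeros(n_total, dtype=bool)
        sel[list(idx_a)] = True
        t_p, df_p, _ = _welch_arrays(pool[sel], pool[~sel], mask)
        sig_p, _ = _suprathreshold(t_p, df_p, mask, voxel_p)
        null_sizes[i] = _max_cluster_size(sig_p, structure)

    clusters = []
    for lab in range(1, n_comp + 1):
        comp = labelled == lab
        size = int(comp.sum())
        p_corr = float((1 + np.sum(null_sizes >= size)) / (1 + n_perm))
        if size > k_min and p_corr < cluster_alpha:
            clusters.append(Cluster(comp, size, float(t_obs[comp].max()), p_corr))
    clusters.sort(key=lambda c: -c.size)
    return ClusterResult(
        clusters, t_obs, thr_map, n_perm, seed, null_sizes, exhaustive
    )


def summarize_cluster(
    cluster_voxels: np.ndarray,
    subject_volumes: dict[str, BrainVolume],
    groups: dict[str, str],
) -> pd.DataFrame:
    """Per-group median/IQR of subjects' median SUVR over a cluster, plus
    pairwise Cliff's delta — the row format of a cluster-report table."""
    if not cluster_voxels.any():
        raise ValueError("cluster is empty")
    per_subject = {
        pid: float(np.median(vol.data[cluster_voxels]))
        for pid, vol in subject_volumes.items()
    }
    group_names = sorted(set(groups[p] for p in per_subject))
    samples = {
        g: np.array([v for p, v in per_subject.items() if groups[p] == g])
        for g in group_names
    }
    rows = []
    for ga, gb in itertools.combinations(group_names, 2):
        delta, mag = cliffs_delta(samples[ga], samples[gb])
        rows.append(
            {
                "contrast": f"{ga}_vs_{gb}",
                f"median_{ga}": float(np.median(samples[ga])),
                f"iqr_{ga}": float(np.subtract(*np.percentile(samples[ga], [75, 25]))),
                f"median_{gb}": float(np.median(samples[gb])),
                f"iqr_{gb}": float(np.subtract(*np.percentile(samples[gb], [75, 25]))),
                "delta": delta,
                "magnitude": mag,
            }
        )
    return pd.DataFrame(rows)
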