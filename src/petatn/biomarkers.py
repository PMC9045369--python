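"""Biomarker thresholding and A/T/N group assignment.

Amyloid (A) status comes from the global PIB SUVR against a ROC/Youden
cutoff — validated by leave-one-out cross-validation — or, when no amyloid
PET exists, from CSF Abeta42 below 600 ng/L.  Neurodegeneration (N) status
comes from single-subject FDG hypometabolism mapping against a control
cohort, or from CSF t-tau above 450 ng/L.  Tau positivity is never
thresholded (groups are A/T*/N): A+ subjects form the AD continuum, A-N+ is
SNAP (suspected non-AD pathophysiology) and A-N- is biomarker-negative.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import math

import numpy as np
from scipy import ndimage, stats

from .volumes import BrainVolume

logger = logging.getLogger(__name__)

AB42_CUTOFF_NG_L = 600.0
TTAU_CUTOFF_NG_L = 450.0
BORDERLINE_PCT = 10.0


class ATNGroup(enum.Enum):
    AD_CONTINUUM = "AD_CONTINUUM"
    SNAP = "SNAP"
    BN = "BN"
    UNCLASSIFIABLE = "UNCLASSIFIABLE"


@dataclasses.dataclass
class BiomarkerProfile:
    """Per-patient A and N statuses with their sources and raw values."""

    patient_id: str
    A_status: str = "missing"  # positive | negative | missing
    A_source: str | None = None  # PET | CSF
    N_status: str = "missing"
    N_source: str | None = None  # FDG | CSF
    csf_ab42: float | None = None
    csf_ttau: float | None = None
    global_pib_suvr: float | None = None
    borderline_flags: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        for status, source, letter in (
            (self.A_status, self.A_source, "A"),
            (self.N_status, self.N_source, "N"),
        ):
            if status not in ("positive", "negative", "missing"):
                raise ValueError(f"bad {letter} status {status!r}")
            if status != "missing" and source is None:
                raise ValueError(f"{letter} status present without a source")


def classify_csf(
    ab42: float | None,
    ttau: float | None,
    ab42_cutoff: float = AB42_CUTOFF_NG_L,
    ttau_cutoff: float = TTAU_CUTOFF_NG_L,
) -> tuple[str, str]:
    """CSF rule: A+ iff Abeta42 < cutoff; N+ iff t-tau > cutoff (both strict).

    ``None``/NaN inputs yield ``missing``; negative concentrations are a data
    error.
    """
    def one(value, cutoff, positive_below: bool) -> str:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return "missing"
        if value < 0:
            raise ValueError(f"negative CSF concentration {value!r}")
        hit = value < cutoff if positive_below else value > cutoff
        return "positive" if hit else "negative"

    return one(ab42, ab42_cutoff, True), one(ttau, ttau_cutoff, False)


def flag_borderline(value: float, cutoff: float, pct: float = BORDERLINE_PCT) -> bool:
    """True iff ``value`` lies within ±pct% of the cutoff (inclusive)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return abs(value - cutoff) <= (pct / 100.0) * cutoff


# -- ROC / Youden cutoff ---------------------------------------------------


@dataclasses.dataclass
class CutoffResult:
    """ROC-derived classification cutoff and its operating characteristics."""

    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    auc: float
    roc_points: list[tuple[float, float, float]]  # (threshold, sens, spec)
    loocv_accuracy: float | None = None


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _sens_spec(values, labels, threshold) -> tuple[float, float]:
    pred = values >= threshold
    sens = float(np.mean(pred[labels])) if labels.any() else float("nan")
    spec = float(np.mean(~pred[~labels])) if (~labels).any() else float("nan")
    return sens, spec


def youden_cutoff(scores: list[tuple[float, bool]]) -> CutoffResult:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between consecutive sorted unique
    scores plus ±inf; classification is ``value >= threshold -> positive``.
    Among tied maxima the lowest threshold is chosen (favours sensitivity).
    AUC is the trapezoidal area under the ROC traced by the candidates.
    """
    values = np.array([v for v, _ in scores], dtype=float)
    labels = np.array([bool(l) for _, l in scores])
    if not labels.any() or labels.all():
        raise ValueError("need at least one positive and one negative score")
    roc = []
    best = None
    for thr in _candidate_thresholds(values):
        sens, spec = _sens_spec(values, labels, thr)
        roc.append((float(thr), sens, spec))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    j, thr, sens, spec = best
    # ROC points sorted by decreasing threshold -> increasing FPR
    roc_sorted = sorted(roc, key=lambda p: -p[0] if np.isfinite(p[0]) else -np.sign(p[0]) * np.inf)
    fpr = np.array([1.0 - spec_ for _, _, spec_ in roc_sorted])
    tpr = np.array([sens_ for _, sens_, _ in roc_sorted])
    auc = float(np.trapezoid(tpr, fpr))
    return CutoffResult(float(thr), sens, spec, float(j), auc, roc)


def loocv_accuracy(scores: list[tuple[float, bool]]) -> float:
    """Leave-one-out accuracy of the Youden cutoff.

    Each sample is classified by the cutoff refit on the other n-1 samples;
    a single-class fold falls back to the full-data cutoff with a warning.
    """
    if len(scores) < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    full = youden_cutoff(scores)
    correct = 0
    for i, (value, label) in enumerate(scores):
        rest = scores[:i] + scores[i + 1 :]
        rest_labels = {l for _, l in rest}
        if len(rest_labels) < 2:
            logger.warning("LOOCV fold %d has a single class; using the full-data cutoff", i)
            thr = full.cutoff
        else:
            thr = youden_cutoff(rest).cutoff
        if (value >= thr) == bool(label):
            correct += 1
    return correct / len(scores)


# -- single-subject FDG hypometabolism ------------------------------------


@dataclasses.dataclass
class HypoCluster:
    voxels: np.ndarray  # boolean grid
    size: int
    peak_t: float


def fdg_single_subject(
    patient: BrainVolume,
    controls: list[BrainVolume],
    patient_age: float,
    patient_sex: int,
    control_ages: list[float],
    control_sexes: list[int],
    susceptible_mask: np.ndarray,
    brain_mask: np.ndarray | None = None,
    voxel_p: float = 0.05,
    k_min: int = 100,
) -> tuple[str, list[HypoCluster]]:
    """Detect single-subject hypometabolism against a control cohort.

    Per in-mask voxel a linear model with intercept, centred age and a binary
    sex indicator is fitted to the controls; the patient's studentized
    prediction residual gives a two-sided p-value (Student t, df = n - 3),
    Bonferroni-corrected over in-mask voxels.  Hypometabolic voxels
    (patient below the control prediction) surviving correction are grouped
    by 26-connectivity; a cluster of at least ``k_min`` voxels intersecting
    ``susceptible_mask`` (regions typically affected by neurodegenerative
    dementia) yields N+.
    """
    n = len(controls)
    if n < 20:
        raise ValueError(f"need at least 20 controls, got {n}")
    if len(control_ages) != n or len(control_sexes) != n:
        raise ValueError("covariate lengths do not match the control count")
    shape = patient.shape
    for c in controls:
        if c.shape != shape:
            raise ValueError("control volume shape mismatch")
    if brain_mask is None:
        brain_mask = np.ones(shape, dtype=bool)
    mask = brain_mask.astype(bool)
    v = int(mask.sum())
    if v == 0:
        raise ValueError("empty brain mask")

    ages = np.asarray(control_ages, dtype=float)
    age_center = ages.mean()
    X = np.column_stack(
        [np.ones(n), ages - age_center, np.asarray(control_sexes, dtype=float)]
    )
    p_cov = X.shape[1]
    if n < p_cov + 3:
        raise ValueError("too few controls for the covariate model")
    Y = np.stack([c.data[mask] for c in controls])  # n x v
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # p x v
    resid = Y - X @ beta
    df = n - p_cov
    s2 = np.sum(resid * resid, axis=0) / df
    x0 = np.array([1.0, patient_age - age_center, float(patient_sex)])
    leverage = float(x0 @ XtX_inv @ x0)
    denom = np.sqrt(np.maximum(s2 * (1.0 + leverage), 1e-300))
    t_vals = (patient.data[mask] - x0 @ beta) / denom
    p_two = 2.0 * stats.t.sf(np.abs(t_vals), df)
    p_corr = np.minimum(p_two * v, 1.0)

    sig = (p_corr < voxel_p) & (t_vals < 0)  # hypometabolic direction only
    sig_grid = np.zeros(shape, dtype=bool)
    sig_grid[mask] = sig
    t_grid = np.zeros(shape)
    t_grid[mask] = t_vals

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labelled, n_comp = ndimage.label(sig_grid, structure=structure)
    clusters = []
    for lab in range(1, n_comp + 1):
        comp = labelled == lab
        size = int(comp.sum())
        if size >= k_min and np.any(comp & susceptible_mask):
            clusters.append(HypoCluster(comp, size, float(np.abs(t_grid[comp]).max())))
    status = "positive" if clusters else "negative"
    return status, clusters


# -- grouping --------------------------------------------------------------


def assign_atn_group(profile: BiomarkerProfile) -> ATNGroup:
    """A+ -> AD continuum (any N); A-N+ -> SNAP; A-N- -> biomarker-negative;
    missing A or N -> unclassifiable."""
    if profile.A_status == "missing" or profile.N_status == "missing":
        return ATNGroup.UNCLASSIFIABLE
    if profile.A_status == "positive":
        return ATNGroup.AD_CONTINUUM
    return ATNGroup.SNAP if profile.N_status == "positive" else ATNGroup.BN


def build_profile(
    patient_id: str,
    csf_ab42: float | None = None,
    csf_ttau: float | None = None,
    global_pib_suvr: float | None = None,
    pib_cutoff: float | None = None,
    fdg_status: str | None = None,
    ab42_cutoff: float = AB42_CUTOFF_NG_L,
    ttau_cutoff: float = TTAU_CUTOFF_NG_L,
    borderline_pct: float = BORDERLINE_PCT,
) -> BiomarkerProfile:
    """Combine PET and CSF evidence into one profile.

    PET takes precedence over CSF for each letter; a PET/CSF disagreement is
    logged, and CSF values within ±``borderline_pct``% of their cutoff are
    flagged for audit.
    """
    a_csf, n_csf = classify_csf(csf_ab42, csf_ttau, ab42_cutoff, ttau_cutoff)
    flags: list[str] = []
    if csf_ab42 is not None and not _isnan(csf_ab42) and flag_borderline(csf_ab42, ab42_cutoff, borderline_pct):
        flags.append("csf_ab42_borderline")
    if csf_ttau is not None and not _isnan(csf_ttau) and flag_borderline(csf_ttau, ttau_cutoff, borderline_pct):
        flags.append("csf_ttau_borderline")

    a_status, a_source = a_csf, ("CSF" if a_csf != "missing" else None)
    if global_pib_suvr is not None and not _isnan(global_pib_suvr) and pib_cutoff is not None:
        a_pet = "positive" if global_pib_suvr >= pib_cutoff else "negative"
        if a_csf != "missing" and a_csf != a_pet:
            logger.warning(
                "%s: amyloid PET (%s) and CSF (%s) disagree; PET takes precedence",
                patient_id, a_pet, a_csf,
            )
            flags.append("amyloid_pet_csf_disagreement")
        a_status, a_source = a_pet, "PET"

    n_status, n_source = n_csf, ("CSF" if n_csf != "missing" else None)
    if fdg_status in ("positive", "negative"):
        if n_csf != "missing" and n_csf != fdg_status:
            logger.warning(
                "%s: FDG (%s) and CSF t-tau (%s) disagree; FDG takes precedence",
                patient_id, fdg_status, n_csf,
            )
            flags.append("neurodegeneration_fdg_csf_disagreement")
        n_status, n_source = fdg_status, "FDG"

    return BiomarkerProfile(
        patient_id=patient_id,
        A_status=a_status,
        A_source=a_source,
        N_status=n_status,
        N_source=n_source,
        csf_ab42=csf_ab42,
        csf_ttau=csf_ttau,
        global_pib_suvr=global_pib_suvr,
        borderline_flags=flags,
    )


def _isnan(x) -> bool:
    return isinstance(x, float) and math.isnan(x)
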