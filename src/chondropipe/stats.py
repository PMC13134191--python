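"""Evaluation metrics and inferential statistics.

Segmentation metrics (DSC, MASD), one-vs-all classification metrics,
rank-based AUC, BCa bootstrap confidence intervals, the DeLong test for
correlated AUCs, and paired permutation tests.

Conventions (documented because the degenerate cases matter for empty
segmentation predictions):

* DSC of two empty masks is 1.0; one empty, one not is 0.0.
* MASD is defined only when both masks have nonempty surfaces; otherwise
  ``None`` is returned.
* Zero-denominator classification cells are reported as 0.0 and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from scipy.spatial import cKDTree

from .imaging_core import surface_voxels

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Segmentation metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SegScore:
    """Per-case segmentation score."""

    dsc: float
    masd_mm: float | None
    precision: float
    sensitivity: float
    empty_gt: bool
    empty_pred: bool


def dsc(gt: np.ndarray, pred: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two binary masks.

    Both masks empty -> 1.0 by convention (logged).
    """
    gt = np.asarray(gt, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if gt.shape != pred.shape:
        raise ValueError(f"grid mismatch: {gt.shape} vs {pred.shape}")
    a, b = int(gt.sum()), int(pred.sum())
    if a + b == 0:
        logger.debug("DSC of two empty masks -> 1.0 by convention")
        return 1.0
    inter = int(np.count_nonzero(gt & pred))
    return 2.0 * inter / (a + b)


def masd(gt: np.ndarray, pred: np.ndarray,
         spacing: tuple[float, float, float]) -> float | None:
    """Mean absolute surface distance in mm, or None if either mask is empty.

    Symmetric average of the two directed mean nearest-surface-voxel
    distances; surfaces are 6-neighborhood boundary voxels and distances are
    center-to-center in physical mm.
    """
    gt = np.asarray(gt, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if gt.shape != pred.shape:
        raise ValueError(f"grid mismatch: {gt.shape} vs {pred.shape}")
    s_gt = surface_voxels(gt)
    s_pred = surface_voxels(pred)
    if len(s_gt) == 0 or len(s_pred) == 0:
        return None
    sp = np.asarray(spacing, dtype=float)
    p_gt = s_gt * sp
    p_pred = s_pred * sp
    d_gp = cKDTree(p_pred).query(p_gt)[0]
    d_pg = cKDTree(p_gt).query(p_pred)[0]
    return 0.5 * (float(d_gp.mean()) + float(d_pg.mean()))


def seg_score(gt: np.ndarray, pred: np.ndarray,
              spacing: tuple[float, float, float]) -> SegScore:
    """DSC, MASD, voxel precision and sensitivity for one case."""
    gt = np.asarray(gt, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    tp = int(np.count_nonzero(gt & pred))
    n_pred, n_gt = int(pred.sum()), int(gt.sum())
    return SegScore(
        dsc=dsc(gt, pred),
        masd_mm=masd(gt, pred, spacing),
        precision=tp / n_pred if n_pred else 0.0,
        sensitivity=tp / n_gt if n_gt else 0.0,
        empty_gt=n_gt == 0,
        empty_pred=n_pred == 0,
    )


# --------------------------------------------------------------------------
# Classification metrics
# --------------------------------------------------------------------------

@dataclass
class EvalReport:
    """One-vs-all classification metrics with optional BCa CIs."""

    classes: tuple[str, ...]
    per_class: dict  # class -> {metric -> value}
    confusion: np.ndarray  # rows = truth, cols = predicted
    n_per_class: dict
    ci: dict = field(default_factory=dict)  # class -> {metric -> (lo, hi)}
    flags: list = field(default_factory=list)


def _one_vs_all(truth: np.ndarray, pred: np.ndarray, cls) -> dict:
    t = truth == cls
    p = pred == cls
    tp = int(np.count_nonzero(t & p))
    fp = int(np.count_nonzero(~t & p))
    fn = int(np.count_nonzero(t & ~p))
    tn = int(np.count_nonzero(~t & ~p))
    prec = tp / (tp + fp) if tp + fp else 0.0
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {"Precision": prec, "Sensitivity": sens, "Specificity": spec, "F1": f1}


def classification_report(
    truth,
    pred,
    classes=("NT", "EC", "ACT"),
    ci: bool = False,
    n_resamples: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> EvalReport:
    """Per-class one-vs-all Precision/Sensitivity/Specificity/F1.

    With ``ci=True``, BCa bootstrap intervals over cases are attached.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("truth and predictions must have equal length")
    seen = set(np.unique(truth)) | set(np.unique(pred))
    unknown = seen - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class set {classes}: {sorted(unknown)}")
    per_class, flags = {}, []
    for cls in classes:
        m = _one_vs_all(truth, pred, cls)
        per_class[cls] = m
        for k, v in m.items():
            if v == 0.0 and np.count_nonzero(truth == cls) == 0:
                flags.append(f"{cls}/{k}: no cases of this class")
    cmat = np.zeros((len(classes), len(classes)), dtype=int)
    idx = {c: i for i, c in enumerate(classes)}
    for t, p in zip(truth, pred):
        cmat[idx[t], idx[p]] += 1
    report = EvalReport(
        classes=tuple(classes),
        per_class=per_class,
        confusion=cmat,
        n_per_class={c: int(np.count_nonzero(truth == c)) for c in classes},
    )
    if ci:
        rng = np.random.default_rng(seed)
        n = len(truth)
        for cls in classes:
            report.ci[cls] = {}
            for metric in ("Precision", "Sensitivity", "Specificity", "F1"):
                def stat(indices):
                    i = np.asarray(indices, dtype=int)
                    return _one_vs_all(truth[i], pred[i], cls)[metric]
                lo, hi = bca_ci(stat, np.arange(n), n_resamples=n_resamples,
                                level=level,
                                seed=int(rng.integers(2**31 - 1)))
                report.ci[cls][metric] = (lo, hi)
    return report


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling.

    ``labels`` are binary; 1 (or True) is the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = sstats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# --------------------------------------------------------------------------
# Bootstrap / inference
# --------------------------------------------------------------------------

def bca_ci(
    statistic,
    sample,
    n_resamples: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    vectorized: bool | None = None,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI for a 1-sample statistic.

    A degenerate bootstrap distribution (e.g. a constant sample) collapses
    to the point interval, with a log flag.
    """
    sample = np.asarray(sample)
    if sample.size < 2:
        raise ValueError("BCa requires sample size >= 2")
    point = float(statistic(sample))
    if not np.isfinite(point):
        raise ValueError("statistic not finite on the sample")
    if sample.dtype.kind in "fiu" and np.ptp(sample) == 0:
        logger.debug("degenerate (constant) sample -> point interval")
        return (point, point)
    if vectorized is None:
        vectorized = False
    try:
        res = sstats.bootstrap(
            (sample,),
            statistic,
            n_resamples=n_resamples,
            confidence_level=level,
            method="BCa",
            vectorized=vectorized,
            random_state=np.random.default_rng(seed),
        )
    except Exception as exc:  # statistic undefined on a jackknife subsample
        raise ValueError(f"BCa failed (statistic undefined on a resample?): {exc}")
    lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    if not np.isfinite(lo) or not np.isfinite(hi):
        logger.warning("degenerate bootstrap distribution -> point interval")
        return (point, point)
    return (lo, hi)


def mann_whitney_r(x, y) -> float:
    """Effect size r = |Z| / sqrt(N) from the normal approximation of the
    two-sided Mann-Whitney U statistic, with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = sstats.rankdata(np.concatenate([x, y]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 0.0
    z = (u - mu) / np.sqrt(var)
    return float(abs(z) / np.sqrt(n))


def _delong_structural(scores: np.ndarray, labels: np.ndarray):
    """Per-observation structural components V10 (positives), V01 (negatives)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    # psi(x, y) = 1 if x > y, 0.5 if x == y, 0 otherwise
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    a = psi.mean()
    return a, v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """DeLong comparison of two correlated AUCs on paired scores.

    Returns (AUC_A, AUC_B, z, two-sided p).  Identical score vectors give
    p = 1 exactly.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("paired scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise ValueError("DeLong requires both classes present")
    auc_a, v10_a, v01_a = _delong_structural(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_structural(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return (float(auc_a), float(auc_b), 0.0, 1.0)
        raise ValueError("zero DeLong variance with unequal AUCs: inconsistent input")
    z = diff / np.sqrt(var)
    p = 2 * sstats.norm.sf(abs(z))
    return (float(auc_a), float(auc_b), float(z), float(min(p, 1.0)))


def permutation_test(
    metric,
    predictions_a,
    predictions_b,
    truth,
    n_iter: int = 10_000,
    seed: int | None = None,
) -> float:
    """Paired two-sided permutation test of metric(A) - metric(B).

    The null distribution swaps A/B within each case independently with
    probability 1/2; p = (1 + #{|null| >= |obs|}) / (n_iter + 1).
    """
    a = np.asarray(predictions_a)
    b = np.asarray(predictions_b)
    truth = np.asarray(truth)
    if not (len(a) == len(b) == len(truth)):
        raise ValueError("paired predictions and truth must have equal length")
    obs = metric(a, truth) - metric(b, truth)
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    attempts = 0
    n = len(a)
    while done < n_iter:
        attempts += 1
        if attempts > 10 * n_iter + 100:
            raise RuntimeError("too many invalid permutations")
        swap = rng.random(n) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        try:
            stat = metric(pa, truth) - metric(pb, truth)
        except Exception:
            logger.debug("metric undefined under a swap; permutation resampled")
            continue
        if not np.isfinite(stat):
            continue
        if abs(stat) >= abs(obs) - 1e-12:
            count += 1
        done += 1
    return (1 + count) / (n_iter + 1)
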