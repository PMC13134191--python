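"""Case-level NT/EC/ACT classification by voxel-vote aggregation.

A multi-label lesion segmentation is reduced to one number per case: the
ACT fraction of tumor voxels, n_ACT / (n_ACT + n_EC).  Thresholding that
fraction classifies the case (>= theta -> ACT); an empty mask maps to NT in
the scouting phase and to EC in the final phase.  The threshold is
optimized by exhaustive ROC-style search for maximal ACT F1.

The fraction scale (rather than a literal ACT:EC odds ratio) is used because
majority voting corresponds to a fraction threshold of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging_core import ACT, EC, MultiLabelMask
from .stats import auc as rank_auc


class _NoTumor:
    """Sentinel for masks without any tumor-labeled voxel."""

    def __repr__(self):
        return "NO_TUMOR"

    def __bool__(self):
        return False


NO_TUMOR = _NoTumor()


@dataclass(frozen=True)
class RatioDecisionRule:
    """ACT-fraction threshold plus the empty-mask policy for the phase."""

    theta: float = 0.5
    empty_policy: str = "as_NT"  # scouting phase; final phase uses "as_EC"

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.empty_policy not in ("as_NT", "as_EC"):
            raise ValueError("empty_policy must be 'as_NT' or 'as_EC'")


@dataclass
class ThresholdSearchResult:
    theta_star: float
    table: pd.DataFrame  # columns: threshold, precision, sensitivity, f1
    auc_of_act_fraction: float


def act_fraction(mask: MultiLabelMask):
    """ACT share of tumor voxels, or NO_TUMOR for an empty mask (never 0.0)."""
    n_act = mask.count(ACT)
    n_ec = mask.count(EC)
    if n_act + n_ec == 0:
        return NO_TUMOR
    return n_act / (n_act + n_ec)


def classify_case(mask: MultiLabelMask, rule: RatioDecisionRule) -> str:
    """NT/EC/ACT decision for one mask under a decision rule.

    Fraction exactly at theta classifies as ACT (the tie favors the
    clinically costly class)."""
    frac = act_fraction(mask)
    if frac is NO_TUMOR:
        return "NT" if rule.empty_policy == "as_NT" else "EC"
    return "ACT" if frac >= rule.theta else "EC"


def _act_f1_at(fractions: np.ndarray, is_act: np.ndarray, theta: float):
    pred_act = fractions >= theta
    tp = int(np.count_nonzero(pred_act & is_act))
    fp = int(np.count_nonzero(pred_act & ~is_act))
    fn = int(np.count_nonzero(~pred_act & is_act))
    prec = tp / (tp + fp) if tp + fp else 0.0
    sens = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return prec, sens, f1


def optimize_ratio_threshold(fractions, classes) -> ThresholdSearchResult:
    """Exhaustive ACT-F1-maximizing threshold search over observed fractions.

    ``classes`` are ground-truth labels restricted to {EC, ACT}; NO_TUMOR
    cases must be excluded or mapped by the caller first.  Candidate
    thresholds are every distinct observed fraction plus 0 and a value above
    1; ties in F1 break toward the lower threshold (favoring ACT
    sensitivity).  The AUC of the fraction as an ACT score is also returned.
    """
    fractions = np.asarray(fractions, dtype=float)
    classes = np.asarray(classes)
    bad = set(np.unique(classes)) - {"EC", "ACT"}
    if bad:
        raise ValueError(f"classes must be EC or ACT, got extraneous {sorted(bad)}")
    is_act = classes == "ACT"
    if is_act.all() or not is_act.any():
        raise ValueError("threshold optimization needs both EC and ACT cases")
    candidates = np.unique(np.concatenate([[0.0], fractions, [1.0 + 1e-9]]))
    rows = []
    best = (-1.0, None)
    for theta in candidates:
        prec, sens, f1 = _act_f1_at(fractions, is_act, theta)
        rows.append({"threshold": float(theta), "precision": prec,
                     "sensitivity": sens, "f1": f1})
        if f1 > best[0] + 1e-12:  # strict improvement; ties keep the lower theta
            best = (f1, float(theta))
    return ThresholdSearchResult(
        theta_star=best[1],
        table=pd.DataFrame(rows),
        auc_of_act_fraction=rank_auc(fractions, is_act),
    )


def run_two_stage(scout, specialist, rule: RatioDecisionRule,
                  case_ids=None, single_model: bool = False) -> dict[str, str]:
    """Scout -> Specialist orchestration.

    A case is NT iff the scout's mask is empty; otherwise the specialist's
    mask is classified with empty_policy="as_EC".  With ``single_model=True``
    the scout provider plays both roles.
    """
    case_ids = list(case_ids) if case_ids is not None else scout.case_ids()
    final_rule = RatioDecisionRule(theta=rule.theta, empty_policy="as_EC")
    spec = scout if single_model else specialist
    out = {}
    for cid in case_ids:
        if scout.get(cid).is_empty():
            out[cid] = "NT"
        else:
            out[cid] = classify_case(spec.get(cid), final_rule)
    return out
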