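"""End-to-end orchestration: phantoms -> masks -> both arms -> evaluation.

A single :class:`RunConfig` drives phantom generation (or a cohort loaded
from a manifest), the Scout/Specialist mask providers, the voxel-ratio and
radiomics classification arms, evaluation reports with BCa intervals, and
optionally the perturbation robustness protocol.  Every random stage gets a
seed derived from the master seed and recorded in the run manifest, so two
runs from the same config are file-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom as ph
from .ensemble import SelectionConfig, build_ensemble, optimize_prob_threshold, rank_features
from .imaging_core import CaseRecord, binarize
from .radiomics import FeatureExtractionConfig, extract_all
from .ratio_classifier import (
    NO_TUMOR,
    RatioDecisionRule,
    act_fraction,
    optimize_ratio_threshold,
    run_two_stage,
)
from .robustness import PerturbationSpec, robustness_report
from .segmentation import ToySegmenterConfig, scout_specialist_pair
from .stats import classification_report, permutation_test

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "run_output"
    # cohort (ratios follow the study's 79:104:23 class mix, scaled down)
    n_nt: int = 16
    n_ec: int = 21
    n_act: int = 5
    master_seed: int = 0
    arm: str = "both"          # voxel_ratio | radiomics | both
    theta: str | float = "optimize"
    n_trials: int = 100
    bootstrap_resamples: int = 2000
    permutation_iterations: int = 2000
    with_robustness: bool = False
    robustness_variants: int = 5
    clinical_scale: bool = False  # full-size grids instead of desk scale

    def phantom_params(self) -> ph.PhantomParams:
        if self.clinical_scale:
            return ph.PhantomParams(grid_shape=(318, 304, 21))
        return ph.PhantomParams()

    def experiment_dict(self) -> dict:
        """Config without the output location (which is not part of the
        experiment identity)."""
        d = asdict(self)
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.experiment_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _derived_seeds(master_seed: int) -> dict[str, int]:
    names = ("cohort", "ensemble", "bootstrap", "permutation", "robustness")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] & 0x7FFFFFFF)
            for n, c in zip(names, children)}


def _report_to_dict(report) -> dict:
    return {
        "per_class": report.per_class,
        "ci": {c: {m: list(v) for m, v in d.items()} for c, d in report.ci.items()},
        "confusion": report.confusion.tolist(),
        "classes": list(report.classes),
        "n_per_class": report.n_per_class,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured arms; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derived_seeds(config.master_seed)
    run_manifest = {"config": config.experiment_dict(),
                    "config_hash": config.config_hash(),
                    "derived_seeds": seeds}

    cases = ph.generate_cohort_records(config.n_nt, config.n_ec, config.n_act,
                                       config.phantom_params(),
                                       master_seed=seeds["cohort"])
    by_id = {c.case_id: c for c in cases}
    truth = pd.Series({c.case_id: c.case_class for c in cases})
    volumes = {c.case_id: c.volume for c in cases}
    scout, specialist = scout_specialist_pair(volumes, ToySegmenterConfig())

    results = pd.DataFrame(index=sorted(truth.index))
    results["truth"] = truth
    reports: dict = {}

    tumor_ids = sorted([cid for cid in truth.index if truth[cid] != "NT"])

    if config.arm in ("voxel_ratio", "both"):
        fr = {}
        for cid in tumor_ids:
            f = act_fraction(specialist.get(cid))
            fr[cid] = 0.0 if f is NO_TUMOR else float(f)  # empty -> EC (fraction 0)
        if config.theta == "optimize":
            search = optimize_ratio_threshold(
                [fr[c] for c in tumor_ids], [truth[c] for c in tumor_ids])
            theta = search.theta_star
            run_manifest["ratio_threshold_search"] = {
                "theta_star": theta, "auc": search.auc_of_act_fraction}
        else:
            theta = float(config.theta)
        rule = RatioDecisionRule(theta=theta, empty_policy="as_NT")
        preds = run_two_stage(scout, specialist, rule, case_ids=sorted(truth.index))
        results["act_fraction"] = pd.Series(fr).reindex(results.index)
        results["pred_ratio"] = pd.Series(preds).reindex(results.index)
        reports["voxel_ratio"] = _report_to_dict(classification_report(
            truth.loc[results.index], results["pred_ratio"],
            ci=True, n_resamples=config.bootstrap_resamples,
            seed=seeds["bootstrap"]))

    if config.arm in ("radiomics", "both"):
        fcfg = FeatureExtractionConfig()
        feats_gt = pd.DataFrame.from_dict(
            {cid: extract_all(by_id[cid].volume, by_id[cid].gt_mask, fcfg)
             for cid in tumor_ids}, orient="index")
        labels = truth.loc[tumor_ids]
        scfg = SelectionConfig(n_trials=config.n_trials,
                               master_seed=seeds["ensemble"])
        ens = build_ensemble(feats_gt, labels, scfg)
        search = optimize_prob_threshold(ens.probabilities.loc[tumor_ids], labels)
        thr = search.theta_star
        run_manifest["radiomics_threshold_search"] = {
            "threshold": thr, "auc": search.auc_of_act_fraction}
        pred_gt = {cid: ("ACT" if ens.probabilities[cid] >= thr else "EC")
                   for cid in tumor_ids}
        # clinical variant: same ensemble scored on predicted-mask features
        pred_pm = {}
        prob_pm = {}
        for cid in tumor_ids:
            pmask = specialist.get(cid)
            if pmask.is_empty():
                pred_pm[cid] = "EC"  # empty predictions count as EC
                prob_pm[cid] = np.nan
                continue
            f = pd.Series(extract_all(by_id[cid].volume, binarize(pmask), fcfg))
            p = ens.predict_for_case(cid, f)
            prob_pm[cid] = p
            pred_pm[cid] = "ACT" if p >= thr else "EC"
        results["prob_radiomics_gt"] = ens.probabilities.reindex(results.index)
        results["pred_radiomics_gt"] = pd.Series(pred_gt).reindex(results.index)
        results["prob_radiomics_pred_masks"] = pd.Series(prob_pm).reindex(results.index)
        results["pred_radiomics_pred_masks"] = pd.Series(pred_pm).reindex(results.index)
        for name, col in (("radiomics_gt", "pred_radiomics_gt"),
                          ("radiomics_pred_masks", "pred_radiomics_pred_masks")):
            sub = results.loc[results[col].notna()]
            reports[name] = _report_to_dict(classification_report(
                sub["truth"], sub[col], classes=("EC", "ACT"),
                ci=True, n_resamples=config.bootstrap_resamples,
                seed=seeds["bootstrap"]))
        importance = rank_features(ens, feats_gt, labels)
        importance.to_csv(out / "importance.csv", index=False)
        if config.with_robustness:
            spec = PerturbationSpec(n_variants=config.robustness_variants,
                                    seed=seeds["robustness"])
            rep = robustness_report(ens, [by_id[c] for c in tumor_ids], spec, fcfg)
            (out / "robustness.json").write_text(json.dumps(rep, indent=2,
                                                            sort_keys=True))

    results.to_csv(out / "results.csv", index_label="case_id")
    (out / "eval_report.json").write_text(json.dumps(reports, indent=2,
                                                     sort_keys=True))
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2,
                                                      sort_keys=True))
    return out


def _act_sensitivity(pred, truth) -> float:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    n_act = np.count_nonzero(truth == "ACT")
    if n_act == 0:
        raise ValueError("no ACT cases")
    return np.count_nonzero((truth == "ACT") & (pred == "ACT")) / n_act


def compare_arms(run_dir: str | Path, n_iter: int = 2000,
                 seed: int = 0) -> dict:
    """Side-by-side per-class metrics for every arm in a finished run, plus a
    paired permutation test of the ACT sensitivity difference between the
    voxel-ratio arm and the radiomics arm on predicted masks."""
    run_dir = Path(run_dir)
    results = pd.read_csv(run_dir / "results.csv", index_col="case_id")
    reports = json.loads((run_dir / "eval_report.json").read_text())
    needed = {"pred_ratio", "pred_radiomics_pred_masks"}
    if not needed <= set(results.columns):
        raise ValueError(f"run at {run_dir} lacks arms: {needed - set(results.columns)}")
    tumor = results[results["truth"] != "NT"]
    a = tumor["pred_ratio"].to_numpy()
    b = tumor["pred_radiomics_pred_masks"].to_numpy()
    missing_a = pd.isna(a).sum()
    missing_b = pd.isna(b).sum()
    if missing_a or missing_b:
        raise ValueError("arms predicted different case sets")
    obs = _act_sensitivity(a, tumor["truth"]) - _act_sensitivity(b, tumor["truth"])
    p = permutation_test(_act_sensitivity, a, b, tumor["truth"].to_numpy(),
                         n_iter=n_iter, seed=seed)
    return {
        "per_arm_reports": reports,
        "act_sensitivity_ratio_arm": _act_sensitivity(a, tumor["truth"]),
        "act_sensitivity_radiomics_pred_masks": _act_sensitivity(b, tumor["truth"]),
        "act_sensitivity_difference": float(obs),
        "permutation_p": float(p),
    }
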