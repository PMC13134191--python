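"""Radiomics classification arm: selection cascade, trial ensemble, ranking.

The EC-vs-ACT classifier is an ensemble of gradient-boosted decision trees:
100 independent stratified 80/20 train/test trials, each fitting the
feature-selection cascade (variance threshold, then |0.40| Pearson
redundancy removal) on its training portion only, training an XGBoost
model, and predicting only its held-out cases.  The per-case ensemble ACT
probability is the mean of that case's held-out trial probabilities, so
every prediction is leakage-free by construction.

Feature importance combines two independent rankings — mean XGBoost gain
across trials and Mann-Whitney effect size r — as
``combined = 0.5 * gain_rank + 0.5 * effect_rank`` over the features that
reach two-sided significance (p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from xgboost import XGBClassifier

from .ratio_classifier import ThresholdSearchResult, optimize_ratio_threshold
from .stats import mann_whitney_r

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Cascade + trial settings; base-learner defaults are the library's with
    max_depth 3 and 200 boosting rounds."""

    variance_threshold: float = 0.0
    corr_threshold: float = 0.40
    n_trials: int = 100
    test_fraction: float = 0.20
    stratified: bool = True
    max_depth: int = 3
    n_estimators: int = 200
    learning_rate: float = 0.3
    master_seed: int = 0
    cascade_scope: str = "per_trial"  # or "global" (sensitivity analysis only)

    def __post_init__(self):
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must be in (0, 1]")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class TrialResult:
    trial_seed: int
    model: XGBClassifier
    heldout_ids: list
    selected_features: list[str]
    gain: dict  # feature -> gain in this trial's model
    heldout_proba: dict  # case_id -> ACT probability


@dataclass
class HeldoutEnsemble:
    """100-trial ensemble; every case is covered by >= 1 held-out prediction."""

    trials: list[TrialResult]
    probabilities: pd.Series  # case_id -> mean held-out ACT probability
    labels: pd.Series
    cfg: SelectionConfig
    audit: list[str] = field(default_factory=list)

    def unique_features(self) -> list[str]:
        """Union of features actually used (nonzero gain) across trials."""
        used = set()
        for t in self.trials:
            used |= {f for f, g in t.gain.items() if g > 0}
        return sorted(used)

    def predict_for_case(self, case_id: str, features: pd.Series) -> float:
        """Score one feature record with the trials that held this case out.

        This is how perturbed variants of a test case are scored: the trial
        assignment of the original case is reused, so the variant is never
        seen by a model that trained on the case."""
        probs = []
        for t in self.trials:
            if case_id in t.heldout_ids:
                x = features[t.selected_features].to_numpy(dtype=float)[None, :]
                probs.append(float(t.model.predict_proba(x)[0, 1]))
        if not probs:
            raise KeyError(f"case {case_id!r} is not covered by any trial")
        return float(np.mean(probs))


def _label_vector(labels: pd.Series) -> np.ndarray:
    bad = set(labels.unique()) - {"EC", "ACT"}
    if bad:
        raise ValueError(f"labels must be EC or ACT, got {sorted(bad)}")
    return (labels == "ACT").astype(int).to_numpy()


def select_features(table: pd.DataFrame, labels: pd.Series,
                    cfg: SelectionConfig | None = None):
    """Variance threshold then pairwise |Pearson| > corr_threshold removal.

    Redundancy removal keeps, within each correlated pair, the feature with
    the larger univariate Mann-Whitney effect size against the labels
    (ties break on the feature name); implemented as a greedy sweep in
    decreasing effect-size order, which resolves every offending pair
    deterministically.  Returns (reduced table, audit log).
    """
    cfg = cfg or SelectionConfig()
    if table.shape[1] < 2:
        raise ValueError("need at least 2 features")
    audit: list[str] = []
    variances = table.var(axis=0, ddof=0)
    keep_var = variances > cfg.variance_threshold
    for f in table.columns[~keep_var]:
        audit.append(f"drop {f}: variance {variances[f]:.3g} <= "
                     f"{cfg.variance_threshold}")
    table = table.loc[:, keep_var]
    if table.shape[1] == 0:
        raise ValueError("all features dropped by the variance threshold")
    y = _label_vector(labels.loc[table.index])
    eff = {
        f: mann_whitney_r(table.loc[y == 1, f], table.loc[y == 0, f])
        for f in table.columns
    }
    order = sorted(table.columns, key=lambda f: (-eff[f], f))
    corr = np.corrcoef(table.to_numpy(dtype=float).T)
    corr = np.nan_to_num(corr, nan=0.0)
    col_idx = {f: i for i, f in enumerate(table.columns)}
    kept: list[str] = []
    for f in order:
        i = col_idx[f]
        clash = next(
            (k for k in kept if abs(corr[i, col_idx[k]]) > cfg.corr_threshold), None
        )
        if clash is None:
            kept.append(f)
        else:
            audit.append(
                f"drop {f}: |rho|={abs(corr[i, col_idx[clash]]):.3f} > "
                f"{cfg.corr_threshold} with {clash} (kept: larger effect size)"
            )
    if not kept:
        raise ValueError("all features dropped by the correlation filter")
    kept_in_order = [f for f in table.columns if f in set(kept)]
    return table.loc[:, kept_in_order], audit


def _stratified_split(index: pd.Index, y: np.ndarray, test_fraction: float,
                      rng: np.random.Generator):
    """Per-class exact-proportion split (>= 1 test case per class)."""
    test_idx = []
    for cls in np.unique(y):
        members = np.asarray(index)[y == cls]
        n_test = max(1, int(round(len(members) * test_fraction)))
        if n_test >= len(members):
            raise ValueError(f"class {cls} too small for a stratified split")
        test_idx.extend(rng.permutation(members)[:n_test])
    test = pd.Index(test_idx)
    train = index.difference(test)
    return train, test


def run_trial(table: pd.DataFrame, labels: pd.Series, trial_seed: int,
              cfg: SelectionConfig | None = None,
              forced_test: list | None = None) -> TrialResult:
    """One stratified train/test trial; deterministic given (table, seed).

    The selection cascade is fitted on the training portion only; the model
    emits ACT probabilities for held-out cases only."""
    cfg = cfg or SelectionConfig()
    y_all = _label_vector(labels)
    for attempt in range(20):
        rng = np.random.default_rng(trial_seed + attempt)
        train, test = _stratified_split(table.index, y_all, cfg.test_fraction, rng)
        if forced_test:
            test = test.union(pd.Index(forced_test))
            train = table.index.difference(test)
        y_train = _label_vector(labels.loc[train])
        if len(np.unique(y_train)) == 2:
            break
        logger.warning("trial seed %d: a class missing from the training split; "
                       "resampled", trial_seed + attempt)
    else:
        raise ValueError("could not build a two-class training split")
    if cfg.cascade_scope == "per_trial":
        reduced, _ = select_features(table.loc[train], labels.loc[train], cfg)
    else:
        reduced, _ = select_features(table, labels, cfg)
    feats = list(reduced.columns)
    model = XGBClassifier(
        max_depth=cfg.max_depth,
        n_estimators=cfg.n_estimators,
        learning_rate=cfg.learning_rate,
        random_state=trial_seed,
        n_jobs=1,
        verbosity=0,
        eval_metric="logloss",
        # exact greedy splits at midpoints between observed values; the
        # histogram method would place cuts on the values themselves, which
        # mis-sides held-out points falling inside a class gap
        tree_method="exact",
    )
    model.fit(table.loc[train, feats].to_numpy(dtype=float),
              _label_vector(labels.loc[train]))
    booster = model.get_booster()
    raw_gain = booster.get_score(importance_type="gain")
    # xgboost names columns f0, f1, ... for array input
    gain = {feats[int(k[1:])]: float(v) for k, v in raw_gain.items()}
    proba = model.predict_proba(table.loc[test, feats].to_numpy(dtype=float))[:, 1]
    return TrialResult(
        trial_seed=trial_seed,
        model=model,
        heldout_ids=list(test),
        selected_features=feats,
        gain=gain,
        heldout_proba={cid: float(p) for cid, p in zip(test, proba)},
    )


def build_ensemble(table: pd.DataFrame, labels: pd.Series,
                   cfg: SelectionConfig | None = None) -> HeldoutEnsemble:
    """n_trials stratified trials plus targeted extra splits until every case
    has at least one held-out prediction."""
    cfg = cfg or SelectionConfig()
    labels = labels.loc[table.index]
    audit: list[str] = []
    trials = []
    ss = np.random.SeedSequence(cfg.master_seed)
    seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(cfg.n_trials)]
    for seed in seeds:
        trials.append(run_trial(table, labels, seed, cfg))
    covered = set()
    for t in trials:
        covered |= set(t.heldout_ids)
    missing = [cid for cid in table.index if cid not in covered]
    extra_seed = int(ss.spawn(1)[0].generate_state(1)[0] & 0x7FFFFFFF)
    for k, cid in enumerate(missing):
        audit.append(f"case {cid} uncovered after {cfg.n_trials} trials: "
                     "targeted extra split")
        logger.info("targeted extra split for uncovered case %s", cid)
        trials.append(run_trial(table, labels, extra_seed + k, cfg,
                                forced_test=[cid]))
    per_case: dict = {cid: [] for cid in table.index}
    for t in trials:
        for cid, p in t.heldout_proba.items():
            per_case[cid].append(p)
    probs = pd.Series({cid: float(np.mean(v)) for cid, v in per_case.items()})
    return HeldoutEnsemble(trials=trials, probabilities=probs,
                           labels=labels, cfg=cfg, audit=audit)


def optimize_prob_threshold(probabilities, labels) -> ThresholdSearchResult:
    """ACT-F1-maximizing probability threshold (same contract as the voxel
    ratio search: exhaustive candidates, ties toward the lower threshold)."""
    return optimize_ratio_threshold(probabilities, labels)


def rank_features(ensemble: HeldoutEnsemble, table: pd.DataFrame,
                  labels: pd.Series) -> pd.DataFrame:
    """Dual-rank importance table over the ensemble's used features.

    gain = mean XGBoost gain across the trials that used the feature;
    effect size r = |Z|/sqrt(N) (Mann-Whitney, tie-corrected).  Features with
    p >= 0.05 are removed; combined rank = 0.5*gain_rank + 0.5*effect_rank,
    ties broken by gain rank.  Lower combined rank = better.
    """
    labels = labels.loc[table.index]
    y = _label_vector(labels)
    feats = ensemble.unique_features()
    rows = []
    for f in feats:
        gains = [t.gain[f] for t in ensemble.trials if t.gain.get(f, 0.0) > 0]
        x_act = table.loc[y == 1, f].to_numpy(dtype=float)
        x_ec = table.loc[y == 0, f].to_numpy(dtype=float)
        try:
            _, p = mannwhitneyu(x_act, x_ec, alternative="two-sided")
        except ValueError:
            p = 1.0
        rows.append({
            "feature": f,
            "mean_gain": float(np.mean(gains)) if gains else 0.0,
            "effect_size_r": mann_whitney_r(x_act, x_ec),
            "p_value": float(p),
            "direction": "higher_in_ACT" if np.median(x_act) > np.median(x_ec)
                         else "higher_in_EC",
        })
    df = pd.DataFrame(rows)
    if df.empty:
        logger.warning("no features used by any trial")
        return df
    df = df[df["p_value"] < 0.05].copy()
    if df.empty:
        logger.warning("no feature reaches significance; empty importance table")
        return df
    df["gain_rank"] = df["mean_gain"].rank(ascending=False, method="min")
    df["effect_rank"] = df["effect_size_r"].rank(ascending=False, method="min")
    df["combined_rank"] = 0.5 * df["gain_rank"] + 0.5 * df["effect_rank"]
    df = df.sort_values(["combined_rank", "gain_rank", "feature"]).reset_index(drop=True)
    return df
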