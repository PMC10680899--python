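"""Evaluation designs: cross-validated AUC, transfer learning, cross-sex
grids, backward-masking sweeps, and the Monte Carlo type-I-error study.

All randomness (fold splits, model initialization, simulation replicates)
is controlled by explicit seeds so every reported AUC is recomputable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cohort import InclusionCriteria, build_cohort
from .labeling import Label, LabelSpec, MatchSpec, label_cohort, propensity_match
from .masking import MaskSpec, mask_cohort
from .retain import CodeDictionary, ModelConfig, RetainClassifier, build_dictionary
from .survival import (
    BaselineFeatureSpec,
    DiscreteTimeGrid,
    DiscreteTimeSurvivalNet,
    featurize_baseline,
)
from .synthetic import SimScenario, null_scenario, simulate_cohort
from .records import years_between


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney probability that a random positive outscores a
    random negative, with ties counted half.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, scores))


def paired_t_test_one_sided(auc_a: Sequence[float], auc_b: Sequence[float]) -> float:
    """One-sided paired t-test p-value for mean(a - b) < 0.

    Small p means *b* is systematically larger.  Degenerate difference
    vectors (zero variance) return 0.5 when identically zero, else 0 or 1
    by the sign of the mean, with a warning.
    """
    a, b = np.asarray(auc_a, float), np.asarray(auc_b, float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.5
        warnings.warn("zero variance of paired differences", stacklevel=2)
        return 0.0 if d.mean() < 0 else 1.0
    return float(stats.ttest_rel(a, b, alternative="less").pvalue)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_aucs: list[float]
    fold_assignments: np.ndarray
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1))


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per sample)."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assign = np.empty(len(labels), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assign[test_idx] = f
    return assign


def cross_validate(
    model_factory: Callable[[int], object],
    records: Sequence,
    labels: Sequence[int],
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV of a fit/predict_proba model.

    ``model_factory(fold)`` must return a fresh unfitted model; each fold
    is scored exactly once.  Deterministic given *seed*.
    """
    y = np.asarray(labels, dtype=int)
    if min(np.bincount(y, minlength=2)) < k:
        raise ValueError(f"need at least {k} samples of each class for {k}-fold CV")
    assign = stratified_folds(y, k, seed)
    fold_aucs = []
    for f in range(k):
        train = np.nonzero(assign != f)[0]
        test = np.nonzero(assign == f)[0]
        model = model_factory(f)
        model.fit([records[i] for i in train], y[train])
        scores = model.predict_proba([records[i] for i in test])
        fold_aucs.append(auc(y[test], scores))
    return CVResult(fold_aucs, assign, seed)


def retain_factory(
    dictionary: CodeDictionary, config: ModelConfig
) -> Callable[[int], RetainClassifier]:
    def factory(fold: int) -> RetainClassifier:
        return RetainClassifier(dictionary, replace(config, seed=config.seed + fold))

    return factory


# ---------------------------------------------------------------------------
# Dataset assembly shared by the experiment designs
# ---------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    """Masked, propensity-matched model inputs plus survival-time targets."""

    records: list            # MaskedRecord per patient
    labels: np.ndarray       # 1 positive / 0 negative
    sexes: np.ndarray        # "male"/"female" per patient
    times: np.ndarray        # years from index to event or censoring
    events: np.ndarray       # event observed flag
    baseline_X: np.ndarray   # baseline covariates at index
    smd_report: pd.DataFrame


def assemble_dataset(
    records: Sequence,
    entries: Sequence,
    mask_years: float,
    feature_spec: BaselineFeatureSpec,
    match: bool = True,
    seed: int = 0,
) -> LabeledDataset:
    """Mask a labeled cohort and propensity-match it into model inputs.

    Matching is re-run for every masking length (covariates are computed on
    the masked records, whose encounter pattern the mask changes).
    """
    by_id = {r.patient_id: r for r in records}
    masked = mask_cohort(by_id, entries, MaskSpec(mask_years=mask_years))
    entry_by_id = {e.patient_id: e for e in entries}
    pos = [masked[pid] for pid in masked
           if entry_by_id[pid].label == Label.POSITIVE]
    neg = [masked[pid] for pid in masked
           if entry_by_id[pid].label == Label.NEGATIVE]
    if match:
        mpos, mneg, report = propensity_match(pos, neg, MatchSpec(ratio=1), seed=seed)
    else:
        mpos, mneg = pos, neg
        report = pd.DataFrame()
    recs = list(mpos) + list(mneg)
    labels = np.r_[np.ones(len(mpos)), np.zeros(len(mneg))].astype(int)
    sexes, times, events, X = [], [], [], []
    for mr in recs:
        entry = entry_by_id[mr.patient_id]
        full = by_id[mr.patient_id]
        sexes.append(full.sex)
        end = entry.event_date if entry.event_date is not None else entry.censor_date
        times.append(years_between(entry.index_date, end))
        events.append(entry.event_date is not None)
        X.append(featurize_baseline(full, entry.index_date, feature_spec))
    return LabeledDataset(
        records=recs,
        labels=labels,
        sexes=np.array(sexes),
        times=np.array(times),
        events=np.array(events, dtype=bool),
        baseline_X=np.array(X),
        smd_report=report,
    )


def prepare_dataset(
    scenario: SimScenario,
    mask_years: float = 0.5,
    label_spec: Optional[LabelSpec] = None,
    criteria: Optional[InclusionCriteria] = None,
    feature_spec: Optional[BaselineFeatureSpec] = None,
    match: bool = True,
    seed: int = 0,
) -> LabeledDataset:
    """Simulate -> index -> label -> mask -> propensity-match, end to end."""
    label_spec = label_spec or LabelSpec(outcome_codes=[scenario.outcome_code])
    criteria = criteria or InclusionCriteria(index_lab_code=scenario.index_lab_code)
    feature_spec = feature_spec or BaselineFeatureSpec(
        code_indicators=sorted(scenario.effects),
        index_lab_code=scenario.index_lab_code,
    )
    records, _ = simulate_cohort(scenario)
    index_dates, _ = build_cohort(records, criteria)
    entries = label_cohort(records, index_dates, label_spec)
    return assemble_dataset(records, entries, mask_years, feature_spec,
                            match=match, seed=seed)


# ---------------------------------------------------------------------------
# Sequence model vs. baseline survival model
# ---------------------------------------------------------------------------

def compare_sequence_vs_baseline(
    ds: LabeledDataset,
    config: ModelConfig,
    grid: Optional[DiscreteTimeGrid] = None,
    k: int = 5,
    seed: int = 0,
) -> dict[str, CVResult]:
    """CV both models on identical folds of the same matched cohort.

    The sequence model sees masked longitudinal records; the survival
    model sees only index-date covariates and is scored by its 10-year
    risk transform, so the two AUCs isolate the value of time-varying
    covariates.
    """
    grid = grid or DiscreteTimeGrid(10, n_bins=max(10, int(np.ceil(ds.times.max()))))
    y = ds.labels
    assign = stratified_folds(y, k, seed)
    dictionary = build_dictionary(ds.records)
    dictionary.freeze()
    seq_aucs, base_aucs = [], []
    for f in range(k):
        train = np.nonzero(assign != f)[0]
        test = np.nonzero(assign == f)[0]
        model = RetainClassifier(dictionary, replace(config, seed=config.seed + f))
        model.fit([ds.records[i] for i in train], y[train])
        seq_aucs.append(auc(y[test], model.predict_proba([ds.records[i] for i in test])))
        net = DiscreteTimeSurvivalNet(
            ds.baseline_X.shape[1], grid, seed=config.seed + f
        )
        net.fit(ds.baseline_X[train], ds.times[train], ds.events[train])
        base_aucs.append(auc(y[test], net.risk_at_horizon(ds.baseline_X[test])))
    return {
        "sequence": CVResult(seq_aucs, assign, seed),
        "baseline": CVResult(base_aucs, assign, seed),
    }


# ---------------------------------------------------------------------------
# Transfer learning
# ---------------------------------------------------------------------------

@dataclass
class TLComparison:
    scratch_aucs: list[float]
    finetuned_aucs: list[float]

    @property
    def mean_difference(self) -> float:
        return float(np.mean(self.finetuned_aucs) - np.mean(self.scratch_aucs))

    @property
    def p_value(self) -> float:
        """One-sided p for the finetuned AUCs being larger."""
        return paired_t_test_one_sided(self.scratch_aucs, self.finetuned_aucs)


def pretrain_finetune(
    source_records: Sequence,
    source_labels: Sequence[int],
    target_records: Sequence,
    target_labels: Sequence[int],
    config: ModelConfig,
) -> RetainClassifier:
    """Pretrain on the large source task, finetune all layers on the target.

    The code dictionary is built on the union of both cohorts and frozen
    before pretraining, so pretrained embeddings stay aligned during
    finetuning.
    """
    dictionary = build_dictionary(list(source_records) + list(target_records))
    dictionary.freeze()
    pretrained = RetainClassifier(dictionary, config)
    pretrained.fit(source_records, source_labels)
    finetuned = pretrained.clone_with_weights()
    finetuned.fit(target_records, target_labels)
    return finetuned


def transfer_cv(
    source_records: Sequence,
    source_labels: Sequence[int],
    target_records: Sequence,
    target_labels: Sequence[int],
    config: ModelConfig,
    k: int = 5,
    seed: int = 0,
) -> TLComparison:
    """Paired from-scratch vs. pretrain->finetune CV on the target cohort.

    Pairing uses identical fold splits and per-fold seeds; the source model
    is pretrained once and re-finetuned per fold.
    """
    y_t = np.asarray(target_labels, dtype=int)
    dictionary = build_dictionary(list(source_records) + list(target_records))
    dictionary.freeze()
    pretrained = RetainClassifier(dictionary, config)
    pretrained.fit(source_records, np.asarray(source_labels, dtype=int))
    assign = stratified_folds(y_t, k, seed)
    scratch_aucs, ft_aucs = [], []
    for f in range(k):
        train = np.nonzero(assign != f)[0]
        test = np.nonzero(assign == f)[0]
        tr_recs = [target_records[i] for i in train]
        te_recs = [target_records[i] for i in test]
        scratch = RetainClassifier(dictionary, replace(config, seed=config.seed + f))
        scratch.fit(tr_recs, y_t[train])
        scratch_aucs.append(auc(y_t[test], scratch.predict_proba(te_recs)))
        ft = pretrained.clone_with_weights()
        ft.config = replace(config, seed=config.seed + f)
        ft.fit(tr_recs, y_t[train])
        ft_aucs.append(auc(y_t[test], ft.predict_proba(te_recs)))
    return TLComparison(scratch_aucs, ft_aucs)


# ---------------------------------------------------------------------------
# Cross-sex evaluation
# ---------------------------------------------------------------------------

def cross_sex_eval(
    ds: LabeledDataset,
    config: ModelConfig,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC matrix over train group {all, male, female} x test group.

    One stratified fold split over the full cohort is shared by every cell:
    each cell trains on the train-group members of the training folds and
    pools held-out predictions over the test-group members, so cells differ
    only in group composition, not in split noise.  Unavailable cells
    (a group missing a class) are NaN.
    """
    y = ds.labels
    assign = stratified_folds(y, k, seed)
    dictionary = build_dictionary(ds.records)
    dictionary.freeze()
    groups = {
        "all": np.ones(len(y), dtype=bool),
        "male": ds.sexes == "male",
        "female": ds.sexes == "female",
    }
    rows = []
    for train_name, train_mask in groups.items():
        # pooled held-out scores for every patient, from the model whose
        # training folds excluded them
        scores = np.full(len(y), np.nan)
        for f in range(k):
            tr = np.nonzero(train_mask & (assign != f))[0]
            te = np.nonzero(assign == f)[0]
            if len(np.unique(y[tr])) < 2:
                continue
            model = RetainClassifier(dictionary, replace(config, seed=config.seed + f))
            model.fit([ds.records[i] for i in tr], y[tr])
            scores[te] = model.predict_proba([ds.records[i] for i in te])
        for test_name, test_mask in groups.items():
            sel = test_mask & ~np.isnan(scores)
            try:
                cell = auc(y[sel], scores[sel])
            except ValueError:
                cell = np.nan
            rows.append({"train": train_name, "test": test_name, "auc": cell})
    return pd.DataFrame(rows).pivot(index="train", columns="test", values="auc")


# ---------------------------------------------------------------------------
# Type-I-error Monte Carlo study
# ---------------------------------------------------------------------------

def logistic_score_test(exposure: np.ndarray, y: np.ndarray) -> float:
    """Rao score test p-value for adding a binary exposure to an
    intercept-only logistic model of the label."""
    x = np.asarray(exposure, float)
    y = np.asarray(y, float)
    ybar = y.mean()
    if ybar in (0.0, 1.0) or np.all(x == x[0]):
        return 1.0  # unidentified; never rejects
    u = float(np.sum(x * (y - ybar)))
    var = ybar * (1 - ybar) * float(np.sum((x - x.mean()) ** 2))
    return float(stats.chi2.sf(u * u / var, df=1))


def type1_error_study(
    scenario_factory: Optional[Callable[[int], SimScenario]] = None,
    n_replicates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    code: str = "DX_NULL",
) -> dict:
    """Empirical rejection rate of the horizon-labeling formulation.

    Per replicate: simulate, detect index dates, label, then score-test the
    association between baseline exposure to the designated code (recorded
    at or before index) and the horizon label.  Under a true null effect
    the rate should match *alpha*.
    """
    if scenario_factory is None:
        scenario_factory = null_scenario_factory
    if n_replicates < 100:
        warnings.warn("fewer than 100 replicates gives a noisy rate", stacklevel=2)
    rejections, evaluable = 0, 0
    label_spec = None
    for r in range(n_replicates):
        scenario = scenario_factory(seed + 1000 * r)
        if label_spec is None:
            label_spec = LabelSpec(outcome_codes=[scenario.outcome_code])
            criteria = InclusionCriteria(index_lab_code=scenario.index_lab_code)
        records, _ = simulate_cohort(scenario)
        index_dates, _ = build_cohort(records, criteria)
        entries = label_cohort(records, index_dates, label_spec)
        by_id = {rec.patient_id: rec for rec in records}
        ys, xs = [], []
        for e in entries:
            if e.label == Label.EXCLUDED:
                continue
            ys.append(1 if e.label == Label.POSITIVE else 0)
            rec = by_id[e.patient_id]
            xs.append(
                1.0 if rec.has_code([code], code_type="DX", before=e.index_date) else 0.0
            )
        ys, xs = np.array(ys), np.array(xs)
        if len(ys) == 0 or len(np.unique(ys)) < 2 or len(np.unique(xs)) < 2:
            continue
        evaluable += 1
        if logistic_score_test(xs, ys) < alpha:
            rejections += 1
    rate = rejections / evaluable if evaluable else np.nan
    return {
        "rejection_rate": rate,
        "n_replicates": n_replicates,
        "n_evaluable": evaluable,
        "alpha": alpha,
    }


def null_scenario_factory(seed: int) -> SimScenario:
    return null_scenario(seed=seed)


# ---------------------------------------------------------------------------
# Backward-masking sweep
# ---------------------------------------------------------------------------

def masking_sweep(
    scenario: SimScenario,
    mask_grid: Sequence[float],
    config: ModelConfig,
    k: int = 5,
    seeds: Sequence[int] = (0,),
) -> pd.DataFrame:
    """Mean CV AUC of the sequence model per masking length.

    Propensity matching is re-run within each masking group.  Returns one
    row per (mask_years, seed).
    """
    rows = []
    for s in seeds:
        sc = replace(scenario, seed=scenario.seed + s)
        for L in mask_grid:
            ds = prepare_dataset(sc, mask_years=L, seed=s)
            dictionary = build_dictionary(ds.records)
            dictionary.freeze()
            cfg = replace(config, seed=config.seed + s)
            cv = cross_validate(
                retain_factory(dictionary, cfg), ds.records, ds.labels, k=k, seed=s
            )
            rows.append(
                {"mask_years": L, "seed": s, "mean_auc": cv.mean, "sd_auc": cv.sd}
            )
    return pd.DataFrame(rows)
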