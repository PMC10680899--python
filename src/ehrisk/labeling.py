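"""Censoring-aware horizon labeling and propensity-score class balancing.

Time-to-event outcomes are converted into a binary "event within H years of
index" label.  Patients whose censoring makes that label undefined are
excluded rather than mislabeled, and very early events (within a minimum
gap of the index) are excluded because they suggest prevalent rather than
incident disease.  The four informative archetypes:

* event after the horizon                     -> negative
* no event, censored after the horizon        -> negative
* event inside [min_gap, horizon]             -> positive
* no event, censored at or before the horizon -> excluded (undefined label)

plus two exclusions: event before index, and event within the minimum gap.
Boundary conventions (config-overridable): an event at exactly the horizon
is positive ("within H years" inclusive); an event at exactly the minimum
gap counts as having cleared the gap (positive); a censor at exactly the
horizon is insufficient (negative labels need strictly more than H years of
event-free observation).

Class balance is restored by 1:1 propensity matching on encounter-pattern
covariates (mean and SD of inter-encounter intervals, encounter count), so
positives and negatives are comparable in how densely they were observed.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .records import PatientRecord, years_between


@dataclass
class LabelSpec:
    horizon_years: float = 10.0
    min_gap_years: float = 2.0
    outcome_codes: list[str] = field(default_factory=lambda: ["DX_EVENT"])

    def __post_init__(self) -> None:
        if not 0 <= self.min_gap_years < self.horizon_years:
            raise ValueError("need 0 <= min_gap_years < horizon_years")


class Label(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    EXCLUDED = "excluded"


class LabelExclusion(str, Enum):
    EVENT_BEFORE_INDEX = "event_before_index"
    EVENT_WITHIN_MIN_GAP = "event_within_min_gap"
    INSUFFICIENT_FOLLOWUP = "insufficient_followup"


@dataclass
class CohortEntry:
    patient_id: str
    index_date: dt.date
    event_date: Optional[dt.date]
    censor_date: dt.date
    label: Label
    exclusion_reason: Optional[LabelExclusion] = None

    @property
    def endpoint_date(self) -> dt.date:
        """Diagnosis date for event patients, censoring date otherwise."""
        return self.event_date if self.event_date is not None else self.censor_date


def assign_label(
    index_date: dt.date,
    event_date: Optional[dt.date],
    censor_date: dt.date,
    spec: LabelSpec,
) -> tuple[Label, Optional[LabelExclusion]]:
    """Label one (index, event, censor) triple; exhaustive over all cases."""
    if censor_date < index_date:
        raise ValueError("censor_date precedes index_date")
    if event_date is not None:
        if event_date > censor_date:
            raise ValueError("event_date after censor_date")
        t = years_between(index_date, event_date)
        if t < 0:
            return Label.EXCLUDED, LabelExclusion.EVENT_BEFORE_INDEX
        if t < spec.min_gap_years:
            return Label.EXCLUDED, LabelExclusion.EVENT_WITHIN_MIN_GAP
        if t <= spec.horizon_years:
            return Label.POSITIVE, None
        return Label.NEGATIVE, None
    if years_between(index_date, censor_date) > spec.horizon_years:
        return Label.NEGATIVE, None
    return Label.EXCLUDED, LabelExclusion.INSUFFICIENT_FOLLOWUP


def label_cohort(
    records: Sequence[PatientRecord],
    index_dates: dict[str, dt.date],
    spec: LabelSpec,
) -> list[CohortEntry]:
    """Label every indexed patient; the first outcome-code date is the event."""
    entries = []
    for rec in records:
        idx = index_dates.get(rec.patient_id)
        if idx is None:
            continue
        event = rec.first_code_date(spec.outcome_codes, code_type="DX")
        censor = rec.last_date
        label, reason = assign_label(idx, event, censor, spec)
        entries.append(CohortEntry(rec.patient_id, idx, event, censor, label, reason))
    return entries


def label_table(entries: Sequence[CohortEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in entries],
            "label": [e.label.value for e in entries],
            "reason": [e.exclusion_reason.value if e.exclusion_reason else "" for e in entries],
            "index_date": [e.index_date.isoformat() for e in entries],
            "endpoint_date": [e.endpoint_date.isoformat() for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# Propensity matching
# ---------------------------------------------------------------------------

@dataclass
class MatchSpec:
    """1:ratio greedy nearest-neighbour propensity matching settings."""

    ratio: int = 1
    caliper: Optional[float] = None  # on the logit scale; None = no caliper

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")


def compute_match_covariates(record: PatientRecord) -> np.ndarray:
    """(mean inter-encounter gap [days], sample SD of gaps, encounter count).

    Single-encounter patients get (0, 0, 1); the SD uses the n-1 denominator
    and is 0 when there are fewer than two gaps.
    """
    if not record.encounters:
        raise ValueError("record has no encounters")
    days = np.array([(e.date - record.encounters[0].date).days for e in record.encounters])
    gaps = np.diff(days)
    if len(gaps) == 0:
        return np.array([0.0, 0.0, 1.0])
    sd = float(np.std(gaps, ddof=1)) if len(gaps) > 1 else 0.0
    return np.array([float(np.mean(gaps)), sd, float(len(days))])


def standardized_mean_difference(x_pos: np.ndarray, x_neg: np.ndarray) -> np.ndarray:
    """Per-covariate SMD with the pooled-variance denominator (NaN for
    groups too small to estimate a variance)."""
    if len(x_pos) < 2 or len(x_neg) < 2:
        return np.full(x_pos.shape[1], np.nan)
    pooled = np.sqrt((np.var(x_pos, axis=0, ddof=1) + np.var(x_neg, axis=0, ddof=1)) / 2)
    pooled = np.where(pooled == 0, 1.0, pooled)
    return (x_pos.mean(axis=0) - x_neg.mean(axis=0)) / pooled


def propensity_match(
    positives: Sequence[PatientRecord],
    negatives: Sequence[PatientRecord],
    spec: MatchSpec = MatchSpec(),
    seed: int = 0,
) -> tuple[list[PatientRecord], list[PatientRecord], pd.DataFrame]:
    """Greedy nearest-neighbour matching on the propensity logit.

    A logistic model of positive-vs-negative is fitted on standardized
    matching covariates; positives are processed in descending propensity
    and each takes its ``ratio`` closest unused negatives on the logit
    scale.  Returns (matched positives, matched controls, SMD report with
    columns covariate / smd_before / smd_after).  Ties in propensity are
    broken by patient_id for determinism.
    """
    if not positives:
        raise ValueError("no positives to match")
    if not negatives:
        raise ValueError("no negatives to match against")
    x_pos = np.array([compute_match_covariates(r) for r in positives])
    x_neg = np.array([compute_match_covariates(r) for r in negatives])
    x = np.vstack([x_pos, x_neg])
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    xs = (x - mu) / sd
    y = np.r_[np.ones(len(positives)), np.zeros(len(negatives))]
    model = LogisticRegression(C=np.inf, max_iter=1000, random_state=seed)
    model.fit(xs, y)
    logits = xs @ model.coef_.ravel() + model.intercept_[0]
    logit_pos, logit_neg = logits[: len(positives)], logits[len(positives):]

    order = sorted(
        range(len(positives)),
        key=lambda i: (-logit_pos[i], positives[i].patient_id),
    )
    available = sorted(
        range(len(negatives)), key=lambda j: (logit_neg[j], negatives[j].patient_id)
    )
    matched_pos: list[PatientRecord] = []
    matched_neg: list[PatientRecord] = []
    kept_pos_idx, kept_neg_idx = [], []
    for i in order:
        take = []
        for _ in range(spec.ratio):
            if not available:
                break
            j = min(
                available,
                key=lambda j: (abs(logit_neg[j] - logit_pos[i]), negatives[j].patient_id),
            )
            if spec.caliper is not None and abs(logit_neg[j] - logit_pos[i]) > spec.caliper:
                break
            available.remove(j)
            take.append(j)
        if len(take) < spec.ratio:
            warnings.warn(
                f"positive {positives[i].patient_id}: matched {len(take)} of "
                f"{spec.ratio} controls",
                stacklevel=2,
            )
        if take:
            matched_pos.append(positives[i])
            kept_pos_idx.append(i)
            for j in take:
                matched_neg.append(negatives[j])
                kept_neg_idx.append(j)

    names = ["mean_gap_days", "sd_gap_days", "n_encounters"]
    smd_before = standardized_mean_difference(x_pos, x_neg)
    smd_after = standardized_mean_difference(
        x_pos[kept_pos_idx], x_neg[kept_neg_idx]
    ) if kept_pos_idx else np.full(3, np.nan)
    report = pd.DataFrame(
        {"covariate": names, "smd_before": smd_before, "smd_after": smd_after}
    )
    return matched_pos, matched_neg, report
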