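"""Precondition-cohort identification from raw records.

The cohort is anchored on a sex-thresholded lab test: a patient enters when
they have at least two abnormal values of the index lab whose first-to-last
span exceeds six months, and the *first* abnormal value dates the index.
Exclusions (age, follow-up, confounder code sets) are applied in a fixed
order so the attrition audit trail is deterministic.  A separate routine
assembles a large case-control pretraining set by sampling matched controls
per case.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .records import HALF_YEAR_DAYS, PatientRecord, years_between

logger = logging.getLogger(__name__)


@dataclass
class InclusionCriteria:
    """Cohort entry and exclusion rules.

    Defaults follow the ALT-based definition: abnormal above 40 IU/mL for
    men and 31 IU/mL for women, two abnormal values more than 183 days
    apart, adults only, at least five years of post-index data.
    ``exclusion_code_sets`` maps a set name to (codes, when) where *when* is
    ``"any_time"`` or ``"before_index"``.
    """

    index_lab_code: str = "LAB_ALT"
    abnormal_threshold_male: float = 40.0
    abnormal_threshold_female: float = 31.0
    min_separation_days: int = HALF_YEAR_DAYS
    min_age_years: int = 18
    min_followup_years: float = 5.0
    exclusion_code_sets: dict[str, tuple[list[str], str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.abnormal_threshold_male <= 0 or self.abnormal_threshold_female <= 0:
            raise ValueError("abnormal thresholds must be > 0")
        if self.min_separation_days < 0:
            raise ValueError("min_separation_days must be >= 0")
        for name, (codes, when) in self.exclusion_code_sets.items():
            if when not in ("any_time", "before_index"):
                raise ValueError(f"exclusion set {name!r}: when must be "
                                 "'any_time' or 'before_index'")

    def threshold_for(self, sex: str) -> float:
        return self.abnormal_threshold_male if sex == "male" else self.abnormal_threshold_female


class ExclusionReason(str, Enum):
    AGE = "age_under_minimum"
    FOLLOWUP = "insufficient_followup"
    CONFOUNDER = "confounder_code"


def find_index_date(
    record: PatientRecord, criteria: InclusionCriteria
) -> Optional[dt.date]:
    """Date of the first abnormal index-lab value, if the patient qualifies.

    Qualification requires at least two abnormal values whose first-to-last
    span strictly exceeds ``min_separation_days``; absence is a valid result
    (returns ``None``).  The result does not depend on the order encounters
    were inserted before sorting, since records keep encounters date-sorted.
    """
    threshold = criteria.threshold_for(record.sex)
    abnormal_dates = [
        d for d, v in record.lab_events(criteria.index_lab_code) if v > threshold
    ]
    if len(abnormal_dates) < 2:
        return None
    if (abnormal_dates[-1] - abnormal_dates[0]).days > criteria.min_separation_days:
        return abnormal_dates[0]
    return None


def apply_exclusions(
    record: PatientRecord,
    index_date: dt.date,
    criteria: InclusionCriteria,
    db_end_date: Optional[dt.date] = None,
) -> tuple[bool, Optional[ExclusionReason]]:
    """Check a patient against the exclusion rules in fixed order.

    Order: age at index -> post-index follow-up -> confounder code sets.
    The reason names the first failing rule.  ``db_end_date`` is accepted
    for symmetry with database extraction but follow-up is measured to the
    patient's last encounter, which by construction cannot exceed it.
    """
    if index_date < record.birth_date:
        raise ValueError(
            f"index date {index_date} precedes birth date {record.birth_date}"
        )
    if record.age_at(index_date) < criteria.min_age_years:
        return False, ExclusionReason.AGE
    last = record.last_date
    if last is None or years_between(index_date, last) < criteria.min_followup_years:
        return False, ExclusionReason.FOLLOWUP
    for name, (codes, when) in criteria.exclusion_code_sets.items():
        before = index_date if when == "before_index" else None
        if record.has_code(codes, code_type="DX", before=before):
            return False, ExclusionReason.CONFOUNDER
    return True, None


def build_cohort(
    records: list[PatientRecord],
    criteria: InclusionCriteria,
    db_end_date: Optional[dt.date] = None,
) -> tuple[dict[str, dt.date], pd.DataFrame]:
    """Apply index detection and exclusions to a record list.

    Returns (patient_id -> index_date for included patients, attrition table
    with one row per filter stage).
    """
    index_dates: dict[str, dt.date] = {}
    counts = {"no_index_event": 0, ExclusionReason.AGE.value: 0,
              ExclusionReason.FOLLOWUP.value: 0, ExclusionReason.CONFOUNDER.value: 0}
    for rec in records:
        idx = find_index_date(rec, criteria)
        if idx is None:
            counts["no_index_event"] += 1
            continue
        ok, reason = apply_exclusions(rec, idx, criteria, db_end_date)
        if not ok:
            counts[reason.value] += 1
            continue
        index_dates[rec.patient_id] = idx
    attrition = pd.DataFrame(
        {
            "rule": ["input", *counts.keys(), "included"],
            "n": [len(records), *counts.values(), len(index_dates)],
        }
    )
    return index_dates, attrition


def build_case_control(
    cases: list[PatientRecord],
    pool: list[PatientRecord],
    ratio: int = 10,
    seed: int = 0,
    age_tolerance_years: float = 5.0,
    duration_tolerance_years: float = 1.0,
    min_age_years: int = 18,
) -> list[tuple[PatientRecord, list[PatientRecord]]]:
    """Sample matched controls per case for the large pretraining set.

    Controls are matched on sex (exact), age at first encounter (within
    ``age_tolerance_years``) and first-to-last encounter duration (within
    ``duration_tolerance_years``), drawn without replacement so control sets
    are disjoint across cases.  Cases with fewer than ``ratio`` eligible
    matches take all available, with a warning.
    """
    if not pool:
        raise ValueError("control pool is empty")
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = np.random.default_rng(seed)
    case_ids = {c.patient_id for c in cases}
    profiles = []
    for rec in pool:
        if rec.patient_id in case_ids:
            continue  # a control set may never contain a case
        if not rec.encounters or rec.age_at(rec.first_date) < min_age_years:
            continue
        profiles.append((rec, rec.age_at(rec.first_date), rec.span_years()))
    used: set[str] = set()
    out = []
    for case in cases:
        c_age = case.age_at(case.first_date)
        c_dur = case.span_years()
        eligible = [
            rec
            for rec, age, dur in profiles
            if rec.patient_id not in used
            and rec.sex == case.sex
            and abs(age - c_age) <= age_tolerance_years
            and abs(dur - c_dur) <= duration_tolerance_years
        ]
        take = min(ratio, len(eligible))
        if take < ratio:
            warnings.warn(
                f"case {case.patient_id}: only {take} of {ratio} matched "
                "controls available",
                stacklevel=2,
            )
        chosen = list(rng.choice(len(eligible), size=take, replace=False)) if take else []
        controls = [eligible[i] for i in chosen]
        used.update(r.patient_id for r in controls)
        out.append((case, controls))
    return out
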