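"""Shared fixtures: tiny hand-built records and small simulated cohorts."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from ehrisk.records import CodedEvent, Encounter, PatientRecord


D0 = dt.date(2005, 1, 15)


def make_record(
    patient_id="P1",
    sex="male",
    age_years=45,
    encounter_days=(0, 30, 200, 400),
    codes_per_encounter=None,
    alt_values=None,
):
    """Small helper to hand-build a PatientRecord.

    ``codes_per_encounter``: list (same length as days) of lists of DX codes.
    ``alt_values``: optional list of ALT lab values (None entries skip the lab).
    """
    birth = D0 - dt.timedelta(days=round(age_years * 365.25))
    encounters = []
    for i, day in enumerate(encounter_days):
        events = []
        if alt_values is not None and alt_values[i] is not None:
            events.append(CodedEvent("LAB", "LAB_ALT", float(alt_values[i])))
        if codes_per_encounter is not None:
            for c in codes_per_encounter[i]:
                events.append(CodedEvent("DX", c))
        if not events:
            events.append(CodedEvent("DX", "BG_FILLER"))
        encounters.append(Encounter(f"{patient_id}-e{i}", D0 + dt.timedelta(days=int(day)), events))
    return PatientRecord(patient_id, sex, birth, encounters)


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 120-patient simulated cohort with effects+telltales."""
    from ehrisk.synthetic import SimScenario, simulate_cohort

    scenario = SimScenario(
        n_patients=120,
        encounter_rate=3.0,
        followup_dist=("uniform", 11.0, 13.0),
        abnormal_prob=0.7,
        baseline_hazard=0.03,
        risk_effects={"DX_RISK_A": 1.5},
        protective_effects={"DX_PROT_A": -1.0},
        telltale_codes=["DX_TELL"],
        telltale_lead_years=1.5,
        background_codes=(5, 0.15),
        censor_hazard=0.01,
        seed=42,
    )
    return simulate_cohort(scenario)


@pytest.fixture(scope="session")
def labeled_small_cohort(small_cohort):
    from ehrisk.cohort import InclusionCriteria, build_cohort
    from ehrisk.labeling import LabelSpec, label_cohort

    records, truth = small_cohort
    index_dates, attrition = build_cohort(records, InclusionCriteria())
    entries = label_cohort(records, index_dates, LabelSpec())
    return records, truth, index_dates, entries


@pytest.fixture(scope="session")
def separable_toy():
    """200 short records where positives carry a marker code: linearly
    separable for the sequence classifier."""
    rng = np.random.default_rng(7)
    records, labels = [], []
    for i in range(200):
        pos = i % 2 == 1
        days = sorted(rng.choice(np.arange(0, 720), size=6, replace=False))
        codes = []
        for _ in days:
            base = [f"BG_{rng.integers(0, 5)}"]
            if pos and rng.random() < 0.8:
                base.append("MARKER")
            codes.append(base)
        records.append(
            make_record(f"T{i:03d}", "male" if i % 4 < 2 else "female",
                        40, days, codes_per_encounter=codes)
        )
        labels.append(int(pos))
    return records, np.array(labels)
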