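"""Generator contracts: determinism, structure, and recovery of the
ground-truth data-generating process."""

import datetime as dt
import io
import math

import numpy as np
import pytest

from ehrisk.io import write_event_table
from ehrisk.synthetic import (
    ScenarioError,
    SimScenario,
    simulate_cohort,
)


def _cohort_csv(records) -> str:
    buf = io.StringIO()
    write_event_table(records, buf)
    return buf.getvalue()


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("abnormal_prob", 1.5),
            ("baseline_hazard", 1.0),
            ("censor_hazard", -0.1),
            ("encounter_rate", 0.0),
            ("sex_ratio", 2.0),
            ("telltale_lead_years", -1.0),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ScenarioError, match=field):
            SimScenario(**{field: value})

    def test_effect_codes_disjoint_from_telltales(self):
        with pytest.raises(ScenarioError, match="disjoint"):
            SimScenario(risk_effects={"DX_X": 1.0}, telltale_codes=["DX_X"])

    def test_hazards_must_not_sum_past_one(self):
        with pytest.raises(ScenarioError, match="below 1"):
            SimScenario(baseline_hazard=0.6, censor_hazard=0.5)


class TestCohortStructure:
    def test_empty_cohort(self):
        records, truth = simulate_cohort(SimScenario(n_patients=0))
        assert records == [] and truth.patients == {}

    def test_fixed_seed_is_byte_identical(self):
        sc = dict(n_patients=40, seed=9, telltale_codes=["DX_T"],
                  risk_effects={"DX_R": 1.0}, baseline_hazard=0.05)
        a, _ = simulate_cohort(SimScenario(**sc))
        b, _ = simulate_cohort(SimScenario(**sc))
        assert _cohort_csv(a) == _cohort_csv(b)

    def test_dates_sorted_and_bounded_by_endpoint(self, small_cohort):
        records, truth = small_cohort
        for rec in records:
            dates = [e.date for e in rec.encounters]
            assert dates == sorted(dates)
            pt = truth.patients[rec.patient_id]
            if pt.event_years is not None:
                # record ends at the diagnosis encounter
                assert rec.encounters[-1].events[-1].code == truth.outcome_code

    def test_degenerate_followup_without_censoring(self):
        sc = SimScenario(n_patients=30, followup_dist=("fixed", 8.0),
                         censor_hazard=0.0, baseline_hazard=0.0, seed=3)
        _, truth = simulate_cohort(sc)
        assert all(pt.obs_end_years == 8.0 for pt in truth.patients.values())

    def test_telltales_only_in_event_patients(self, small_cohort):
        records, truth = small_cohort
        for rec in records:
            pt = truth.patients[rec.patient_id]
            has_telltale = any(
                "DX_TELL" in enc.codes("DX") for enc in rec.encounters
            )
            if pt.event_years is None:
                assert not has_telltale

    def test_telltale_emissions_precede_diagnosis(self, small_cohort):
        records, truth = small_cohort
        for rec in records:
            pt = truth.patients[rec.patient_id]
            if pt.event_years is None or not pt.telltale_emission_dates:
                continue
            dx_date = rec.encounters[-1].date
            assert all(d < dx_date for d in pt.telltale_emission_dates)


class TestGroundTruthRecovery:
    def test_cumulative_incidence_matches_closed_form(self):
        # with all effects zero the yearly hazard is exactly `h`, so the
        # 10-year cumulative incidence among fully observed patients is
        # 1 - (1-h)^10
        h, T, n = 0.05, 10, 12000
        sc = SimScenario(
            n_patients=n, encounter_rate=1.5, followup_dist=("fixed", 12.0),
            abnormal_prob=0.9, baseline_hazard=h, censor_hazard=0.0,
            background_codes=(0, 0.0), seed=11,
        )
        _, truth = simulate_cohort(sc)
        # fully observed: indexed with at least T complete post-index years
        eligible = [
            pt for pt in truth.patients.values()
            if pt.index_date is not None
            and (pt.event_years is not None or pt.obs_end_years >= T)
        ]
        events = [
            pt for pt in eligible
            if pt.event_years is not None and pt.event_years <= T
        ]
        expected = 1.0 - (1.0 - h) ** T
        phat = len(events) / len(eligible)
        se = math.sqrt(expected * (1 - expected) / len(eligible))
        assert abs(phat - expected) < 3 * se

    def test_logistic_hazard_regression_recovers_log_hr(self):
        # person-year expansion from ground truth; logistic regression on
        # (active exposure, event) must recover the simulated log-HR of 1.0
        target = 1.0
        sc = SimScenario(
            n_patients=4000, encounter_rate=1.5, followup_dist=("fixed", 12.0),
            abnormal_prob=0.9, baseline_hazard=0.05,
            risk_effects={"DX_R": target}, background_codes=(0, 0.0),
            censor_hazard=0.0, seed=21,
        )
        _, truth = simulate_cohort(sc)
        # person-year expansion: one Bernoulli(h_j) trial per complete
        # post-index year, exposure = code active at the start of the year
        rows, ys = [], []
        for pt in truth.patients.values():
            if pt.index_years is None:
                continue
            onset = pt.onsets.get("DX_R")
            if pt.event_years is not None:
                n_years = int(pt.event_years) + 1
                event_year = int(pt.event_years)
            else:
                n_years = int(pt.obs_end_years - pt.index_years)
                event_year = -1
            for j in range(n_years):
                active = onset is not None and onset <= pt.index_years + j
                rows.append(1.0 if active else 0.0)
                ys.append(1 if j == event_year else 0)
        X = np.column_stack([np.ones(len(rows)), np.array(rows)])
        y = np.array(ys, dtype=float)
        beta = np.zeros(2)
        for _ in range(50):  # Newton-Raphson for the 2-parameter logistic
            p = 1.0 / (1.0 + np.exp(-X @ beta))
            W = p * (1 - p)
            grad = X.T @ (y - p)
            info = (X * W[:, None]).T @ X
            step = np.linalg.solve(info, grad)
            beta += step
            if np.abs(step).max() < 1e-10:
                break
        se = math.sqrt(np.linalg.inv(info)[1, 1])
        assert abs(beta[1] - target) < 2 * se

    def test_rare_incidence_regime(self):
        # the target-cohort scenario family produces a rare outcome:
        # roughly 2 events per 1000 indexed patients within 10 years
        from ehrisk.synthetic import rare_incidence_scenario

        sc = rare_incidence_scenario(8000, seed=13)
        sc.background_codes = (0, 0.0)
        sc.encounter_rate = 2.0
        _, truth = simulate_cohort(sc)
        indexed = [p for p in truth.patients.values() if p.index_years is not None]
        events = [
            p for p in indexed
            if p.event_years is not None and p.event_years <= 10
        ]
        p_true = 1.0 - (1.0 - 0.0002) ** 10
        phat = len(events) / len(indexed)
        se = math.sqrt(p_true * (1 - p_true) / len(indexed))
        assert abs(phat - p_true) < 3 * se

    def test_incidence_monotone_in_effect_size(self):
        rates = []
        for eff in (0.0, 1.0, 2.0):
            sc = SimScenario(
                n_patients=2500, encounter_rate=1.5,
                followup_dist=("fixed", 12.0), abnormal_prob=0.9,
                baseline_hazard=0.02, risk_effects={"DX_R": eff},
                background_codes=(0, 0.0), censor_hazard=0.0,
                carrier_prob=1.0, onset_mode="baseline", seed=31,
            )
            _, truth = simulate_cohort(sc)
            carriers = [
                pt for pt in truth.patients.values()
                if pt.index_date is not None and "DX_R" in pt.onsets
            ]
            rates.append(
                sum(pt.event_years is not None for pt in carriers) / len(carriers)
            )
        assert rates[0] < rates[1] < rates[2]
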