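"""Horizon labeling truth table, matching covariates, propensity matching."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ehrisk.labeling import (
    Label,
    LabelExclusion,
    LabelSpec,
    MatchSpec,
    assign_label,
    compute_match_covariates,
    propensity_match,
    standardized_mean_difference,
)
from ehrisk.records import add_years

from conftest import D0, make_record

SPEC = LabelSpec()


def _label(event_days, censor_days):
    event = D0 + dt.timedelta(days=event_days) if event_days is not None else None
    censor = D0 + dt.timedelta(days=censor_days)
    return assign_label(D0, event, censor, SPEC)


YEARS = lambda y: round(y * 365.25)  # noqa: E731


class TestTruthTable:
    @pytest.mark.parametrize(
        "event_days, censor_days, label, reason",
        [
            (YEARS(11), YEARS(12), Label.NEGATIVE, None),   # archetype 1: late event
            (None, YEARS(12), Label.NEGATIVE, None),        # archetype 2: long follow-up
            (YEARS(5), YEARS(5), Label.POSITIVE, None),     # archetype 3: event in window
            (None, YEARS(7), Label.EXCLUDED, LabelExclusion.INSUFFICIENT_FOLLOWUP),  # 4
            (YEARS(1.5), YEARS(1.5), Label.EXCLUDED, LabelExclusion.EVENT_WITHIN_MIN_GAP),
            (-YEARS(1), YEARS(3), Label.EXCLUDED, LabelExclusion.EVENT_BEFORE_INDEX),
            # horizon boundary: the last day inside 10 years is positive,
            # the first day beyond it is negative ("within 10y" inclusive)
            (3652, 3660, Label.POSITIVE, None),
            (3653, 3660, Label.NEGATIVE, None),
            # minimum-gap boundary: clearing 2 years counts as positive
            (731, YEARS(3), Label.POSITIVE, None),
            (730, YEARS(3), Label.EXCLUDED, LabelExclusion.EVENT_WITHIN_MIN_GAP),
            (None, 3652, Label.EXCLUDED, LabelExclusion.INSUFFICIENT_FOLLOWUP),
        ],
    )
    def test_archetypes_and_boundaries(self, event_days, censor_days, label, reason):
        got_label, got_reason = _label(event_days, censor_days)
        assert (got_label, got_reason) == (label, reason)

    def test_event_after_censor_is_data_error(self):
        with pytest.raises(ValueError, match="event_date"):
            assign_label(D0, add_years(D0, 5), add_years(D0, 4), SPEC)

    def test_censor_before_index_is_data_error(self):
        with pytest.raises(ValueError, match="censor_date"):
            assign_label(D0, None, D0 - dt.timedelta(days=1), SPEC)

    @given(
        event_days=st.one_of(st.none(), st.integers(-2000, 6000)),
        censor_extra=st.integers(0, 6000),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_partition_matches_rule_oracle(self, event_days, censor_extra):
        """Every (index, event, censor) triple lands in exactly one outcome,
        agreeing with an independent day-arithmetic oracle."""
        event = D0 + dt.timedelta(days=event_days) if event_days is not None else None
        censor_days = (max(event_days, 0) if event_days is not None else 0) + censor_extra
        censor = D0 + dt.timedelta(days=censor_days)
        got = assign_label(D0, event, censor, SPEC)

        horizon_d, gap_d = 10 * 365.25, 2 * 365.25
        if event_days is not None:
            if event_days < 0:
                want = (Label.EXCLUDED, LabelExclusion.EVENT_BEFORE_INDEX)
            elif event_days < gap_d:
                want = (Label.EXCLUDED, LabelExclusion.EVENT_WITHIN_MIN_GAP)
            elif event_days <= horizon_d:
                want = (Label.POSITIVE, None)
            else:
                want = (Label.NEGATIVE, None)
        elif censor_days > horizon_d:
            want = (Label.NEGATIVE, None)
        else:
            want = (Label.EXCLUDED, LabelExclusion.INSUFFICIENT_FOLLOWUP)
        assert got == want


class TestMatchCovariates:
    def test_hand_arithmetic(self):
        rec = make_record(encounter_days=(0, 10, 30))
        mean, sd, count = compute_match_covariates(rec)
        assert mean == 15 and count == 3
        assert sd == pytest.approx(7.0710678, abs=1e-6)  # sample SD of (10, 20)

    def test_single_encounter(self):
        assert list(compute_match_covariates(make_record(encounter_days=(0,)))) == [0, 0, 1]

    def test_equally_spaced_has_zero_sd(self):
        rec = make_record(encounter_days=(0, 50, 100, 150))
        assert compute_match_covariates(rec)[1] == 0.0


class TestPropensityMatch:
    def _cohort(self, n, rng, k_range=(4, 12)):
        out = []
        for i in range(n):
            k = rng.integers(*k_range)
            days = np.sort(rng.choice(np.arange(1, 3000), size=k, replace=False))
            out.append(make_record(f"R{k_range[0]}-{i}", "male", 50, tuple(days)))
        return out

    def test_matching_reduces_or_bounds_imbalance(self):
        # negatives drawn with systematically more encounters: matching
        # must shrink the imbalance (or land inside the conventional 0.1 band)
        rng = np.random.default_rng(5)
        pos = self._cohort(40, rng, k_range=(4, 10))
        neg = self._cohort(160, rng, k_range=(6, 18))
        mpos, mneg, report = propensity_match(pos, neg, MatchSpec(ratio=1), seed=0)
        assert len(mpos) == len(mneg) == 40
        for _, row in report.iterrows():
            assert (
                abs(row["smd_after"]) < abs(row["smd_before"])
                or abs(row["smd_after"]) <= 0.1
            )

    def test_one_pair(self):
        pos = [make_record("P", "male", 50, (0, 100))]
        neg = [make_record("N", "male", 50, (0, 90))]
        mpos, mneg, _ = propensity_match(pos, neg)
        assert mpos[0].patient_id == "P" and mneg[0].patient_id == "N"

    def test_greedy_assignment_matches_independent_replay(self):
        """The pairing equals a from-scratch replay of the greedy rule:
        refit the same propensity model in the test, order positives by
        descending logit, give each its nearest unused negative."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(11)
        pos = self._cohort(6, rng, k_range=(4, 10))
        neg = self._cohort(10, rng, k_range=(5, 14))
        mpos, mneg, _ = propensity_match(pos, neg, seed=0)
        got = dict(zip([p.patient_id for p in mpos], [n.patient_id for n in mneg]))

        x = np.array([compute_match_covariates(r) for r in pos + neg])
        xs = (x - x.mean(0)) / x.std(0)
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        lr = LogisticRegression(C=np.inf, max_iter=1000, random_state=0).fit(xs, y)
        logits = xs @ lr.coef_.ravel() + lr.intercept_[0]
        lp, ln = logits[: len(pos)], logits[len(pos):]
        want, used = {}, set()
        for i in sorted(range(len(pos)), key=lambda i: (-lp[i], pos[i].patient_id)):
            j = min(
                (j for j in range(len(neg)) if j not in used),
                key=lambda j: (abs(ln[j] - lp[i]), neg[j].patient_id),
            )
            used.add(j)
            want[pos[i].patient_id] = neg[j].patient_id
        assert got == want

    def test_controls_never_reused(self):
        rng = np.random.default_rng(6)
        pos = self._cohort(15, rng)
        neg = self._cohort(15, rng)
        _, mneg, _ = propensity_match(pos, neg)
        ids = [n.patient_id for n in mneg]
        assert len(ids) == len(set(ids))

    def test_no_negatives_is_error(self):
        with pytest.raises(ValueError):
            propensity_match([make_record("P", "male", 50, (0,))], [])


def test_smd_zero_for_identical_groups():
    x = np.random.default_rng(0).normal(size=(30, 3))
    assert np.allclose(standardized_mean_difference(x, x), 0.0)
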