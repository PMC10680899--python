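"""Synthetic longitudinal EHR cohorts with known ground truth.

The generator emulates the statistical structure that the downstream
strategies target, with every piece of ground truth retained for recovery
tests:

* an index event defined by repeated abnormal values of a sex-thresholded
  lab test (the time origin for all risk horizons);
* a discrete-time event hazard on a yearly grid after the index date,
  modulated on the logit scale by time-varying "effect" codes while they are
  active (risk codes raise the hazard, protective codes lower it, and the
  log-hazard-ratios may differ by sex);
* delayed diagnosis: "telltale" codes that start appearing a random lead
  time before the formal outcome diagnosis code, which is exactly the
  leakage that backward masking must remove;
* right-censoring through a per-year loss-to-follow-up hazard and a finite
  planned observation span;
* uninformative background codes.

Time is internally integer days (1 year = 365.25 days); encounters are a
homogeneous Poisson process per patient; all randomness flows from a single
seed via per-patient ``numpy`` sub-streams, so a fixed seed yields a
byte-identical cohort regardless of evaluation order.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .records import (
    DAYS_PER_YEAR,
    HALF_YEAR_DAYS,
    CodedEvent,
    Encounter,
    PatientRecord,
    add_years,
)

EPOCH = dt.date(2000, 1, 1)

#: Sex-specific abnormality thresholds for the index lab (IU/mL).
ABNORMAL_THRESHOLD = {"male": 40.0, "female": 31.0}


class ScenarioError(ValueError):
    """A scenario field violates its constraints; message names the field."""


def _as_sex_map(value) -> dict[str, float]:
    if isinstance(value, dict):
        return {"male": float(value["male"]), "female": float(value["female"])}
    return {"male": float(value), "female": float(value)}


@dataclass
class SimScenario:
    """Full specification of the synthetic data-generating process.

    ``risk_effects`` / ``protective_effects`` map a diagnosis code to its
    per-sex log-hazard-ratio, either as a scalar (shared across sexes) or as
    a ``{"male": x, "female": y}`` dict.  ``followup_dist`` is either
    ``("fixed", years)`` or ``("uniform", low, high)``.
    ``background_codes`` is ``(count, per_encounter_prob)``.
    """

    n_patients: int = 1000
    sex_ratio: float = 0.5
    encounter_rate: float = 4.0
    #: sigma of the mean-preserving log-normal spread of per-patient visit
    #: rates around encounter_rate (EHR visit frequency is highly variable;
    #: the overlap it creates is what lets propensity matching balance
    #: encounter-pattern covariates between long and short records)
    encounter_rate_dispersion: float = 0.8
    followup_dist: tuple = ("uniform", 11.0, 14.0)
    index_lab_code: str = "LAB_ALT"
    abnormal_prob: float = 0.6
    baseline_hazard: float = 0.01
    risk_effects: dict = field(default_factory=dict)
    protective_effects: dict = field(default_factory=dict)
    telltale_codes: list = field(default_factory=list)
    telltale_lead_years: float = 1.5
    background_codes: tuple = (20, 0.15)
    censor_hazard: float = 0.0
    outcome_code: str = "DX_EVENT"
    # generator constants left open by the study design, fixed here once:
    carrier_prob: float = 0.5          # P(patient ever acquires an effect code)
    active_emission_prob: float = 0.7  # P(active effect code recorded per encounter)
    telltale_emission_prob: float = 0.5
    onset_mode: str = "post_index"     # "post_index" | "baseline"
    age_range: tuple = (25, 75)
    seed: int = 0

    def __post_init__(self) -> None:
        self.risk_effects = {c: _as_sex_map(v) for c, v in self.risk_effects.items()}
        self.protective_effects = {
            c: _as_sex_map(v) for c, v in self.protective_effects.items()
        }
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ScenarioError("n_patients must be >= 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ScenarioError("sex_ratio must lie in [0, 1]")
        if self.encounter_rate <= 0:
            raise ScenarioError("encounter_rate must be > 0")
        for name in ("abnormal_prob", "carrier_prob", "active_emission_prob",
                     "telltale_emission_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ScenarioError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.baseline_hazard < 1.0:
            raise ScenarioError("baseline_hazard must lie in [0, 1)")
        if not 0.0 <= self.censor_hazard < 1.0:
            raise ScenarioError("censor_hazard must lie in [0, 1)")
        if self.baseline_hazard + self.censor_hazard >= 1.0:
            raise ScenarioError(
                "baseline_hazard + censor_hazard must stay below 1 per time step"
            )
        if self.telltale_lead_years < 0:
            raise ScenarioError("telltale_lead_years must be >= 0")
        if self.onset_mode not in ("post_index", "baseline"):
            raise ScenarioError("onset_mode must be 'post_index' or 'baseline'")
        kind = self.followup_dist[0]
        if kind not in ("fixed", "uniform"):
            raise ScenarioError("followup_dist kind must be 'fixed' or 'uniform'")
        effect_codes = set(self.risk_effects) | set(self.protective_effects)
        if set(self.risk_effects) & set(self.protective_effects):
            raise ScenarioError(
                "risk_effects and protective_effects keys must be disjoint"
            )
        if effect_codes & set(self.telltale_codes) or self.index_lab_code in (
            effect_codes | set(self.telltale_codes)
        ):
            raise ScenarioError(
                "risk_effects/protective_effects must be disjoint from "
                "telltale_codes and index_lab_code"
            )

    @property
    def effects(self) -> dict[str, dict[str, float]]:
        merged = dict(self.risk_effects)
        merged.update(self.protective_effects)
        return merged

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PatientTruth:
    """Ground truth for a single simulated patient."""

    patient_id: str
    sex: str
    index_date: Optional[dt.date]
    #: index offset in years from the first encounter, or None
    index_years: Optional[float]
    #: event time in years from index, or None
    event_years: Optional[float]
    #: observation end in years from first encounter (censor time)
    obs_end_years: float
    #: effect-code onset times in years from first encounter
    onsets: dict[str, float] = field(default_factory=dict)
    telltale_emission_dates: list[dt.date] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Cohort-level ground truth: per-patient truths plus true effect sizes."""

    patients: dict[str, PatientTruth] = field(default_factory=dict)
    log_hr_by_sex: dict[str, dict[str, float]] = field(default_factory=dict)
    outcome_code: str = "DX_EVENT"

    def event_years(self, patient_id: str) -> Optional[float]:
        return self.patients[patient_id].event_years


def _draw_followup(dist: tuple, rng: np.random.Generator) -> float:
    if dist[0] == "fixed":
        return float(dist[1])
    return float(rng.uniform(dist[1], dist[2]))


def _index_from_abnormals(abn_days: np.ndarray) -> Optional[int]:
    """First abnormal-lab day if >=2 abnormals span more than 6 months."""
    if len(abn_days) < 2:
        return None
    if abn_days[-1] - abn_days[0] > HALF_YEAR_DAYS:
        return int(abn_days[0])
    return None


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _simulate_patient(
    pid: str, scenario: SimScenario, rng: np.random.Generator
) -> tuple[Optional[PatientRecord], PatientTruth]:
    sex = "male" if rng.random() < scenario.sex_ratio else "female"
    start = EPOCH + dt.timedelta(days=int(rng.integers(0, 5 * 365)))
    age = int(rng.integers(scenario.age_range[0], scenario.age_range[1] + 1))
    birth = start - dt.timedelta(days=round(age * DAYS_PER_YEAR))

    span = _draw_followup(scenario.followup_dist, rng)
    if scenario.censor_hazard > 0:
        g = rng.geometric(scenario.censor_hazard)  # censoring falls in year g-1
        censor = (g - 1) + rng.random()
        span = min(span, censor)

    sigma = scenario.encounter_rate_dispersion
    rate = scenario.encounter_rate * rng.lognormal(-0.5 * sigma**2, sigma)
    n_enc = rng.poisson(rate * span)
    enc_days = np.unique(
        np.concatenate([[0], (rng.random(n_enc) * span * DAYS_PER_YEAR).astype(int)])
    )
    enc_years = enc_days / DAYS_PER_YEAR

    # index lab at every encounter
    threshold = ABNORMAL_THRESHOLD[sex]
    abnormal = rng.random(len(enc_days)) < scenario.abnormal_prob
    lab_values = np.where(
        abnormal,
        rng.uniform(threshold + 1, threshold + 60, len(enc_days)),
        rng.uniform(5.0, threshold - 1, len(enc_days)),
    )
    index_day = _index_from_abnormals(enc_days[abnormal])
    index_years = index_day / DAYS_PER_YEAR if index_day is not None else None

    # effect-code onsets (years from first encounter)
    onsets: dict[str, float] = {}
    for code in scenario.effects:
        if rng.random() >= scenario.carrier_prob:
            continue
        if scenario.onset_mode == "baseline":
            onsets[code] = 0.0
        elif index_years is not None:
            onsets[code] = float(rng.uniform(index_years, max(span, index_years)))
        else:
            onsets[code] = float(rng.uniform(0.0, span))

    # yearly discrete-time event hazard after index
    event_years = None  # from index
    if index_years is not None and scenario.baseline_hazard > 0:
        base = _logit(scenario.baseline_hazard)
        n_years = int(span - index_years)  # only fully observed years
        u = rng.random(max(n_years, 0))
        for j in range(n_years):
            eta = base
            for code, onset in onsets.items():
                if onset <= index_years + j:
                    eta += scenario.effects[code][sex]
            if u[j] < 1.0 / (1.0 + math.exp(-eta)):
                event_years = j + rng.random()
                break

    if event_years is not None:
        end_years = index_years + event_years
        event_day = int(round(end_years * DAYS_PER_YEAR))
        enc_mask = enc_days <= event_day
        enc_days = enc_days[enc_mask]
        enc_years = enc_years[enc_mask]
        abnormal = abnormal[enc_mask]
        lab_values = lab_values[enc_mask]
    else:
        end_years = span
        event_day = None

    # telltale emissions: strictly before the diagnosis-code date
    telltale_start = None
    if event_day is not None and scenario.telltale_codes:
        lead = rng.exponential(scenario.telltale_lead_years)
        telltale_start = event_day - lead * DAYS_PER_YEAR
    telltale_hits = {}
    if telltale_start is not None:
        eligible = (enc_days >= telltale_start) & (enc_days < event_day)
        for code in scenario.telltale_codes:
            telltale_hits[code] = eligible & (
                rng.random(len(enc_days)) < scenario.telltale_emission_prob
            )

    # active effect-code emissions
    effect_hits = {}
    for code, onset in onsets.items():
        effect_hits[code] = (enc_years >= onset) & (
            rng.random(len(enc_days)) < scenario.active_emission_prob
        )

    n_bg, bg_prob = scenario.background_codes
    bg_hits = rng.random((len(enc_days), n_bg)) < bg_prob if n_bg else None

    encounters = []
    sex_code = "SEX_M" if sex == "male" else "SEX_F"
    for i, day in enumerate(enc_days):
        events = [CodedEvent("LAB", scenario.index_lab_code, round(float(lab_values[i]), 1))]
        if i == 0:
            events.append(CodedEvent("DEMO", sex_code))
        for code, hits in effect_hits.items():
            if hits[i]:
                events.append(CodedEvent("DX", code))
        for code, hits in telltale_hits.items():
            if hits[i]:
                events.append(CodedEvent("DX", code))
        if bg_hits is not None:
            for k in np.nonzero(bg_hits[i])[0]:
                events.append(CodedEvent("DX", f"BG_{k:03d}"))
        date = start + dt.timedelta(days=int(day))
        encounters.append(Encounter(f"{pid}-e{i}", date, events))

    telltale_dates = []
    if telltale_hits:
        any_hit = np.zeros(len(enc_days), dtype=bool)
        for hits in telltale_hits.values():
            any_hit |= hits
        telltale_dates = [
            start + dt.timedelta(days=int(d)) for d in enc_days[any_hit]
        ]

    if event_day is not None:
        event_date = start + dt.timedelta(days=event_day)
        encounters = [e for e in encounters if e.date < event_date]
        encounters.append(
            Encounter(
                f"{pid}-dx",
                event_date,
                [CodedEvent("DX", scenario.outcome_code)],
            )
        )

    record = PatientRecord(pid, sex, birth, encounters)
    truth = PatientTruth(
        patient_id=pid,
        sex=sex,
        index_date=(start + dt.timedelta(days=index_day)) if index_day is not None else None,
        index_years=index_years,
        event_years=event_years,
        obs_end_years=end_years,
        onsets=onsets,
        telltale_emission_dates=telltale_dates,
    )
    return record, truth


def simulate_cohort(scenario: SimScenario) -> tuple[list[PatientRecord], GroundTruth]:
    """Simulate a cohort of :class:`PatientRecord` with full ground truth.

    Deterministic given ``scenario.seed``; per-patient randomness is drawn
    from spawned sub-streams so results do not depend on iteration order.
    """
    scenario.validate()
    truth = GroundTruth(
        log_hr_by_sex=scenario.effects, outcome_code=scenario.outcome_code
    )
    records: list[PatientRecord] = []
    children = np.random.SeedSequence(scenario.seed).spawn(scenario.n_patients)
    for i, child in enumerate(children):
        pid = f"P{i:06d}"
        rec, pt = _simulate_patient(pid, scenario, np.random.default_rng(child))
        records.append(rec)
        truth.patients[pid] = pt
    return records, truth


# ---------------------------------------------------------------------------
# Scenario families used by the experiments.  These defaults ARE the study
# conditions; they are chosen once and documented in docs/methods.md.
# ---------------------------------------------------------------------------

def rare_incidence_scenario(n_patients: int = 20000, seed: int = 0) -> SimScenario:
    """Target-cohort conditions: rare outcome (~2/1000 at 10 years)."""
    return SimScenario(
        n_patients=n_patients,
        baseline_hazard=0.0002,
        followup_dist=("uniform", 11.0, 14.0),
        censor_hazard=0.02,
        seed=seed,
    )


def trajectory_scenario(n_patients: int = 2000, seed: int = 0, *,
                        onset_mode: str = "post_index") -> SimScenario:
    """Hazard driven by post-index code trajectories (time-varying signal)."""
    return SimScenario(
        n_patients=n_patients,
        encounter_rate=5.0,
        followup_dist=("uniform", 11.0, 14.0),
        abnormal_prob=0.7,
        baseline_hazard=0.015,
        risk_effects={"DX_RISK_A": 1.6, "DX_RISK_B": 1.2},
        protective_effects={"DX_PROT_A": -1.2},
        background_codes=(15, 0.15),
        censor_hazard=0.01,
        onset_mode=onset_mode,
        seed=seed,
    )


def telltale_scenario(n_patients: int = 2000, seed: int = 0) -> SimScenario:
    """Adds delayed-diagnosis telltale codes on top of the trajectory signal."""
    sc = trajectory_scenario(n_patients, seed)
    sc.telltale_codes = ["DX_TELL_A", "DX_TELL_B"]
    sc.telltale_lead_years = 2.0
    sc.validate()
    return sc


def sex_bias_scenario(n_patients: int = 2400, seed: int = 0) -> SimScenario:
    """Disjoint sex-specific risk codes (covariate imbalance by sex)."""
    return SimScenario(
        n_patients=n_patients,
        encounter_rate=5.0,
        followup_dist=("uniform", 11.0, 14.0),
        abnormal_prob=0.7,
        baseline_hazard=0.012,
        risk_effects={
            "DX_RISK_M": {"male": 2.0, "female": 0.0},
            "DX_RISK_F": {"male": 0.0, "female": 2.0},
        },
        background_codes=(15, 0.15),
        censor_hazard=0.01,
        seed=seed,
    )


def null_scenario(n_patients: int = 300, seed: int = 0,
                  effect: float = 0.0) -> SimScenario:
    """Type-I-error study conditions: one designated code with a given effect
    (zero under the null), onset at baseline so exposure is measurable at the
    index date, and follow-up long enough that every indexed patient labels."""
    return SimScenario(
        n_patients=n_patients,
        encounter_rate=2.0,
        followup_dist=("fixed", 12.0),
        abnormal_prob=0.7,
        baseline_hazard=0.03,
        risk_effects={"DX_NULL": effect},
        background_codes=(0, 0.0),
        censor_hazard=0.0,
        onset_mode="baseline",
        seed=seed,
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write the per-patient ground-truth sidecar table (CSV)."""
    import pandas as pd

    rows = []
    for pt in truth.patients.values():
        rows.append(
            {
                "patient_id": pt.patient_id,
                "sex": pt.sex,
                "index_date": pt.index_date.isoformat() if pt.index_date else "",
                "event_years": "" if pt.event_years is None else pt.event_years,
                "obs_end_years": pt.obs_end_years,
                "n_telltale_emissions": len(pt.telltale_emission_dates),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
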