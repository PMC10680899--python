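"""Backward masking against delayed diagnosis.

Telltale signs of a slowly progressing disease are often recorded well
before its formal diagnosis code.  A model trained on full histories can
exploit these near-diagnosis encounters instead of genuine risk factors.
Backward masking removes every encounter within the last ``mask_years``
before each patient's endpoint — the diagnosis date for event patients,
the censoring (last-encounter) date otherwise — so increasing the mask
length withholds progressively more recent longitudinal information.

Removal is strict: an encounter dated exactly ``endpoint - mask_years`` is
retained.  Masked sets are therefore nested across mask lengths, and
labels (computed before masking) are unchanged by it.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .labeling import CohortEntry
from .records import DAYS_PER_YEAR, Encounter, PatientRecord, add_years, years_between

logger = logging.getLogger(__name__)

DEFAULT_MASK_GRID = (0.5, 1.0, 2.0, 4.0)


@dataclass
class MaskSpec:
    mask_years: float = 0.5
    #: measure retained history from "first_encounter" or from "index"
    history_origin: str = "first_encounter"

    def __post_init__(self) -> None:
        if self.mask_years < 0:
            raise ValueError("mask_years must be >= 0")
        if self.history_origin not in ("first_encounter", "index"):
            raise ValueError("history_origin must be 'first_encounter' or 'index'")


@dataclass
class MaskedRecord:
    """A PatientRecord with its final ``mask_years`` of history removed."""

    record: PatientRecord
    endpoint_date: dt.date
    retained_history_years: float

    @property
    def patient_id(self) -> str:
        return self.record.patient_id

    @property
    def encounters(self) -> list[Encounter]:
        return self.record.encounters


def mask_history(
    record: PatientRecord, endpoint: dt.date, spec: MaskSpec
) -> MaskedRecord:
    """Drop encounters with date strictly after ``endpoint - mask_years``.

    The result may be empty; retained encounters keep their original order.
    ``retained_history_years`` spans first original encounter (or index,
    per spec) to the last retained encounter, 0 if nothing is retained.
    """
    cutoff = endpoint - dt.timedelta(days=round(spec.mask_years * DAYS_PER_YEAR))
    kept = [e for e in record.encounters if e.date <= cutoff]
    masked = PatientRecord(record.patient_id, record.sex, record.birth_date, list(kept))
    if kept and record.encounters:
        origin = record.encounters[0].date
        retained = max(years_between(origin, kept[-1].date), 0.0)
    else:
        retained = 0.0
    return MaskedRecord(masked, endpoint, retained)


def mask_cohort(
    records: dict[str, PatientRecord],
    entries: Sequence[CohortEntry],
    spec: MaskSpec,
    index_dates: Optional[dict[str, dt.date]] = None,
) -> dict[str, MaskedRecord]:
    """Mask every labeled (non-excluded) patient relative to its endpoint.

    Patients whose masked record becomes empty are dropped with a logged
    count: sequence models need at least one encounter.
    """
    out: dict[str, MaskedRecord] = {}
    n_empty = 0
    for entry in entries:
        if entry.label.value == "excluded":
            continue
        rec = records[entry.patient_id]
        masked = mask_history(rec, entry.endpoint_date, spec)
        if spec.history_origin == "index" and index_dates is not None and masked.encounters:
            masked.retained_history_years = max(
                years_between(index_dates[entry.patient_id], masked.encounters[-1].date),
                0.0,
            )
        if not masked.encounters:
            n_empty += 1
            continue
        out[entry.patient_id] = masked
    if n_empty:
        logger.info(
            "masking at %.2f years emptied %d records (dropped)",
            spec.mask_years,
            n_empty,
        )
    return out


def masking_profile(
    records: dict[str, PatientRecord],
    entries: Sequence[CohortEntry],
    mask_grid: Sequence[float] = DEFAULT_MASK_GRID,
) -> pd.DataFrame:
    """Mean/median retained medical history per mask length.

    Mirrors the attrition of longitudinal information as the mask grows:
    the mean is monotone non-increasing in mask length.
    """
    labeled = [e for e in entries if e.label.value != "excluded"]
    if not labeled:
        raise ValueError("empty (or fully excluded) cohort")
    rows = []
    for L in mask_grid:
        spec = MaskSpec(mask_years=L)
        retained = [
            mask_history(records[e.patient_id], e.endpoint_date, spec).retained_history_years
            for e in labeled
        ]
        rows.append(
            {
                "mask_years": L,
                "mean_history_years": float(np.mean(retained)),
                "median_history_years": float(np.median(retained)),
                "n_patients": len(retained),
            }
        )
    return pd.DataFrame(rows)
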