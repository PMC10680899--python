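"""Cohort-level aggregation of per-code attention contribution scores.

The sequence model attributes its positive-class logit to individual
(encounter, code) occurrences.  Aggregation is a two-stage mean — within
each patient across the encounters where the code occurs, then across
patients — which weights every patient equally regardless of how often the
code appears in their record.  Codes seen in too few patients are dropped
from cohort rankings; a per-patient display filter keeps only codes with at
least one score outside the middle percentile band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AttentionRecord:
    """One code occurrence's signed contribution to a patient's risk logit."""

    patient_id: str
    encounter_index: int
    code: str
    score: float


@dataclass
class CodeImportance:
    code: str
    importance: float
    n_patients: int
    rank: int


def _records_frame(records: Sequence[AttentionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "encounter_index": [r.encounter_index for r in records],
            "code": [r.code for r in records],
            "score": [r.score for r in records],
        }
    )


def aggregate_scores(
    records: Sequence[AttentionRecord], min_patients: int = 10
) -> list[CodeImportance]:
    """Two-stage mean importance per code, ranked risk-first.

    Stage 1: mean score per (patient, code) across the encounters where the
    code occurs.  Stage 2: mean of those patient-level means across
    patients.  Codes observed in fewer than ``min_patients`` patients are
    excluded.  Rank 1 is the strongest risk factor (most positive); the end
    of the list holds the strongest protective factors.
    """
    if not records:
        return []
    # canonical row order first, so float accumulation and rank ties do not
    # depend on the order records arrive in
    df = _records_frame(records).sort_values(
        ["code", "patient_id", "encounter_index", "score"], kind="mergesort"
    )
    per_patient = df.groupby(["code", "patient_id"])["score"].mean()
    cohort = per_patient.groupby("code").agg(["mean", "size"])
    cohort = cohort[cohort["size"] >= min_patients]
    cohort = cohort.reset_index().sort_values(
        ["mean", "code"], ascending=[False, True], kind="mergesort"
    ).set_index("code")
    return [
        CodeImportance(code, float(row["mean"]), int(row["size"]), rank)
        for rank, (code, row) in enumerate(cohort.iterrows(), start=1)
    ]


def importance_table(importances: Sequence[CodeImportance]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "code": [c.code for c in importances],
            "importance": [c.importance for c in importances],
            "n_patients": [c.n_patients for c in importances],
            "rank": [c.rank for c in importances],
        }
    )


def patient_heatmap_data(
    records: Sequence[AttentionRecord], lower: float = 25.0, upper: float = 75.0
) -> pd.DataFrame:
    """Code x encounter score matrix for one patient's display.

    A code is kept iff any of its per-encounter scores falls strictly
    outside the [lower, upper] percentile band of all the patient's scores
    (percentiles by linear interpolation over the pooled distribution).
    With a degenerate band (all scores equal) nothing is kept.
    """
    if not records:
        raise ValueError("no attention records")
    df = _records_frame(records)
    if df["patient_id"].nunique() > 1:
        raise ValueError("heatmap data is per-patient; got multiple patients")
    lo, hi = np.percentile(df["score"], [lower, upper])
    keep = df.groupby("code")["score"].transform(
        lambda s: ((s < lo) | (s > hi)).any()
    )
    kept = df[keep.astype(bool)]
    return kept.pivot_table(
        index="code", columns="encounter_index", values="score"
    )


def sexwise_rankings(
    records: Sequence[AttentionRecord],
    sex_by_patient: dict[str, str],
    min_patients: int = 10,
) -> dict[str, object]:
    """Per-sex cohort rankings plus codes whose sign flips between sexes.

    Returns {"male": [...], "female": [...], "sign_discordant": [...]};
    an absent sex yields a single list and a note instead.
    """
    by_sex: dict[str, list[AttentionRecord]] = {"male": [], "female": []}
    for r in records:
        by_sex[sex_by_patient[r.patient_id]].append(r)
    out: dict[str, object] = {}
    rankings = {}
    for sex, recs in by_sex.items():
        if recs:
            rankings[sex] = aggregate_scores(recs, min_patients=min_patients)
    out.update(rankings)
    if len(rankings) < 2:
        out["note"] = "only one sex present; no cross-sex comparison"
        return out
    means = {
        sex: {c.code: c.importance for c in ranking}
        for sex, ranking in rankings.items()
    }
    shared = set(means["male"]) & set(means["female"])
    out["sign_discordant"] = sorted(
        c for c in shared if np.sign(means["male"][c]) != np.sign(means["female"][c])
        and means["male"][c] != 0 and means["female"][c] != 0
    )
    return out
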