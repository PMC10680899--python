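"""Event-table readers/writers, run configuration, and the end-to-end
pipeline (simulate -> cohort -> label -> mask -> match -> model -> rankings).

The canonical interchange format is a long-format CSV event table, one row
per code occurrence::

    patient_id, encounter_id, date, code_type, code, value

with ISO-8601 dates, ``code_type`` in {DX, MED, LAB, DEMO} and ``value``
populated only for LAB rows.  Patient-level demographics travel in the same
table as rows with the reserved encounter id ``__demo__`` (codes
``SEX_M``/``SEX_F`` and ``BIRTH_<iso-date>``), so a cohort round-trips
through a single file.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .attention import aggregate_scores, importance_table
from .cohort import InclusionCriteria, build_cohort
from .experiments import assemble_dataset, cross_validate, retain_factory
from .survival import BaselineFeatureSpec
from .labeling import LabelSpec, label_cohort, label_table
from .masking import DEFAULT_MASK_GRID, masking_profile
from .records import CodedEvent, Encounter, PatientRecord
from .retain import ModelConfig, RetainClassifier, build_dictionary
from .synthetic import SimScenario, simulate_cohort, write_ground_truth

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["patient_id", "encounter_id", "date", "code_type", "code", "value"]
DEMO_ENCOUNTER_ID = "__demo__"


class SchemaError(ValueError):
    pass


def write_event_table(records: Sequence[PatientRecord], path) -> None:
    """Write records to the long-format CSV, demographics included."""
    rows = []
    for rec in records:
        first = rec.first_date or dt.date.today()
        sex_code = "SEX_M" if rec.sex == "male" else "SEX_F"
        rows.append((rec.patient_id, DEMO_ENCOUNTER_ID, first.isoformat(),
                     "DEMO", sex_code, ""))
        rows.append((rec.patient_id, DEMO_ENCOUNTER_ID, first.isoformat(),
                     "DEMO", f"BIRTH_{rec.birth_date.isoformat()}", ""))
        for enc in rec.encounters:
            for ev in enc.events:
                rows.append(
                    (
                        rec.patient_id,
                        enc.encounter_id,
                        enc.date.isoformat(),
                        ev.code_type,
                        ev.code,
                        "" if ev.value is None else ev.value,
                    )
                )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_event_table(path) -> list[PatientRecord]:
    """Read a long-format event table back into :class:`PatientRecord`\\ s.

    Rows are grouped per patient and encounter and date-sorted.  Malformed
    rows (bad date, non-numeric LAB value, unknown code type) are rejected
    with their line numbers logged; missing columns raise ``SchemaError``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"event table missing columns: {sorted(missing)}")
    records: dict[str, dict] = {}
    n_bad = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        try:
            date = dt.date.fromisoformat(row.date)
            value = None
            if row.code_type == "LAB" and row.value != "":
                value = float(row.value)
            elif row.value not in ("", None) and row.code_type != "LAB":
                raise ValueError("non-LAB row carries a value")
            info = records.setdefault(
                row.patient_id,
                {"sex": None, "birth": None, "encounters": {}},
            )
            if row.encounter_id == DEMO_ENCOUNTER_ID:
                if row.code in ("SEX_M", "SEX_F"):
                    info["sex"] = "male" if row.code == "SEX_M" else "female"
                elif row.code.startswith("BIRTH_"):
                    info["birth"] = dt.date.fromisoformat(row.code[6:])
                continue
            enc = info["encounters"].setdefault(row.encounter_id, (date, []))
            enc[1].append(CodedEvent(row.code_type, row.code, value))
        except (ValueError, KeyError) as exc:
            n_bad += 1
            logger.warning("rejected line %d: %s", i, exc)
    if n_bad:
        logger.warning("rejected %d malformed event rows", n_bad)
    out = []
    for pid, info in records.items():
        if info["sex"] is None or info["birth"] is None:
            logger.warning("patient %s lacks demographics; skipped", pid)
            continue
        encounters = [
            Encounter(eid, date, events)
            for eid, (date, events) in info["encounters"].items()
        ]
        out.append(PatientRecord(pid, info["sex"], info["birth"], encounters))
    out.sort(key=lambda r: r.patient_id)
    return out


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run from scratch."""

    scenario: SimScenario = field(default_factory=SimScenario)
    criteria: InclusionCriteria = field(default_factory=InclusionCriteria)
    label_spec: LabelSpec = field(default_factory=LabelSpec)
    mask_grid: tuple = DEFAULT_MASK_GRID
    model: ModelConfig = field(default_factory=ModelConfig)
    cv_folds: int = 5
    seed: int = 0
    event_table: Optional[str] = None  # ingest instead of simulate

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "scenario" in kwargs:
            sc = dict(kwargs["scenario"])
            for key in ("followup_dist", "background_codes", "age_range"):
                if key in sc and isinstance(sc[key], list):
                    sc[key] = tuple(sc[key])
            kwargs["scenario"] = SimScenario(**sc)
        if "criteria" in kwargs:
            crit = dict(kwargs["criteria"])
            if "exclusion_code_sets" in crit:
                crit["exclusion_code_sets"] = {
                    k: (list(v[0]), v[1])
                    for k, v in crit["exclusion_code_sets"].items()
                }
            kwargs["criteria"] = InclusionCriteria(**crit)
        if "label_spec" in kwargs:
            kwargs["label_spec"] = LabelSpec(**kwargs["label_spec"])
        if "model" in kwargs:
            kwargs["model"] = ModelConfig(**kwargs["model"])
        if "mask_grid" in kwargs:
            kwargs["mask_grid"] = tuple(kwargs["mask_grid"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the full flow and write all stage outputs to *out_dir*.

    Stages: simulate (or ingest) -> index detection & exclusions ->
    horizon labeling -> backward-masking grid (propensity matching re-run
    per mask length) -> cross-validated sequence model per mask length ->
    attention aggregation at the shortest mask.  Fully rerunnable from
    (config, seed) alone; the config hash is embedded in the manifest and
    the metrics table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    config.to_yaml(out / "config.yaml")

    if config.event_table:
        records = read_event_table(config.event_table)
        logger.info("ingested %d patients", len(records))
    else:
        records, truth = simulate_cohort(config.scenario)
        write_event_table(records, out / "events.csv")
        write_ground_truth(truth, out / "ground_truth.csv")
    index_dates, attrition = build_cohort(records, config.criteria)
    attrition.to_csv(out / "attrition.csv", index=False)
    entries = label_cohort(records, index_dates, config.label_spec)
    label_table(entries).to_csv(out / "labels.csv", index=False)
    by_id = {r.patient_id: r for r in records}
    masking_profile(by_id, entries, config.mask_grid).to_csv(
        out / "masking_profile.csv", index=False
    )

    metrics_rows = []
    rankings_written = False
    feature_spec = BaselineFeatureSpec(
        code_indicators=sorted(config.scenario.effects),
        index_lab_code=config.criteria.index_lab_code,
    )
    for L in config.mask_grid:
        ds = assemble_dataset(
            records, entries, L, feature_spec, seed=config.seed
        )
        ds.smd_report.to_csv(out / f"matching_mask{L}.csv", index=False)
        write_event_table([mr.record for mr in ds.records], out / f"events_mask{L}.csv")
        dictionary = build_dictionary(ds.records)
        dictionary.freeze()
        cv = cross_validate(
            retain_factory(dictionary, config.model),
            ds.records,
            ds.labels,
            k=config.cv_folds,
            seed=config.seed,
        )
        for f, a in enumerate(cv.fold_aucs):
            metrics_rows.append(
                {"mask_years": L, "fold": f, "auc": a, "config_hash": cfg_hash}
            )
        if not rankings_written:
            model = RetainClassifier(dictionary, config.model)
            model.fit(ds.records, ds.labels)
            att = []
            for rec in ds.records:
                att.extend(model.code_contributions(rec))
            importance_table(aggregate_scores(att, min_patients=10)).to_csv(
                out / "rankings.csv", index=False
            )
            rankings_written = True
    pd.DataFrame(metrics_rows).to_csv(out / "metrics.csv", index=False)
    manifest = {
        "config_hash": cfg_hash,
        "n_patients": len(records),
        "n_indexed": len(index_dates),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", out)
    return out
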