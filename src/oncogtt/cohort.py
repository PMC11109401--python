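"""Inpatient cohort model: domain types, exchange formats, inclusion filter.

One :class:`AdmissionRecord` is one inpatient stay with its demographics,
diagnoses, timestamped laboratory results, medication orders, coded
clinical/symptom events and intervention events.  Records are validated on
construction: laboratory units must equal the canonical unit for the
analyte (no silent conversion), child timestamps must fall within the stay
(a 30-day pre-admission window is allowed for baseline labs), and the
length of stay is always derived from the dates, never stored.

Two exchange formats are supported: JSON-Lines (one admission object per
line, nested child arrays) and a relational CSV directory
(admissions.csv, labs.csv, meds.csv, events.csv, interventions.csv keyed
by admission_id).
"""

from __future__ import annotations

import json
import logging
import math
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
from pydantic import (
    BaseModel,
    Field,
    ValidationError,
    field_serializer,
    field_validator,
    model_validator,
)

from . import vocab

logger = logging.getLogger(__name__)

BASELINE_WINDOW_DAYS = 30


class CohortParseError(ValueError):
    """A record failed validation; carries the offending location."""

    def __init__(self, message: str, line: int | None = None, field: str | None = None):
        loc = f" (line {line})" if line is not None else ""
        fld = f" [field: {field}]" if field else ""
        super().__init__(f"{message}{loc}{fld}")
        self.line = line
        self.field = field


class LabResult(BaseModel):
    """A single timestamped laboratory (or vital-sign) measurement."""

    analyte: str
    value: Optional[float] = None
    unit: str
    collected_at: datetime
    ref_low: Optional[float] = None
    ref_high: Optional[float] = None
    qualitative_result: Optional[Literal["positive", "negative"]] = None
    is_baseline: bool = False

    @field_validator("analyte")
    @classmethod
    def _known_analyte(cls, v: str) -> str:
        if v not in vocab.ANALYTES:
            raise ValueError(f"unknown analyte {v!r}")
        return v

    @model_validator(mode="after")
    def _check(self) -> "LabResult":
        canon = vocab.canonical_unit(self.analyte)
        if self.unit != canon:
            raise ValueError(
                f"unit {self.unit!r} for {self.analyte} is not the canonical {canon!r}"
            )
        if self.value is None and self.qualitative_result is None:
            raise ValueError(f"{self.analyte}: value or qualitative_result required")
        if self.value is not None and not math.isfinite(self.value):
            raise ValueError(f"{self.analyte}: value must be finite")
        if self.ref_low is not None and self.ref_high is not None:
            if not self.ref_low < self.ref_high:
                raise ValueError(f"{self.analyte}: ref_low must be < ref_high")
        return self

    def uln(self) -> Optional[float]:
        """Upper limit of normal: the row's ref_high, else the vocabulary default."""
        if self.ref_high is not None:
            return self.ref_high
        return vocab.default_ref_range(self.analyte)[1]

    def lln(self) -> Optional[float]:
        if self.ref_low is not None:
            return self.ref_low
        return vocab.default_ref_range(self.analyte)[0]


class MedicationOrder(BaseModel):
    drug_name: str
    drug_class: str
    is_antineoplastic: bool
    start_date: date
    stop_date: date
    route: str = "iv"

    @field_validator("drug_class")
    @classmethod
    def _known_class(cls, v: str) -> str:
        if v not in vocab.DRUG_CLASSES:
            raise ValueError(f"unknown drug class {v!r}")
        return v

    @model_validator(mode="after")
    def _check(self) -> "MedicationOrder":
        if self.stop_date < self.start_date:
            raise ValueError(f"{self.drug_name}: stop_date before start_date")
        expected = self.drug_class in vocab.ANTINEOPLASTIC_CLASSES
        if self.is_antineoplastic != expected:
            raise ValueError(
                f"{self.drug_name}: is_antineoplastic={self.is_antineoplastic} "
                f"inconsistent with class {self.drug_class!r}"
            )
        return self


class ClinicalEvent(BaseModel):
    """A coded symptom or imaging finding with optional typed attributes."""

    code: str
    onset_date: date
    attributes: dict[str, float | int | str] = Field(default_factory=dict)

    @field_validator("code")
    @classmethod
    def _known_code(cls, v: str) -> str:
        if v not in vocab.SYMPTOM_CODES:
            raise ValueError(f"unknown event code {v!r}")
        return v


class InterventionEvent(BaseModel):
    kind: str
    date: date
    due_to_toxicity: bool = False

    @field_validator("kind")
    @classmethod
    def _known_kind(cls, v: str) -> str:
        if v not in vocab.INTERVENTION_KINDS:
            raise ValueError(f"unknown intervention kind {v!r}")
        return v


class AdmissionRecord(BaseModel):
    admission_id: str
    age: int = Field(ge=0, le=120)
    sex: Literal["male", "female"]
    admit_date: date
    discharge_date: date
    tumor_type: Optional[str] = None
    tumor_stage: str = "not-staged"
    comorbidities: set[str] = Field(default_factory=set)
    prior_chemotherapy_count: int = Field(default=0, ge=0)
    prior_adr_history: bool = False
    radiotherapy: bool = False
    labs: list[LabResult] = Field(default_factory=list)
    medications: list[MedicationOrder] = Field(default_factory=list)
    events: list[ClinicalEvent] = Field(default_factory=list)
    interventions: list[InterventionEvent] = Field(default_factory=list)

    @field_serializer("comorbidities")
    def _sorted_comorbidities(self, v: set[str]) -> list[str]:
        return sorted(v)  # byte-stable serialization across processes

    @field_validator("tumor_type")
    @classmethod
    def _known_tumor(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in vocab.TUMOR_CATEGORY:
            raise ValueError(f"unknown tumor type {v!r}")
        return v

    @field_validator("tumor_stage")
    @classmethod
    def _known_stage(cls, v: str) -> str:
        if v not in vocab.TUMOR_STAGES:
            raise ValueError(f"unknown tumor stage {v!r}")
        return v

    @model_validator(mode="after")
    def _check(self) -> "AdmissionRecord":
        if self.discharge_date < self.admit_date:
            raise ValueError(f"{self.admission_id}: discharge before admission")
        lo = self.admit_date - timedelta(days=BASELINE_WINDOW_DAYS)
        hi = self.discharge_date
        for lab in self.labs:
            d = lab.collected_at.date()
            if not lo <= d <= hi:
                raise ValueError(
                    f"{self.admission_id}: lab {lab.analyte} at {d} outside "
                    f"[{lo}, {hi}]"
                )
            if d < self.admit_date and not lab.is_baseline:
                raise ValueError(
                    f"{self.admission_id}: pre-admission lab {lab.analyte} at {d} "
                    "not flagged is_baseline"
                )
        for ev in self.events:
            if not lo <= ev.onset_date <= hi:
                raise ValueError(f"{self.admission_id}: event {ev.code} outside stay")
        for iv in self.interventions:
            if not lo <= iv.date <= hi:
                raise ValueError(f"{self.admission_id}: intervention outside stay")
        return self

    @property
    def length_of_stay(self) -> int:
        """Whole days between admission and discharge (derived, never stored)."""
        return (self.discharge_date - self.admit_date).days

    @property
    def n_combined_drugs(self) -> int:
        """Number of distinct drugs ordered during the stay."""
        return len({m.drug_name for m in self.medications})

    def has_antineoplastic(self) -> bool:
        return any(m.is_antineoplastic for m in self.medications)

    def tumor_category(self) -> Optional[str]:
        if self.tumor_type is None:
            return None
        return vocab.TUMOR_CATEGORY[self.tumor_type]


Cohort = list[AdmissionRecord]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_CSV_FILES = ("admissions.csv", "labs.csv", "meds.csv", "events.csv", "interventions.csv")


def _check_unique_ids(cohort: Cohort) -> None:
    seen: set[str] = set()
    for adm in cohort:
        if adm.admission_id in seen:
            raise CohortParseError(f"duplicate admission_id {adm.admission_id!r}")
        seen.add(adm.admission_id)


def read_cohort(path: str | Path, format: Literal["jsonl", "csv-dir"] = "jsonl") -> Cohort:
    """Read a cohort file (JSON-Lines) or directory (relational CSV).

    Malformed records raise :class:`CohortParseError` naming the field and
    line; an empty input yields an empty cohort with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "jsonl":
        cohort = _read_jsonl(path)
    elif format == "csv-dir":
        cohort = _read_csv_dir(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if not cohort:
        logger.warning("cohort at %s is empty", path)
    _check_unique_ids(cohort)
    return cohort


def write_cohort(cohort: Cohort, path: str | Path,
                 format: Literal["jsonl", "csv-dir"] = "jsonl") -> list[Path]:
    """Write a cohort; ``read_cohort(write_cohort(c))`` reproduces ``c``."""
    path = Path(path)
    if format == "jsonl":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            for adm in cohort:
                fh.write(json.dumps(adm.model_dump(mode="json"), sort_keys=True) + "\n")
        return [path]
    if format == "csv-dir":
        return _write_csv_dir(cohort, path)
    raise ValueError(f"unknown format {format!r}")


def _read_jsonl(path: Path) -> Cohort:
    cohort: Cohort = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CohortParseError(f"invalid JSON: {exc}", line=lineno) from exc
            try:
                cohort.append(AdmissionRecord.model_validate(obj))
            except ValidationError as exc:
                first = exc.errors()[0]
                field = ".".join(str(p) for p in first["loc"])
                raise CohortParseError(first["msg"], line=lineno, field=field) from exc
    return cohort


def _sets_to_str(values: Iterable[str]) -> str:
    return ";".join(sorted(values))


def _write_csv_dir(cohort: Cohort, path: Path) -> list[Path]:
    path.mkdir(parents=True, exist_ok=True)
    adm_rows, lab_rows, med_rows, ev_rows, iv_rows = [], [], [], [], []
    for adm in cohort:
        adm_rows.append({
            "admission_id": adm.admission_id, "age": adm.age, "sex": adm.sex,
            "admit_date": adm.admit_date.isoformat(),
            "discharge_date": adm.discharge_date.isoformat(),
            "tumor_type": adm.tumor_type or "", "tumor_stage": adm.tumor_stage,
            "comorbidities": _sets_to_str(adm.comorbidities),
            "prior_chemotherapy_count": adm.prior_chemotherapy_count,
            "prior_adr_history": adm.prior_adr_history,
            "radiotherapy": adm.radiotherapy,
        })
        for lab in adm.labs:
            lab_rows.append({
                "admission_id": adm.admission_id, "analyte": lab.analyte,
                "value": "" if lab.value is None else repr(lab.value),
                "unit": lab.unit, "collected_at": lab.collected_at.isoformat(),
                "ref_low": "" if lab.ref_low is None else repr(lab.ref_low),
                "ref_high": "" if lab.ref_high is None else repr(lab.ref_high),
                "qualitative_result": lab.qualitative_result or "",
                "is_baseline": lab.is_baseline,
            })
        for med in adm.medications:
            med_rows.append({
                "admission_id": adm.admission_id, "drug_name": med.drug_name,
                "drug_class": med.drug_class,
                "is_antineoplastic": med.is_antineoplastic,
                "start_date": med.start_date.isoformat(),
                "stop_date": med.stop_date.isoformat(), "route": med.route,
            })
        for ev in adm.events:
            ev_rows.append({
                "admission_id": adm.admission_id, "code": ev.code,
                "onset_date": ev.onset_date.isoformat(),
                "attributes": json.dumps(ev.attributes, sort_keys=True),
            })
        for iv in adm.interventions:
            iv_rows.append({
                "admission_id": adm.admission_id, "kind": iv.kind,
                "date": iv.date.isoformat(), "due_to_toxicity": iv.due_to_toxicity,
            })
    frames = {
        "admissions.csv": pd.DataFrame(adm_rows, columns=[
            "admission_id", "age", "sex", "admit_date", "discharge_date",
            "tumor_type", "tumor_stage", "comorbidities",
            "prior_chemotherapy_count", "prior_adr_history", "radiotherapy"]),
        "labs.csv": pd.DataFrame(lab_rows, columns=[
            "admission_id", "analyte", "value", "unit", "collected_at",
            "ref_low", "ref_high", "qualitative_result", "is_baseline"]),
        "meds.csv": pd.DataFrame(med_rows, columns=[
            "admission_id", "drug_name", "drug_class", "is_antineoplastic",
            "start_date", "stop_date", "route"]),
        "events.csv": pd.DataFrame(ev_rows, columns=[
            "admission_id", "code", "onset_date", "attributes"]),
        "interventions.csv": pd.DataFrame(iv_rows, columns=[
            "admission_id", "kind", "date", "due_to_toxicity"]),
    }
    written = []
    for name, frame in frames.items():
        out = path / name
        frame.to_csv(out, index=False)
        written.append(out)
    return written


def _opt_float(v: str) -> float | None:
    return None if v == "" else float(v)


def _read_csv_dir(path: Path) -> Cohort:
    if not path.is_dir():
        raise CohortParseError(f"{path} is not a directory")
    for name in _CSV_FILES:
        if not (path / name).exists():
            raise CohortParseError(f"missing table {name} in {path}")
    tables = {
        name: pd.read_csv(path / name, dtype=str, keep_default_na=False)
        for name in _CSV_FILES
    }
    children: dict[str, dict[str, list]] = {
        k: {} for k in ("labs", "meds", "events", "interventions")
    }
    for _, row in tables["labs.csv"].iterrows():
        children["labs"].setdefault(row["admission_id"], []).append(dict(
            analyte=row["analyte"], value=_opt_float(row["value"]),
            unit=row["unit"], collected_at=row["collected_at"],
            ref_low=_opt_float(row["ref_low"]), ref_high=_opt_float(row["ref_high"]),
            qualitative_result=row["qualitative_result"] or None,
            is_baseline=row["is_baseline"] == "True",
        ))
    for _, row in tables["meds.csv"].iterrows():
        children["meds"].setdefault(row["admission_id"], []).append(dict(
            drug_name=row["drug_name"], drug_class=row["drug_class"],
            is_antineoplastic=row["is_antineoplastic"] == "True",
            start_date=row["start_date"], stop_date=row["stop_date"],
            route=row["route"],
        ))
    for _, row in tables["events.csv"].iterrows():
        children["events"].setdefault(row["admission_id"], []).append(dict(
            code=row["code"], onset_date=row["onset_date"],
            attributes=json.loads(row["attributes"]) if row["attributes"] else {},
        ))
    for _, row in tables["interventions.csv"].iterrows():
        children["interventions"].setdefault(row["admission_id"], []).append(dict(
            kind=row["kind"], date=row["date"],
            due_to_toxicity=row["due_to_toxicity"] == "True",
        ))
    cohort: Cohort = []
    for lineno, (_, row) in enumerate(tables["admissions.csv"].iterrows(), start=2):
        aid = row["admission_id"]
        obj = dict(
            admission_id=aid, age=int(row["age"]), sex=row["sex"],
            admit_date=row["admit_date"], discharge_date=row["discharge_date"],
            tumor_type=row["tumor_type"] or None, tumor_stage=row["tumor_stage"],
            comorbidities=set(filter(None, row["comorbidities"].split(";"))),
            prior_chemotherapy_count=int(row["prior_chemotherapy_count"]),
            prior_adr_history=row["prior_adr_history"] == "True",
            radiotherapy=row["radiotherapy"] == "True",
            labs=children["labs"].get(aid, []),
            medications=children["meds"].get(aid, []),
            events=children["events"].get(aid, []),
            interventions=children["interventions"].get(aid, []),
        )
        try:
            cohort.append(AdmissionRecord.model_validate(obj))
        except ValidationError as exc:
            first = exc.errors()[0]
            field = ".".join(str(p) for p in first["loc"])
            raise CohortParseError(first["msg"], line=lineno, field=field) from exc
    return cohort


# ---------------------------------------------------------------------------
# Inclusion / exclusion
# ---------------------------------------------------------------------------

class ExclusionReason:
    AGE = "age-under-18"
    LOS = "length-of-stay-out-of-window"
    NO_ANTINEOPLASTIC = "no-antineoplastic-treatment"
    NO_MALIGNANCY = "no-malignant-tumor-diagnosis"


def apply_inclusion_criteria(
    cohort: Cohort,
    los_min: int = 2,
    los_max: int = 30,
    strict_los: bool = False,
) -> tuple[Cohort, list[tuple[AdmissionRecord, list[str]]]]:
    """Partition a cohort into study-eligible and excluded admissions.

    Eligible: malignant-tumor diagnosis, age >= 18 years, length of stay
    within [los_min, los_max] days, and at least one antineoplastic
    medication order.  With ``strict_los=True`` the lower bound is
    exclusive (stay strictly longer than ``los_min`` days).  The filter is
    total and idempotent; every excluded record carries machine-readable
    reasons.
    """
    included: Cohort = []
    excluded: list[tuple[AdmissionRecord, list[str]]] = []
    for adm in cohort:
        reasons = []
        if adm.tumor_type is None:
            reasons.append(ExclusionReason.NO_MALIGNANCY)
        if adm.age < 18:
            reasons.append(ExclusionReason.AGE)
        los = adm.length_of_stay
        low_ok = los > los_min if strict_los else los >= los_min
        if not (low_ok and los <= los_max):
            reasons.append(ExclusionReason.LOS)
        if not adm.has_antineoplastic():
            reasons.append(ExclusionReason.NO_ANTINEOPLASTIC)
        if reasons:
            excluded.append((adm, reasons))
        else:
            included.append(adm)
    return included, excluded
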