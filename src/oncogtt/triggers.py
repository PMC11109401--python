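"""Trigger registry and screening engine.

The registry declares 37 screening rules ("triggers") over an inpatient
admission, organised in four modules: 22 laboratory indices (L1-L22), 10
clinical symptoms (S1-S10), 3 antidotes (T1-T3) and 2 interventions
(M1-M2).  Each trigger is a declarative :class:`PredicateSpec`; the
evaluator is a pure function of (definition, admission) and emits at most
one :class:`TriggerHit` per trigger per admission, dated at the earliest
qualifying evidence.

Numeric comparisons are strict (``<`` / ``>``) exactly as the rules are
written; a value exactly at a cutoff never fires.  Laboratory predicates
that reference the ULN (upper limit of normal) resolve it from the lab
row's own reference range, falling back to the analyte vocabulary default.
"""

from __future__ import annotations

import logging
from datetime import date, datetime
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .cohort import AdmissionRecord, Cohort, LabResult

logger = logging.getLogger(__name__)

TriggerModule = Literal["laboratory", "symptom", "antidote", "intervention"]

#: Canonical registry order (admission order, then this order, sorts hits).
TRIGGER_ORDER: list[str] = (
    [f"L{i}" for i in range(1, 23)]
    + [f"S{i}" for i in range(1, 11)]
    + ["T1", "T2", "T3", "M1", "M2"]
)


class PredicateSpec(BaseModel):
    """A declarative predicate: a variant name plus variant-specific parameters.

    Variants
    --------
    lab-threshold
        One analyte compared to a cutoff.  Optional ``sex_cutoffs`` (maps
        sex to cutoff), ``forbidden_comorbidities`` (predicate vetoed when
        the admission carries any of them).
    lab-any
        Disjunctive normal form over lab conditions: ``groups`` is a list
        of condition lists; the predicate fires when every condition of at
        least one group is satisfied by some lab.  Conditions support
        ``uln_multiplier`` (cutoff = multiplier x row ULN), ``qualitative``
        and morning-hour windows (``hour_min``/``hour_max``).
    hepatotoxicity
        ALT or D-BIL above 2x ULN, or AST+ALP+TBIL simultaneously (same
        collection date) above their ULN with at least one above 2x ULN.
    creatinine-renal
        Creatinine above 1.5x ULN or above 1.5x the admission baseline
        (earliest creatinine, pre-admission baselines preferred), or GFR
        below 60.
    bp-new-onset
        A blood-pressure reading above 140/90 preceded by an in-admission
        reading within the normal range.
    symptom-any
        Any coded event among ``codes``.
    symptom-attr
        A coded event whose required numeric attribute crosses a cutoff;
        a missing attribute logs a warning and does not fire.
    diarrhea-composite
        Diarrhea with >4 stools/day, or diarrhea accompanied by a
        companion code (bellyache, hemoproctia, mucous stool, fever).
    med-co-occurrence
        Orders of two drug classes with date spans overlapping on at
        least one calendar day.
    med-present
        Any order of a drug class; optional tumor-type exclusions.
    intervention
        An intervention event among ``kinds``; optionally only when
        flagged as motivated by toxicity.
    """

    variant: str
    params: dict = Field(default_factory=dict)


class TriggerDefinition(BaseModel):
    trigger_id: str
    module: TriggerModule
    name: str
    associated_ade: str
    predicate: PredicateSpec
    enabled: bool = True


class TriggerHit(BaseModel):
    trigger_id: str
    admission_id: str
    evidence: list[str] = Field(min_length=1)
    hit_date: date


# ---------------------------------------------------------------------------
# Built-in registry
# ---------------------------------------------------------------------------

def _lab(analyte: str, direction: str, cutoff: float, **extra) -> PredicateSpec:
    return PredicateSpec(variant="lab-threshold",
                         params={"analyte": analyte, "direction": direction,
                                 "cutoff": cutoff, **extra})


def _cond(analyte: str, direction: str, cutoff: float | None = None, **extra) -> dict:
    c = {"analyte": analyte, "direction": direction, **extra}
    if cutoff is not None:
        c["cutoff"] = cutoff
    return c


def builtin_registry() -> list[TriggerDefinition]:
    """The default 37-trigger registry (22 laboratory, 10 symptom, 3 antidote,
    2 intervention)."""
    defs = [
        TriggerDefinition(
            trigger_id="L1", module="laboratory",
            name="Hemoglobin < 100 g/L", associated_ade="anemia",
            predicate=_lab("HGB", "<", 100.0)),
        TriggerDefinition(
            trigger_id="L2", module="laboratory",
            name="Platelets < 100 x10^9/L", associated_ade="thrombocytopenia",
            predicate=_lab("PLT", "<", 100.0)),
        TriggerDefinition(
            trigger_id="L3", module="laboratory",
            name="Neutrophils < 1.8 x10^9/L", associated_ade="neutropenia",
            predicate=_lab("NEUT", "<", 1.8)),
        TriggerDefinition(
            trigger_id="L4", module="laboratory",
            name="WBC < 4.0 x10^9/L", associated_ade="leukopenia",
            predicate=_lab("WBC", "<", 4.0)),
        TriggerDefinition(
            trigger_id="L5", module="laboratory",
            name="ALT or D-BIL > 2x ULN, or AST+ALP+TBIL simultaneously "
                 "elevated with at least one > 2x ULN",
            associated_ade="hepatic-injury",
            predicate=PredicateSpec(variant="hepatotoxicity", params={})),
        TriggerDefinition(
            trigger_id="L6", module="laboratory",
            name="Creatinine > 1.5x ULN or 1.5x baseline, and/or GFR < 60",
            associated_ade="renal-injury",
            predicate=PredicateSpec(
                variant="creatinine-renal",
                params={"uln_multiplier": 1.5, "baseline_multiplier": 1.5,
                        "gfr_cutoff": 60.0})),
        TriggerDefinition(
            trigger_id="L7", module="laboratory",
            name="Blood pressure > 140/90 mmHg with previous values normal",
            associated_ade="hypertension",
            predicate=PredicateSpec(
                variant="bp-new-onset",
                params={"sbp_cutoff": 140.0, "dbp_cutoff": 90.0})),
        TriggerDefinition(
            trigger_id="L8", module="laboratory",
            name="Fasting glucose > 8.9 mmol/L (not type 2 diabetes)",
            associated_ade="hyperglycemia",
            predicate=_lab("GLU_FASTING", ">", 8.9,
                           forbidden_comorbidities=["diabetes-mellitus"])),
        TriggerDefinition(
            trigger_id="L9", module="laboratory",
            name="Fasting glucose < 3.9 mmol/L (not type 2 diabetes)",
            associated_ade="hypoglycemia",
            predicate=_lab("GLU_FASTING", "<", 3.9,
                           forbidden_comorbidities=["diabetes-mellitus"])),
        TriggerDefinition(
            trigger_id="L10", module="laboratory",
            name="Potassium > 5.3 mmol/L", associated_ade="hyperkalemia",
            predicate=_lab("K", ">", 5.3)),
        TriggerDefinition(
            trigger_id="L11", module="laboratory",
            name="Potassium < 3.5 mmol/L", associated_ade="hypokalemia",
            predicate=_lab("K", "<", 3.5)),
        TriggerDefinition(
            trigger_id="L12", module="laboratory",
            name="Calcium > 2.52 mmol/L", associated_ade="hypercalcemia",
            predicate=_lab("CA", ">", 2.52)),
        TriggerDefinition(
            trigger_id="L13", module="laboratory",
            name="Calcium < 2.11 mmol/L", associated_ade="hypocalcemia",
            predicate=_lab("CA", "<", 2.11)),
        TriggerDefinition(
            trigger_id="L14", module="laboratory",
            name="Uric acid: female > 360, male > 420 umol/L",
            associated_ade="hyperuricemia",
            predicate=_lab("UA", ">", 420.0,
                           sex_cutoffs={"female": 360.0, "male": 420.0})),
        TriggerDefinition(
            trigger_id="L15", module="laboratory",
            name="Proteinuria: qualitative positive or > 150 mg/24h",
            associated_ade="proteinuria",
            predicate=PredicateSpec(variant="lab-any", params={"groups": [
                [_cond("UPRO_QUAL", "qual", qualitative="positive")],
                [_cond("UPRO_24H", ">", 150.0)],
            ]})),
        TriggerDefinition(
            trigger_id="L16", module="laboratory",
            name="TnI > 0.034 ng/mL, or CK-MB > 25 U/L with CK > 200 U/L",
            associated_ade="myocardial-injury",
            predicate=PredicateSpec(variant="lab-any", params={"groups": [
                [_cond("TNI", ">", 0.034)],
                [_cond("CKMB", ">", 25.0), _cond("CK", ">", 200.0)],
            ]})),
        TriggerDefinition(
            trigger_id="L17", module="laboratory",
            name="BNP > 400 pg/mL or NT-proBNP > 2000 pg/mL",
            associated_ade="cardiac-failure",
            predicate=PredicateSpec(variant="lab-any", params={"groups": [
                [_cond("BNP", ">", 400.0)],
                [_cond("NTPROBNP", ">", 2000.0)],
            ]})),
        TriggerDefinition(
            trigger_id="L18", module="laboratory",
            name="TSH > 4.2 uIU/mL with FT4 < 0.81 ng/dL",
            associated_ade="hypothyroidism",
            predicate=PredicateSpec(variant="lab-any", params={"groups": [
                [_cond("TSH", ">", 4.2), _cond("FT4", "<", 0.81)],
            ]})),
        TriggerDefinition(
            trigger_id="L19", module="laboratory",
            name="TSH < 0.27 uIU/mL with FT4 > 1.89 ng/dL",
            associated_ade="hyperthyroidism",
            predicate=PredicateSpec(variant="lab-any", params={"groups": [
                [_cond("TSH", "<", 0.27), _cond("FT4", ">", 1.89)],
            ]})),
        TriggerDefinition(
            trigger_id="L20", module="laboratory",
            name="CT: pulmonary interstitial changes (ground glass or patch nodules)",
            associated_ade="lung-injury",
            predicate=PredicateSpec(variant="symptom-any", params={
                "codes": ["ct-ground-glass", "ct-patchy-nodule"]})),
        TriggerDefinition(
            trigger_id="L21", module="laboratory",
            name="TSH < 0.27 uIU/mL with FT4 < 0.81 ng/dL",
            associated_ade="secondary-hypothyroidism",
            predicate=PredicateSpec(variant="lab-any", params={"groups": [
                [_cond("TSH", "<", 0.27), _cond("FT4", "<", 0.81)],
            ]})),
        TriggerDefinition(
            trigger_id="L22", module="laboratory",
            name="Morning ACTH < 7.2 pg/mL with morning cortisol < 6.02 ug/dL",
            associated_ade="adrenocortical-hypofunction",
            predicate=PredicateSpec(variant="lab-any", params={"groups": [
                [_cond("ACTH", "<", 7.2, hour_min=7, hour_max=10),
                 _cond("COR", "<", 6.02, hour_min=6, hour_max=10)],
            ]})),
        TriggerDefinition(
            trigger_id="S1", module="symptom",
            name="Fever (temperature > 38.2 C)", associated_ade="fever",
            predicate=PredicateSpec(variant="symptom-attr", params={
                "code": "fever", "attribute": "temperature_c",
                "direction": ">", "cutoff": 38.2})),
        TriggerDefinition(
            trigger_id="S2", module="symptom",
            name="Oral mucositis", associated_ade="oral-mucositis",
            predicate=PredicateSpec(variant="symptom-any",
                                    params={"codes": ["oral-mucositis"]})),
        TriggerDefinition(
            trigger_id="S3", module="symptom",
            name="Diarrhea (>4 stools/day) and/or bellyache, hemoproctia, "
                 "mucous stool, fever",
            associated_ade="diarrhea-colonitis",
            predicate=PredicateSpec(variant="diarrhea-composite", params={
                "stools_cutoff": 4,
                "companions": ["bellyache", "hemoproctia", "mucous-stool", "fever"]})),
        TriggerDefinition(
            trigger_id="S4", module="symptom",
            name="Nausea and/or vomiting", associated_ade="nausea-vomiting",
            predicate=PredicateSpec(variant="symptom-any",
                                    params={"codes": ["nausea", "vomiting"]})),
        TriggerDefinition(
            trigger_id="S5", module="symptom",
            name="Constipation", associated_ade="constipation",
            predicate=PredicateSpec(variant="symptom-any",
                                    params={"codes": ["constipation"]})),
        TriggerDefinition(
            trigger_id="S6", module="symptom",
            name="Erythema, numbness, desquamation of hands and feet",
            associated_ade="hand-foot-syndrome",
            predicate=PredicateSpec(variant="symptom-any",
                                    params={"codes": ["hand-foot-erythema"]})),
        TriggerDefinition(
            trigger_id="S7", module="symptom",
            name="Limb distal paresthesia, pain, numbness, hypoesthesia",
            associated_ade="peripheral-neuritis",
            predicate=PredicateSpec(variant="symptom-any",
                                    params={"codes": ["distal-paresthesia"]})),
        TriggerDefinition(
            trigger_id="S8", module="symptom",
            name="Rash (maculopapule, pustular eruption) / itching",
            associated_ade="rash",
            predicate=PredicateSpec(variant="symptom-any",
                                    params={"codes": ["rash", "pruritus"]})),
        TriggerDefinition(
            trigger_id="S9", module="symptom",
            name="Local skin pain, burning, erythema, ulcer, necrosis",
            associated_ade="extravasation",
            predicate=PredicateSpec(variant="symptom-any",
                                    params={"codes": ["extravasation-sign"]})),
        TriggerDefinition(
            trigger_id="S10", module="symptom",
            name="Nodular, patchy, bright/dark red capillary hyperplasia",
            associated_ade="capillary-hyperplasia",
            predicate=PredicateSpec(variant="symptom-any",
                                    params={"codes": ["capillary-hyperplasia"]})),
        TriggerDefinition(
            trigger_id="T1", module="antidote",
            name="Simultaneous use of glucocorticoids and antihistamines",
            associated_ade="drug-allergy",
            predicate=PredicateSpec(variant="med-co-occurrence", params={
                "class_a": "glucocorticoid", "class_b": "antihistamine",
                "window_days": 0})),
        TriggerDefinition(
            trigger_id="T2", module="antidote",
            name="Anticoagulant drug", associated_ade="thrombosis",
            predicate=PredicateSpec(variant="med-present",
                                    params={"drug_class": "anticoagulant"})),
        TriggerDefinition(
            trigger_id="T3", module="antidote",
            name="Calcium leucovorin (except colorectal and gastric cancer)",
            associated_ade="methotrexate-toxicity",
            predicate=PredicateSpec(variant="med-present", params={
                "drug_class": "leucovorin",
                "forbidden_tumor_types": ["colorectal", "gastric"]})),
        TriggerDefinition(
            trigger_id="M1", module="intervention",
            name="Unexpected emergency, rescue, transfer to the ICU",
            associated_ade="icu-care-required",
            predicate=PredicateSpec(variant="intervention", params={
                "kinds": ["icu-transfer", "emergency-rescue"],
                "require_toxicity": False})),
        TriggerDefinition(
            trigger_id="M2", module="intervention",
            name="Abrupt adjustment of antitumor therapy due to toxicity",
            associated_ade="regimen-adjustment",
            predicate=PredicateSpec(variant="intervention", params={
                "kinds": ["drug-withdrawal", "dose-reduction", "regimen-change"],
                "require_toxicity": True})),
    ]
    assert [d.trigger_id for d in defs] == TRIGGER_ORDER
    return defs


# ---------------------------------------------------------------------------
# Predicate evaluation
# ---------------------------------------------------------------------------

def _cmp(value: float, direction: str, cutoff: float) -> bool:
    if direction == "<":
        return value < cutoff
    if direction == ">":
        return value > cutoff
    raise ValueError(f"unknown direction {direction!r}")


def _lab_ref(lab: LabResult) -> str:
    return f"lab:{lab.analyte}:{lab.collected_at.isoformat()}"


def _labs_of(adm: AdmissionRecord, analyte: str) -> list[LabResult]:
    return sorted((l for l in adm.labs if l.analyte == analyte),
                  key=lambda l: l.collected_at)


def _match_condition(adm: AdmissionRecord, cond: dict) -> Optional[LabResult]:
    """Earliest lab satisfying one condition dict, or None."""
    for lab in _labs_of(adm, cond["analyte"]):
        if "hour_min" in cond:
            if not cond["hour_min"] <= lab.collected_at.hour <= cond["hour_max"]:
                continue
        if cond["direction"] == "qual":
            if lab.qualitative_result == cond["qualitative"]:
                return lab
            continue
        if lab.value is None:
            continue
        cutoff = cond.get("cutoff")
        if "uln_multiplier" in cond:
            uln = lab.uln()
            if uln is None:
                continue
            cutoff = cond["uln_multiplier"] * uln
        if _cmp(lab.value, cond["direction"], cutoff):
            return lab
    return None


def _eval_lab_threshold(defn: TriggerDefinition, adm: AdmissionRecord):
    p = defn.predicate.params
    for como in p.get("forbidden_comorbidities", []):
        if como in adm.comorbidities:
            return None
    cutoff = p["cutoff"]
    if "sex_cutoffs" in p:
        cutoff = p["sex_cutoffs"][adm.sex]
    for lab in _labs_of(adm, p["analyte"]):
        if lab.value is not None and _cmp(lab.value, p["direction"], cutoff):
            return [lab], lab.collected_at.date()
    return None


def _eval_lab_any(defn: TriggerDefinition, adm: AdmissionRecord):
    best: Optional[tuple[list[LabResult], date]] = None
    for group in defn.predicate.params["groups"]:
        matches = [_match_condition(adm, cond) for cond in group]
        if any(m is None for m in matches):
            continue
        gdate = max(m.collected_at.date() for m in matches)
        if best is None or gdate < best[1]:
            best = (matches, gdate)
    return best


def _eval_hepatotoxicity(defn: TriggerDefinition, adm: AdmissionRecord):
    best: Optional[tuple[list[LabResult], date]] = None
    for analyte in ("ALT", "DBIL"):
        for lab in _labs_of(adm, analyte):
            uln = lab.uln()
            if lab.value is not None and uln and lab.value > 2 * uln:
                d = lab.collected_at.date()
                if best is None or d < best[1]:
                    best = ([lab], d)
                break
    # AST, ALP and TBIL all above ULN on the same collection date,
    # with at least one above 2x ULN.
    by_date: dict[date, dict[str, LabResult]] = {}
    for analyte in ("AST", "ALP", "TBIL"):
        for lab in _labs_of(adm, analyte):
            by_date.setdefault(lab.collected_at.date(), {})[analyte] = lab
    for d in sorted(by_date):
        trio = by_date[d]
        if len(trio) < 3:
            continue
        if all(l.value is not None and l.uln() and l.value > l.uln()
               for l in trio.values()) and \
           any(l.value > 2 * l.uln() for l in trio.values()):
            if best is None or d < best[1]:
                best = (list(trio.values()), d)
            break
    return best


def _eval_creatinine_renal(defn: TriggerDefinition, adm: AdmissionRecord):
    p = defn.predicate.params
    best: Optional[tuple[list[LabResult], date]] = None
    creas = _labs_of(adm, "CREA")
    baseline = creas[0] if creas else None
    for lab in creas:
        uln = lab.uln()
        hit = False
        if lab.value is not None and uln and lab.value > p["uln_multiplier"] * uln:
            hit = True
        if (baseline is not None and lab is not baseline
                and lab.value is not None and baseline.value
                and lab.value > p["baseline_multiplier"] * baseline.value):
            hit = True
        if hit:
            best = ([lab], lab.collected_at.date())
            break
    for lab in _labs_of(adm, "GFR"):
        if lab.value is not None and lab.value < p["gfr_cutoff"]:
            d = lab.collected_at.date()
            if best is None or d < best[1]:
                best = ([lab], d)
            break
    return best


def _eval_bp_new_onset(defn: TriggerDefinition, adm: AdmissionRecord):
    p = defn.predicate.params
    # pair SBP/DBP rows sharing a collection timestamp into readings
    readings: dict[datetime, dict[str, LabResult]] = {}
    for analyte in ("SBP", "DBP"):
        for lab in _labs_of(adm, analyte):
            readings.setdefault(lab.collected_at, {})[analyte] = lab
    seen_normal = False
    for ts in sorted(readings):
        r = readings[ts]
        sbp = r.get("SBP").value if "SBP" in r else None
        dbp = r.get("DBP").value if "DBP" in r else None
        high = (sbp is not None and sbp > p["sbp_cutoff"]) or \
               (dbp is not None and dbp > p["dbp_cutoff"])
        normal = (sbp is not None and sbp <= p["sbp_cutoff"]) and \
                 (dbp is not None and dbp <= p["dbp_cutoff"])
        if high and seen_normal:
            return list(r.values()), ts.date()
        if normal:
            seen_normal = True
    return None


def _eval_symptom_any(defn: TriggerDefinition, adm: AdmissionRecord):
    codes = set(defn.predicate.params["codes"])
    hits = sorted((e for e in adm.events if e.code in codes),
                  key=lambda e: e.onset_date)
    if hits:
        ev = hits[0]
        return [f"event:{ev.code}:{ev.onset_date.isoformat()}"], ev.onset_date
    return None


def _eval_symptom_attr(defn: TriggerDefinition, adm: AdmissionRecord):
    p = defn.predicate.params
    matched = None
    for ev in sorted((e for e in adm.events if e.code == p["code"]),
                     key=lambda e: e.onset_date):
        if p["attribute"] not in ev.attributes:
            logger.warning(
                "%s: event %s on %s lacks attribute %s; trigger %s not evaluated "
                "on this event", adm.admission_id, ev.code, ev.onset_date,
                p["attribute"], defn.trigger_id)
            continue
        if _cmp(float(ev.attributes[p["attribute"]]), p["direction"], p["cutoff"]):
            matched = ev
            break
    if matched is None:
        return None
    return ([f"event:{matched.code}:{matched.onset_date.isoformat()}"],
            matched.onset_date)


def _eval_diarrhea_composite(defn: TriggerDefinition, adm: AdmissionRecord):
    p = defn.predicate.params
    diarrheas = sorted((e for e in adm.events if e.code == "diarrhea"),
                       key=lambda e: e.onset_date)
    if not diarrheas:
        return None
    companions = sorted((e for e in adm.events if e.code in set(p["companions"])),
                        key=lambda e: e.onset_date)
    best: Optional[tuple[list[str], date]] = None
    for ev in diarrheas:
        stools = ev.attributes.get("stools_per_day")
        if stools is not None and float(stools) > p["stools_cutoff"]:
            best = ([f"event:diarrhea:{ev.onset_date.isoformat()}"], ev.onset_date)
            break
    if companions:
        ev, comp = diarrheas[0], companions[0]
        d = max(ev.onset_date, comp.onset_date)
        if best is None or d < best[1]:
            best = ([f"event:diarrhea:{ev.onset_date.isoformat()}",
                     f"event:{comp.code}:{comp.onset_date.isoformat()}"], d)
    return best


def _eval_med_co_occurrence(defn: TriggerDefinition, adm: AdmissionRecord):
    p = defn.predicate.params
    window = p.get("window_days", 0)
    best: Optional[tuple[list[str], date]] = None
    meds_a = [m for m in adm.medications if m.drug_class == p["class_a"]]
    meds_b = [m for m in adm.medications if m.drug_class == p["class_b"]]
    for a in meds_a:
        for b in meds_b:
            # overlap of [start, stop] spans widened by the window
            lo = max(a.start_date, b.start_date)
            hi = min(b.stop_date, a.stop_date)
            if (lo - hi).days <= window:
                d = lo
                if best is None or d < best[1]:
                    best = ([f"med:{a.drug_name}", f"med:{b.drug_name}"], d)
    return best


def _eval_med_present(defn: TriggerDefinition, adm: AdmissionRecord):
    p = defn.predicate.params
    if adm.tumor_type in set(p.get("forbidden_tumor_types", [])):
        return None
    meds = sorted((m for m in adm.medications if m.drug_class == p["drug_class"]),
                  key=lambda m: m.start_date)
    if meds:
        return [f"med:{meds[0].drug_name}"], meds[0].start_date
    return None


def _eval_intervention(defn: TriggerDefinition, adm: AdmissionRecord):
    p = defn.predicate.params
    kinds = set(p["kinds"])
    for iv in sorted(adm.interventions, key=lambda i: i.date):
        if iv.kind not in kinds:
            continue
        if p.get("require_toxicity") and not iv.due_to_toxicity:
            continue
        return [f"intervention:{iv.kind}:{iv.date.isoformat()}"], iv.date
    return None


_EVALUATORS = {
    "lab-threshold": _eval_lab_threshold,
    "lab-any": _eval_lab_any,
    "hepatotoxicity": _eval_hepatotoxicity,
    "creatinine-renal": _eval_creatinine_renal,
    "bp-new-onset": _eval_bp_new_onset,
    "symptom-any": _eval_symptom_any,
    "symptom-attr": _eval_symptom_attr,
    "diarrhea-composite": _eval_diarrhea_composite,
    "med-co-occurrence": _eval_med_co_occurrence,
    "med-present": _eval_med_present,
    "intervention": _eval_intervention,
}


def evaluate_trigger(defn: TriggerDefinition, adm: AdmissionRecord) -> Optional[TriggerHit]:
    """Evaluate one trigger on one admission.

    Pure function of its inputs: returns a :class:`TriggerHit` citing the
    earliest qualifying evidence, or None.
    """
    if not defn.enabled:
        return None
    result = _EVALUATORS[defn.predicate.variant](defn, adm)
    if result is None:
        return None
    evidence, hit_date = result
    refs = [_lab_ref(e) if isinstance(e, LabResult) else e for e in evidence]
    return TriggerHit(trigger_id=defn.trigger_id, admission_id=adm.admission_id,
                      evidence=refs, hit_date=hit_date)


def screen_cohort(cohort: Cohort, registry: list[TriggerDefinition] | None = None
                  ) -> list[TriggerHit]:
    """Screen every admission against every enabled trigger.

    Deterministic output order: admission order, then registry trigger order.
    At most one hit per (trigger, admission) pair.
    """
    if registry is None:
        registry = builtin_registry()
    hits: list[TriggerHit] = []
    for adm in cohort:
        for defn in registry:
            hit = evaluate_trigger(defn, adm)
            if hit is not None:
                hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Registry / hits serialization
# ---------------------------------------------------------------------------

def save_registry(registry: list[TriggerDefinition], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump([d.model_dump() for d in registry], fh, sort_keys=False)
    return path


def load_registry(path: str | Path) -> list[TriggerDefinition]:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"registry file {path} must contain a list of triggers")
    regs = [TriggerDefinition.model_validate(item) for item in raw]
    ids = [d.trigger_id for d in regs]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate trigger_id in registry")
    return regs


def write_hits_csv(hits: list[TriggerHit], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [{
        "admission_id": h.admission_id, "trigger_id": h.trigger_id,
        "hit_date": h.hit_date.isoformat(),
        "evidence_type": h.evidence[0].split(":", 1)[0],
        "evidence_ref": "|".join(h.evidence),
    } for h in hits]
    pd.DataFrame(rows, columns=["admission_id", "trigger_id", "hit_date",
                                "evidence_type", "evidence_ref"]).to_csv(path, index=False)
    return path
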