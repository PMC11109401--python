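"""Adjudication: trigger hits + reviewer annotations -> deduplicated ADE records.

A fired trigger is only a clue; a reviewer decides whether an adverse drug
event (ADE) actually occurred, names it, attributes suspected drugs and
answers the causality questions.  This module turns those annotations into
:class:`ADERecord` candidates, auto-grades the four hematology analytes
against CTCAE v5.0 value bands, assesses causality with an explicit
Karch-Lasagna decision table (shipped as data so sites can amend it),
merges candidates identified by more than one trigger, classifies
seriousness, and applies the causality inclusion filter (only certain /
probable / possible events are counted).
"""

from __future__ import annotations

from datetime import date
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import vocab
from .cohort import AdmissionRecord, Cohort
from .triggers import TRIGGER_ORDER, TriggerHit

Causality = Literal["certain", "probable", "possible", "conditional", "doubtful"]

#: Causality categories retained by the study inclusion rule.
INCLUDED_CAUSALITY = {"certain", "probable", "possible"}

#: Regulatory seriousness criteria (any one makes the event serious).
SAE_CRITERIA = {
    "hospitalization", "disability", "congenital-anomaly",
    "intervention-required", "life-threatening", "death", "other-serious",
}


class CausalityAnswers(BaseModel):
    """Answers to the Karch-Lasagna causality questions."""

    temporal_sequence: bool
    known_reaction_pattern: bool
    dechallenge_improvement: Literal["yes", "no", "not-done"]
    rechallenge_recurrence: Literal["yes", "no", "not-done"]
    alternative_explanation: bool


#: Ordered decision table: the first row whose conditions all match decides
#: the category.  A missing key is a wildcard.  Total over all 72 answer
#: combinations by construction (the last row is unconditional).
CAUSALITY_RULES: list[tuple[dict, str]] = [
    ({"temporal_sequence": False}, "doubtful"),
    ({"known_reaction_pattern": False, "alternative_explanation": True}, "doubtful"),
    ({"known_reaction_pattern": False}, "conditional"),
    ({"alternative_explanation": True}, "possible"),
    ({"dechallenge_improvement": "yes", "rechallenge_recurrence": "yes"}, "certain"),
    ({"dechallenge_improvement": "yes"}, "probable"),
    ({}, "possible"),
]


def assess_causality(answers: CausalityAnswers) -> Causality:
    """Map causality answers to a category via the decision table.

    Total and deterministic: every combination of answers yields exactly
    one of certain / probable / possible / conditional / doubtful.
    """
    data = answers.model_dump()
    for conditions, category in CAUSALITY_RULES:
        if all(data[k] == v for k, v in conditions.items()):
            return category  # type: ignore[return-value]
    raise AssertionError("decision table is not total")  # pragma: no cover


# ---------------------------------------------------------------------------
# CTCAE v5.0 laboratory grading (hematology analytes)
# ---------------------------------------------------------------------------

NOT_GRADED = "not-graded"

#: value-band lower edges for grades 1..(n-1); values below the last edge get
#: the final grade.  Grade 1 additionally requires value < LLN.
_CTCAE_BANDS: dict[str, tuple[list[float], int]] = {
    # (descending band edges, grade when below all edges)
    "HGB": ([100.0, 80.0], 3),   # anemia: <LLN-100 / <100-80 / <80
    "WBC": ([3.0, 2.0, 1.0], 4),
    "NEUT": ([1.5, 1.0, 0.5], 4),
    "PLT": ([75.0, 50.0, 25.0], 4),
}

CTCAE_AUTO_ANALYTES = set(_CTCAE_BANDS)

#: analyte -> the ADE term its CTCAE bands grade
CTCAE_ANALYTE_TERM = {
    "HGB": "anemia", "WBC": "leukopenia", "NEUT": "neutropenia",
    "PLT": "thrombocytopenia",
}


def grade_lab_ctcae(analyte: str, value: float,
                    ref_low: Optional[float] = None,
                    ref_high: Optional[float] = None):
    """CTCAE v5.0 grade band for a cytopenia value.

    Returns an int grade 1-4, None when the value is within normal limits,
    or the :data:`NOT_GRADED` marker for analytes without value-based
    bands (their grade comes from reviewer annotation).
    """
    if analyte not in _CTCAE_BANDS:
        return NOT_GRADED
    lln = ref_low if ref_low is not None else vocab.default_ref_range(analyte)[0]
    if value >= lln:
        return None
    edges, worst = _CTCAE_BANDS[analyte]
    for grade, edge in enumerate(edges, start=1):
        if value >= edge:
            return grade
    return worst


# ---------------------------------------------------------------------------
# ADE records and reviewer annotations
# ---------------------------------------------------------------------------

class ADERecord(BaseModel):
    ade_id: str
    admission_id: str
    ade_term: str
    system_organ_class: str
    suspected_drugs: list[tuple[str, str]] = Field(default_factory=list)
    causality: Causality
    ctcae_grade: int = Field(ge=1, le=5)
    sae: bool = False
    sae_criteria: list[str] = Field(default_factory=list)
    linked_triggers: set[str] = Field(min_length=1)
    onset_date: date


class TriggerAnnotation(BaseModel):
    """One reviewer judgement for one (admission, trigger) hit."""

    admission_id: str
    trigger_id: str
    is_ade: bool
    ade_term: Optional[str] = None
    onset_date: Optional[date] = None
    grade: Optional[int] = Field(default=None, ge=1, le=5)
    answers: Optional[CausalityAnswers] = None
    suspected_drugs: list[tuple[str, str]] = Field(default_factory=list)
    sae_flags: list[str] = Field(default_factory=list)


def classify_sae(criteria_flags: set[str] | list[str]) -> bool:
    """Serious iff at least one regulatory seriousness criterion is flagged."""
    flags = set(criteria_flags)
    unknown = flags - SAE_CRITERIA
    if unknown:
        raise ValueError(f"unknown SAE criteria: {sorted(unknown)}")
    return bool(flags)


def _auto_grade(adm: AdmissionRecord, hit: TriggerHit, term: str) -> Optional[int]:
    """CTCAE grade from the hit's laboratory evidence, when the ADE term is
    one of the four auto-gradable cytopenias."""
    for ref in hit.evidence:
        if not ref.startswith("lab:"):
            continue
        _, analyte, ts = ref.split(":", 2)
        if analyte not in CTCAE_AUTO_ANALYTES or CTCAE_ANALYTE_TERM[analyte] != term:
            continue
        for lab in adm.labs:
            if lab.analyte == analyte and lab.collected_at.isoformat() == ts:
                g = grade_lab_ctcae(analyte, lab.value, lab.lln(), lab.uln())
                if isinstance(g, int):
                    return g
    return None


def adjudicate_hits(
    cohort: Cohort,
    hits: list[TriggerHit],
    annotations: list[TriggerAnnotation],
) -> list[ADERecord]:
    """Build candidate ADE records from hits and reviewer annotations.

    Each hit with a matching ``is_ade`` annotation yields one candidate
    carrying that single trigger; candidates are merged downstream by
    :func:`deduplicate_ades`.  Annotations for (admission, trigger) pairs
    without a hit raise a consistency error.
    """
    by_adm = {adm.admission_id: adm for adm in cohort}
    hit_index = {(h.admission_id, h.trigger_id): h for h in hits}
    ann_index: dict[tuple[str, str], TriggerAnnotation] = {}
    for ann in annotations:
        key = (ann.admission_id, ann.trigger_id)
        if key in ann_index:
            raise ValueError(f"duplicate annotation for {key}")
        ann_index[key] = ann

    orphans = [k for k, a in ann_index.items() if a.is_ade and k not in hit_index]
    if orphans:
        raise ValueError(f"annotations without a matching hit: {sorted(orphans)[:5]}")

    candidates: list[ADERecord] = []
    seq = 0
    for hit in hits:
        ann = ann_index.get((hit.admission_id, hit.trigger_id))
        if ann is None or not ann.is_ade:
            continue
        if ann.ade_term is None or ann.ade_term not in vocab.ADE_SOC:
            raise ValueError(
                f"{hit.admission_id}/{hit.trigger_id}: missing or unknown ADE term "
                f"{ann.ade_term!r}")
        adm = by_adm[hit.admission_id]
        grade = _auto_grade(adm, hit, ann.ade_term)
        if grade is None:
            grade = ann.grade if ann.grade is not None else 1
        answers = ann.answers
        causality: Causality = assess_causality(answers) if answers else "probable"
        sae = classify_sae(ann.sae_flags)
        seq += 1
        candidates.append(ADERecord(
            ade_id=f"ade-{seq:04d}",
            admission_id=hit.admission_id,
            ade_term=ann.ade_term,
            system_organ_class=vocab.ADE_SOC[ann.ade_term],
            suspected_drugs=list(ann.suspected_drugs),
            causality=causality,
            ctcae_grade=grade,
            sae=sae,
            sae_criteria=sorted(set(ann.sae_flags)),
            linked_triggers={hit.trigger_id},
            onset_date=ann.onset_date or hit.hit_date,
        ))
    return candidates


def deduplicate_ades(candidates: list[ADERecord],
                     merge_window_days: int = 7) -> list[ADERecord]:
    """Merge candidates describing the same clinical event.

    Candidates on the same admission with the same ADE term whose onsets
    fall within ``merge_window_days`` of the cluster anchor are one event:
    the merged record unions the linked triggers, suspected drugs and SAE
    criteria, keeps the earliest onset and the worst grade.  Input order
    does not matter (candidates are canonically sorted first) and the
    operation is idempotent.
    """
    order = {tid: i for i, tid in enumerate(TRIGGER_ORDER)}
    ordered = sorted(
        candidates,
        key=lambda c: (c.admission_id, c.ade_term, c.onset_date,
                       min(order.get(t, 99) for t in c.linked_triggers)))
    merged: list[ADERecord] = []
    anchors: dict[tuple[str, str], list[ADERecord]] = {}
    for cand in ordered:
        cluster = None
        for rec in anchors.get((cand.admission_id, cand.ade_term), []):
            if abs((cand.onset_date - rec.onset_date).days) <= merge_window_days:
                cluster = rec
                break
        if cluster is None:
            rec = cand.model_copy(deep=True)
            merged.append(rec)
            anchors.setdefault((cand.admission_id, cand.ade_term), []).append(rec)
        else:
            cluster.linked_triggers |= cand.linked_triggers
            for d in cand.suspected_drugs:
                if d not in cluster.suspected_drugs:
                    cluster.suspected_drugs.append(d)
            cluster.sae = cluster.sae or cand.sae
            cluster.sae_criteria = sorted(set(cluster.sae_criteria) | set(cand.sae_criteria))
            cluster.ctcae_grade = max(cluster.ctcae_grade, cand.ctcae_grade)
            cluster.onset_date = min(cluster.onset_date, cand.onset_date)
    for i, rec in enumerate(merged, start=1):
        rec.ade_id = f"ade-{i:04d}"
    return merged


def filter_by_causality(ades: list[ADERecord]) -> list[ADERecord]:
    """Retain only events assessed certain, probable or possible."""
    return [a for a in ades if a.causality in INCLUDED_CAUSALITY]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _drugs_to_str(drugs: list[tuple[str, str]]) -> str:
    return ";".join(f"{name}:{cls}" for name, cls in drugs)


def _drugs_from_str(s: str) -> list[tuple[str, str]]:
    out = []
    for part in filter(None, s.split(";")):
        name, cls = part.rsplit(":", 1)
        out.append((name, cls))
    return out


def write_ades_csv(ades: list[ADERecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    order = {tid: i for i, tid in enumerate(TRIGGER_ORDER)}
    rows = [{
        "ade_id": a.ade_id, "admission_id": a.admission_id,
        "ade_term": a.ade_term, "soc": a.system_organ_class,
        "suspected_drugs": _drugs_to_str(a.suspected_drugs),
        "causality": a.causality, "grade": a.ctcae_grade, "sae": a.sae,
        "linked_triggers": ";".join(sorted(a.linked_triggers,
                                           key=lambda t: order.get(t, 99))),
        "onset_date": a.onset_date.isoformat(),
    } for a in ades]
    pd.DataFrame(rows, columns=[
        "ade_id", "admission_id", "ade_term", "soc", "suspected_drugs",
        "causality", "grade", "sae", "linked_triggers", "onset_date",
    ]).to_csv(path, index=False)
    return path


def write_annotations_csv(annotations: list[TriggerAnnotation], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for a in annotations:
        ans = a.answers.model_dump() if a.answers else {}
        rows.append({
            "admission_id": a.admission_id, "trigger_id": a.trigger_id,
            "is_ade": a.is_ade, "ade_term": a.ade_term or "",
            "onset_date": a.onset_date.isoformat() if a.onset_date else "",
            "grade": "" if a.grade is None else a.grade,
            "temporal_sequence": ans.get("temporal_sequence", ""),
            "known_reaction_pattern": ans.get("known_reaction_pattern", ""),
            "dechallenge_improvement": ans.get("dechallenge_improvement", ""),
            "rechallenge_recurrence": ans.get("rechallenge_recurrence", ""),
            "alternative_explanation": ans.get("alternative_explanation", ""),
            "suspected_drugs": _drugs_to_str(a.suspected_drugs),
            "sae_flags": ";".join(a.sae_flags),
        })
    pd.DataFrame(rows, columns=[
        "admission_id", "trigger_id", "is_ade", "ade_term", "onset_date",
        "grade", "temporal_sequence", "known_reaction_pattern",
        "dechallenge_improvement", "rechallenge_recurrence",
        "alternative_explanation", "suspected_drugs", "sae_flags",
    ]).to_csv(path, index=False)
    return path


def read_annotations_csv(path: str | Path) -> list[TriggerAnnotation]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: list[TriggerAnnotation] = []
    for _, row in frame.iterrows():
        answers = None
        if row["temporal_sequence"] != "":
            answers = CausalityAnswers(
                temporal_sequence=row["temporal_sequence"] == "True",
                known_reaction_pattern=row["known_reaction_pattern"] == "True",
                dechallenge_improvement=row["dechallenge_improvement"],
                rechallenge_recurrence=row["rechallenge_recurrence"],
                alternative_explanation=row["alternative_explanation"] == "True",
            )
        out.append(TriggerAnnotation(
            admission_id=row["admission_id"], trigger_id=row["trigger_id"],
            is_ade=row["is_ade"] == "True",
            ade_term=row["ade_term"] or None,
            onset_date=row["onset_date"] or None,
            grade=int(row["grade"]) if row["grade"] != "" else None,
            answers=answers,
            suspected_drugs=_drugs_from_str(row["suspected_drugs"]),
            sae_flags=list(filter(None, row["sae_flags"].split(";"))),
        ))
    return out
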