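"""Synthetic oncology cohorts with the reference study's statistical structure.

Two entry points:

:func:`generate_cohort`
    A seeded stochastic generator.  Per admission and trigger, a
    Bernoulli draw with the trigger's positivity probability decides
    whether a hit-inducing observation is planted (a lab value beyond the
    cutoff, or the qualifying event / medication / intervention); with the
    trigger's linkage probability the hit is accompanied by ground-truth
    ADE annotations (term, CTCAE grade from the severity mixture,
    suspected drugs from the catalogue weights, causality from the
    mixture).  Non-hit laboratory observations sit strictly inside normal
    ranges.  Defaults reproduce the reference cohort's marginals
    (positivity = positives/500, linkage = per-trigger PPV).

:func:`build_replay_fixture`
    A fully deterministic (no RNG) 500-admission cohort constructed so
    that screening + adjudication + metrics reproduce the reference
    marginals simultaneously and exactly: per-trigger positives and
    linked-ADE counts (totals 1,556 and 715), 459 admissions with a hit,
    315 with an ADE, 680 unique ADEs of which 35 carry two triggers,
    the severity / system-organ / causality / suspected-drug tables,
    77 admissions with a serious event, and 3,264 total patient-days.
    A self-check runs the full pipeline and raises on any violated
    marginal.

Ground truth is emitted as a separate annotations list, never embedded in
the cohort, so the screening path cannot see labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import vocab
from .adjudication import (
    ADERecord,
    CausalityAnswers,
    TriggerAnnotation,
    adjudicate_hits,
    deduplicate_ades,
    filter_by_causality,
)
from .cohort import (
    AdmissionRecord,
    ClinicalEvent,
    Cohort,
    InterventionEvent,
    LabResult,
    MedicationOrder,
)
from .triggers import TRIGGER_ORDER, builtin_registry, screen_cohort

# ---------------------------------------------------------------------------
# Reference-study marginals
# ---------------------------------------------------------------------------

#: trigger_id -> (positive triggers, trigger-linked ADEs) in the 500-record
#: reference cohort.
STUDY_TRIGGER_MARGINALS: dict[str, tuple[int, int]] = {
    "L1": (116, 107), "L2": (86, 74), "L3": (143, 131), "L4": (212, 195),
    "L5": (26, 18), "L6": (5, 4), "L7": (105, 3), "L8": (2, 0), "L9": (2, 0),
    "L10": (2, 0), "L11": (58, 1), "L12": (1, 0), "L13": (130, 0),
    "L14": (30, 2), "L15": (11, 3), "L16": (1, 0), "L17": (0, 0),
    "L18": (1, 1), "L19": (1, 1), "L20": (143, 2), "L21": (0, 0),
    "L22": (0, 0),
    "S1": (25, 11), "S2": (1, 1), "S3": (32, 22), "S4": (70, 64),
    "S5": (8, 2), "S6": (3, 3), "S7": (17, 16), "S8": (23, 15),
    "S9": (0, 0), "S10": (2, 2),
    "T1": (180, 2), "T2": (84, 0), "T3": (3, 2),
    "M1": (1, 1), "M2": (32, 32),
}

#: Triggers whose linked ADEs are events already identified by another
#: trigger (antidote/intervention clues without an ADE term of their own in
#: the outcome tables); they account for the 35 multi-trigger ADEs.
MULTI_LINK_TRIGGERS = ("T3", "M1", "M2")

STUDY_N = 500
STUDY_PATIENT_DAYS = 3264
STUDY_CAUSALITY_COUNTS = {"certain": 180, "probable": 492, "possible": 8}

STUDY_DEMOGRAPHICS = {
    "sex": {"male": 282, "female": 218},
    "age_bands": {(29, 44): 43, (45, 69): 316, (70, 79): 121, (80, 86): 20},
    "tumor_category": {"digestive-system": 260, "lung": 75, "gynecological": 48,
                       "lymphoma": 38, "breast": 33, "urogenital": 20, "other": 26},
    "tumor_stage": {"I": 17, "II": 25, "III": 87, "IV": 301,
                    "SCLC-limited": 2, "SCLC-extensive": 13, "not-staged": 55},
    "comorbidity": {"hypertension": 251, "diabetes-mellitus": 113,
                    "coronary-heart-disease": 68, "cerebrovascular-disease": 49,
                    "hyperlipidemia": 53, "other": 225},
}

_DIGESTIVE_CYCLE = ["colorectal", "gastric", "esophageal", "pancreatic", "hepatobiliary"]

LOS_MEAN, LOS_SD, LOS_RANGE = 6.53, 4.21, (2, 28)

_BASE_REGIMEN = [("oxaliplatin", "platinum"), ("fluorouracil", "antimetabolite"),
                 ("paclitaxel", "plant-derived")]

#: normal panel used for non-fired laboratory analytes
_NORMAL_PANEL = {
    "HGB": 130.0, "PLT": 200.0, "NEUT": 3.0, "WBC": 6.0, "ALT": 25.0,
    "CREA": 70.0, "K": 4.2, "CA": 2.30, "GLU_FASTING": 5.0,
}

#: hit-inducing lab value per (analyte, CTCAE grade) for the auto-graded
#: cytopenias; chosen in the middle of each grade band.
_GRADE_VALUES = {
    "HGB": {2: 90.0, 3: 70.0},
    "WBC": {1: 3.5, 2: 2.5, 3: 1.5, 4: 0.8},
    "NEUT": {1: 1.6, 2: 1.2, 3: 0.8, 4: 0.4},
    "PLT": {1: 90.0, 2: 60.0, 3: 40.0, 4: 20.0},
}

_CAUSALITY_ANSWERS = {
    "certain": CausalityAnswers(
        temporal_sequence=True, known_reaction_pattern=True,
        dechallenge_improvement="yes", rechallenge_recurrence="yes",
        alternative_explanation=False),
    "probable": CausalityAnswers(
        temporal_sequence=True, known_reaction_pattern=True,
        dechallenge_improvement="yes", rechallenge_recurrence="not-done",
        alternative_explanation=False),
    "possible": CausalityAnswers(
        temporal_sequence=True, known_reaction_pattern=True,
        dechallenge_improvement="not-done", rechallenge_recurrence="not-done",
        alternative_explanation=True),
}

_ASSOCIATED_TERM = {d.trigger_id: d.associated_ade for d in builtin_registry()}


class SynthConfig(BaseModel):
    """Generator configuration; defaults are the reference-study conditions."""

    n_admissions: int = Field(default=STUDY_N, ge=1)
    seed: int = 0
    trigger_positivity: dict[str, float] = Field(
        default_factory=lambda: {t: p / STUDY_N
                                 for t, (p, _) in STUDY_TRIGGER_MARGINALS.items()})
    linkage_ppv: dict[str, float] = Field(
        default_factory=lambda: {t: (l / p if p else 0.0)
                                 for t, (p, l) in STUDY_TRIGGER_MARGINALS.items()})
    causality_mixture: dict[str, float] = Field(
        default_factory=lambda: {k: v / 680 for k, v in STUDY_CAUSALITY_COUNTS.items()})
    los_mean: float = LOS_MEAN
    los_sd: float = LOS_SD
    los_range: tuple[int, int] = LOS_RANGE

    @model_validator(mode="after")
    def _check(self) -> "SynthConfig":
        for name, probs in (("trigger_positivity", self.trigger_positivity),
                            ("linkage_ppv", self.linkage_ppv)):
            for tid, p in probs.items():
                if tid not in STUDY_TRIGGER_MARGINALS:
                    raise ValueError(f"{name}: unknown trigger_id {tid!r}")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{tid}]={p} outside [0, 1]")
        if abs(sum(self.causality_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("causality_mixture must sum to 1")
        return self


@dataclass
class GeneratedCohort:
    cohort: Cohort
    annotations: list[TriggerAnnotation]
    #: ground truth: (admission_id, trigger_id, has_ade)
    truth: list[tuple[str, str, bool]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Evidence materializers
# ---------------------------------------------------------------------------

def _ts(d: date, hour: int = 8, minute: int = 0) -> datetime:
    return datetime.combine(d, time(hour, minute))


def _mklab(analyte: str, value: Optional[float], d: date, hour: int = 8,
           minute: int = 0, qualitative: Optional[str] = None) -> LabResult:
    lo, hi = vocab.default_ref_range(analyte)
    return LabResult(analyte=analyte, value=value, unit=vocab.canonical_unit(analyte),
                     collected_at=_ts(d, hour, minute), ref_low=lo, ref_high=hi,
                     qualitative_result=qualitative)


@dataclass
class _Obs:
    labs: list[LabResult] = field(default_factory=list)
    events: list[ClinicalEvent] = field(default_factory=list)
    meds: list[MedicationOrder] = field(default_factory=list)
    interventions: list[InterventionEvent] = field(default_factory=list)


def make_trigger_evidence(trigger_id: str, admit: date, discharge: date,
                          sex: str, grade: Optional[int] = None) -> _Obs:
    """Observations that make `trigger_id` fire on this admission.

    For the auto-graded cytopenia triggers an optional CTCAE ``grade``
    places the value inside that grade's band; otherwise values sit 10%
    beyond the cutoff (defensive against boundary-strictness bugs).
    """
    d0, d1 = admit, admit + timedelta(days=1)
    d2 = min(admit + timedelta(days=2), discharge)
    obs = _Obs()
    lab = obs.labs.append
    ev = obs.events.append
    simple = {"L8": ("GLU_FASTING", 9.8), "L9": ("GLU_FASTING", 3.5),
              "L10": ("K", 5.9), "L11": ("K", 3.1), "L12": ("CA", 2.78),
              "L13": ("CA", 1.9), "L16": ("TNI", 0.038), "L17": ("BNP", 450.0)}
    hema = {"L1": "HGB", "L2": "PLT", "L3": "NEUT", "L4": "WBC"}
    symptoms = {"S2": "oral-mucositis", "S4": "nausea", "S5": "constipation",
                "S6": "hand-foot-erythema", "S7": "distal-paresthesia",
                "S8": "rash", "S9": "extravasation-sign",
                "S10": "capillary-hyperplasia", "L20": "ct-ground-glass"}
    if trigger_id in hema:
        analyte = hema[trigger_id]
        default = {"HGB": 90.0, "PLT": 90.0, "NEUT": 1.62, "WBC": 3.6}[analyte]
        value = _GRADE_VALUES[analyte].get(grade, default) if grade else default
        lab(_mklab(analyte, value, d1))
    elif trigger_id in simple:
        analyte, value = simple[trigger_id]
        lab(_mklab(analyte, value, d1))
    elif trigger_id == "L5":
        lab(_mklab("ALT", 88.0, d1))            # 2.2x ULN 40
    elif trigger_id == "L6":
        lab(_mklab("CREA", 60.0, d0))           # baseline
        lab(_mklab("CREA", 95.0, d2))           # 1.58x baseline
    elif trigger_id == "L7":
        lab(_mklab("SBP", 120.0, d0))
        lab(_mklab("DBP", 75.0, d0))
        lab(_mklab("SBP", 154.0, d2))
        lab(_mklab("DBP", 95.0, d2))
    elif trigger_id == "L14":
        lab(_mklab("UA", 396.0 if sex == "female" else 462.0, d1))
    elif trigger_id == "L15":
        lab(_mklab("UPRO_QUAL", None, d1, qualitative="positive"))
    elif trigger_id == "L18":
        lab(_mklab("TSH", 5.5, d1))
        lab(_mklab("FT4", 0.6, d1))
    elif trigger_id == "L19":
        lab(_mklab("TSH", 0.2, d1))
        lab(_mklab("FT4", 2.2, d1))
    elif trigger_id == "L21":
        lab(_mklab("TSH", 0.2, d1))
        lab(_mklab("FT4", 0.6, d1))
    elif trigger_id == "L22":
        lab(_mklab("ACTH", 5.0, d1, hour=8))
        lab(_mklab("COR", 4.0, d1, hour=8, minute=30))
    elif trigger_id == "S1":
        ev(ClinicalEvent(code="fever", onset_date=d1,
                         attributes={"temperature_c": 38.9}))
    elif trigger_id == "S3":
        ev(ClinicalEvent(code="diarrhea", onset_date=d1,
                         attributes={"stools_per_day": 6}))
    elif trigger_id in symptoms:
        ev(ClinicalEvent(code=symptoms[trigger_id], onset_date=d1))
    elif trigger_id == "T1":
        obs.meds.append(MedicationOrder(
            drug_name="dexamethasone", drug_class="glucocorticoid",
            is_antineoplastic=False, start_date=d1, stop_date=d2))
        obs.meds.append(MedicationOrder(
            drug_name="promethazine", drug_class="antihistamine",
            is_antineoplastic=False, start_date=d1, stop_date=d1))
    elif trigger_id == "T2":
        obs.meds.append(MedicationOrder(
            drug_name="enoxaparin", drug_class="anticoagulant",
            is_antineoplastic=False, start_date=d1, stop_date=d2))
    elif trigger_id == "T3":
        obs.meds.append(MedicationOrder(
            drug_name="calcium-leucovorin", drug_class="leucovorin",
            is_antineoplastic=False, start_date=d1, stop_date=d2))
    elif trigger_id == "M1":
        obs.interventions.append(InterventionEvent(
            kind="icu-transfer", date=d1, due_to_toxicity=True))
    elif trigger_id == "M2":
        obs.interventions.append(InterventionEvent(
            kind="dose-reduction", date=d1, due_to_toxicity=True))
    else:  # pragma: no cover
        raise ValueError(f"no materializer for trigger {trigger_id!r}")
    return obs


def _hit_analytes(trigger_id: str) -> set[str]:
    """Panel analytes touched by a trigger's evidence (to skip normals)."""
    return {
        "L1": {"HGB"}, "L2": {"PLT"}, "L3": {"NEUT"}, "L4": {"WBC"},
        "L5": {"ALT"}, "L6": {"CREA"}, "L8": {"GLU_FASTING"},
        "L9": {"GLU_FASTING"}, "L10": {"K"}, "L11": {"K"}, "L12": {"CA"},
        "L13": {"CA"},
    }.get(trigger_id, set())


# ---------------------------------------------------------------------------
# Stochastic generator
# ---------------------------------------------------------------------------

def _lognormal_los(rng: np.random.Generator, mean: float, sd: float,
                   lo: int, hi: int) -> int:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    for _ in range(100):
        draw = int(round(rng.lognormal(mu, np.sqrt(sigma2))))
        if lo <= draw <= hi:
            return draw
    return int(round(mean))


def _sample_categorical(rng: np.random.Generator, counts: dict) -> object:
    keys = list(counts)
    probs = np.array([counts[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _sample_grade(rng: np.random.Generator, term: str) -> int:
    counts = vocab.SEVERITY_COUNTS.get(term)
    if counts is None:
        mix = vocab.DEFAULT_SEVERITY_MIX
        return int(rng.choice(list(mix), p=list(mix.values())))
    probs = np.array(counts, dtype=float)
    return int(rng.choice([1, 2, 3, 4], p=probs / probs.sum()))


_DRUG_NAMES = [name for name, _, _ in vocab.SUSPECTED_DRUG_WEIGHTS]
_DRUG_PROBS = np.array([w for _, _, w in vocab.SUSPECTED_DRUG_WEIGHTS], dtype=float)
_DRUG_PROBS /= _DRUG_PROBS.sum()


def _sample_drugs(rng: np.random.Generator, k: int) -> list[tuple[str, str]]:
    idx = rng.choice(len(_DRUG_NAMES), size=min(k, 3), replace=False, p=_DRUG_PROBS)
    return [(vocab.SUSPECTED_DRUG_WEIGHTS[i][0], vocab.SUSPECTED_DRUG_WEIGHTS[i][1])
            for i in idx]


def generate_cohort(config: SynthConfig | None = None) -> GeneratedCohort:
    """Seeded synthetic cohort plus ground-truth annotations."""
    if config is None:
        config = SynthConfig()
    rng = np.random.default_rng(config.seed)
    demo = STUDY_DEMOGRAPHICS
    cohort: Cohort = []
    annotations: list[TriggerAnnotation] = []
    truth: list[tuple[str, str, bool]] = []
    cats = list(config.causality_mixture)
    cat_probs = np.array([config.causality_mixture[c] for c in cats])
    for i in range(config.n_admissions):
        aid = f"syn-{i:04d}"
        sex = _sample_categorical(rng, demo["sex"])
        band = _sample_categorical(rng, demo["age_bands"])
        age = int(rng.integers(band[0], band[1] + 1))
        category = _sample_categorical(rng, demo["tumor_category"])
        tumor = (str(_sample_categorical(rng, dict.fromkeys(_DIGESTIVE_CYCLE, 1)))
                 if category == "digestive-system" else str(category))
        stage = str(_sample_categorical(rng, demo["tumor_stage"]))
        comorbidities = {c for c, n in demo["comorbidity"].items()
                         if rng.random() < n / STUDY_N}
        los = _lognormal_los(rng, config.los_mean, config.los_sd, *config.los_range)
        admit = date(2020, 6, 1) + timedelta(days=int(rng.integers(0, 330)))
        discharge = admit + timedelta(days=los)
        obs = _Obs()
        base_drug, base_class = _BASE_REGIMEN[i % len(_BASE_REGIMEN)]
        obs.meds.append(MedicationOrder(
            drug_name=base_drug, drug_class=base_class, is_antineoplastic=True,
            start_date=admit + timedelta(days=1),
            stop_date=min(admit + timedelta(days=3), discharge)))
        fired_analytes: set[str] = set()
        for tid in TRIGGER_ORDER:
            p = config.trigger_positivity.get(tid, 0.0)
            if tid in ("L8", "L9") and "diabetes-mellitus" in comorbidities:
                continue
            if tid == "T3" and tumor in ("colorectal", "gastric"):
                continue
            if rng.random() >= p:
                continue
            linked = rng.random() < config.linkage_ppv.get(tid, 0.0)
            term = _ASSOCIATED_TERM[tid]
            grade = _sample_grade(rng, term) if linked else None
            hit_obs = make_trigger_evidence(tid, admit, discharge, sex, grade)
            obs.labs += hit_obs.labs
            obs.events += hit_obs.events
            obs.meds += hit_obs.meds
            obs.interventions += hit_obs.interventions
            fired_analytes |= _hit_analytes(tid)
            truth.append((aid, tid, linked))
            if linked:
                causality = cats[int(rng.choice(len(cats), p=cat_probs))]
                sae_flags = []
                if grade == 4:
                    sae_flags = ["life-threatening"]
                elif grade == 3 and rng.random() < 0.5:
                    sae_flags = ["hospitalization"]
                drugs = _sample_drugs(rng, 1 + int(rng.random() < 0.5))
                annotations.append(TriggerAnnotation(
                    admission_id=aid, trigger_id=tid, is_ade=True, ade_term=term,
                    grade=grade, answers=_CAUSALITY_ANSWERS[causality],
                    suspected_drugs=drugs, sae_flags=sae_flags))
        for analyte, value in _NORMAL_PANEL.items():
            if analyte not in fired_analytes:
                obs.labs.append(_mklab(analyte, value, admit + timedelta(days=1)))
        cohort.append(AdmissionRecord(
            admission_id=aid, age=age, sex=sex, admit_date=admit,
            discharge_date=discharge, tumor_type=tumor, tumor_stage=stage,
            comorbidities=comorbidities,
            prior_chemotherapy_count=int(rng.poisson(2.0)),
            prior_adr_history=bool(rng.random() < 0.2),
            radiotherapy=bool(rng.random() < 0.15),
            labs=obs.labs, medications=obs.meds, events=obs.events,
            interventions=obs.interventions))
    return GeneratedCohort(cohort=cohort, annotations=annotations, truth=truth)


# ---------------------------------------------------------------------------
# Deterministic replay fixture
# ---------------------------------------------------------------------------

class FixtureError(AssertionError):
    """The replay fixture violates one or more target marginals."""


def _interleave_counts(counts: dict) -> list:
    """Deterministic proportional interleaving of categorical counts."""
    total = sum(counts.values())
    assigned = dict.fromkeys(counts, 0)
    seq = []
    for i in range(total):
        best, best_deficit = None, None
        for k, n in counts.items():
            deficit = n * (i + 1) / total - assigned[k]
            if best is None or deficit > best_deficit:
                best, best_deficit = k, deficit
        seq.append(best)
        assigned[best] += 1
    return seq


def _spread_flags(total: int, k: int) -> list[bool]:
    """k True values spread evenly over `total` positions (Bresenham)."""
    return [((i + 1) * k) // total - (i * k) // total == 1 for i in range(total)]


def build_replay_fixture() -> GeneratedCohort:
    """Deterministic 500-admission cohort reproducing the study marginals.

    Allocation: ADE-bearing hits for the 34 term triggers round-robin over
    admissions 0-314; the 35 multi-link hits (T3, M1, M2) attach to the
    first ADE of admissions 0-34; the remaining 841 non-ADE hits
    round-robin over admissions 0-458; admissions 459-499 stay negative.
    The self-check then runs the real pipeline and verifies every marginal.
    """
    n = STUDY_N
    n_ade_adm, n_hit_adm = 315, 459
    # --- hit/ADE allocation -------------------------------------------------
    hits_by_adm: dict[int, list[str]] = {i: [] for i in range(n)}
    hit_keys: set[tuple[str, int]] = set()
    #: per admission: list of ADE dicts (trigger, term, grade)
    ades_by_adm: dict[int, list[dict]] = {i: [] for i in range(n)}
    ade_order: list[dict] = []
    p = 0
    for tid in TRIGGER_ORDER:
        if tid in MULTI_LINK_TRIGGERS:
            continue
        _, linked = STUDY_TRIGGER_MARGINALS[tid]
        term = _ASSOCIATED_TERM[tid]
        g1, g2, g3, g4 = vocab.SEVERITY_COUNTS.get(term, (linked, 0, 0, 0))
        grades = [1] * g1 + [2] * g2 + [3] * g3 + [4] * g4
        assert len(grades) == linked, (tid, term)
        for k in range(linked):
            adm = p % n_ade_adm
            assert (tid, adm) not in hit_keys
            entry = {"trigger": tid, "term": term, "grade": grades[k], "adm": adm,
                     "partners": []}
            hits_by_adm[adm].append(tid)
            hit_keys.add((tid, adm))
            ades_by_adm[adm].append(entry)
            ade_order.append(entry)
            p += 1
    # multi-link triggers attach to the first ADE of distinct admissions
    multi_targets = {"T3": [0, 1], "M1": [2], "M2": list(range(3, 35))}
    t3_no_colorectal: set[int] = set()
    for tid in MULTI_LINK_TRIGGERS:
        for adm in multi_targets[tid]:
            partner = ades_by_adm[adm][0]
            partner["partners"].append(tid)
            hits_by_adm[adm].append(tid)
            hit_keys.add((tid, adm))
            if tid == "T3":
                t3_no_colorectal.add(adm)
    # non-ADE hits
    q = 0
    no_diabetes: set[int] = set()
    for tid in TRIGGER_ORDER:
        pos, linked = STUDY_TRIGGER_MARGINALS[tid]
        extra = pos - linked if tid not in MULTI_LINK_TRIGGERS \
            else pos - len(multi_targets[tid])
        for _ in range(extra):
            while (tid, q % n_hit_adm) in hit_keys:
                q += 1
            adm = q % n_hit_adm
            hits_by_adm[adm].append(tid)
            hit_keys.add((tid, adm))
            q += 1
            if tid in ("L8", "L9"):
                no_diabetes.add(adm)
            if tid == "T3":
                t3_no_colorectal.add(adm)
    # --- per-ADE attributes in creation order -------------------------------
    causality_seq = _interleave_counts(STUDY_CAUSALITY_COUNTS)
    mentions: list[tuple[str, str]] = []
    for name, cls, count in vocab.SUSPECTED_DRUG_WEIGHTS:
        mentions += [(name, cls)] * count
    half = len(mentions) // 2                     # 1032 -> 516
    n_two = len(mentions) - len(ade_order)        # ADEs with two suspected drugs
    leftovers = mentions[n_two:half] + mentions[half + n_two:]
    for i, entry in enumerate(ade_order):
        entry["causality"] = causality_seq[i]
        if i < n_two:
            pair = [mentions[i], mentions[half + i]]
            if pair[0] == pair[1]:                # defensive: keep drugs distinct
                pair[1] = leftovers[0]
            entry["drugs"] = pair
        else:
            entry["drugs"] = [leftovers[i - n_two]]
        entry["sae_flags"] = []
    # SAE: all grade-4 events are life-threatening; grade-3 events prolong
    # hospitalization on additional admissions until 77 are serious.
    sae_admissions: set[int] = set()
    for entry in ade_order:
        if entry["grade"] == 4:
            entry["sae_flags"] = ["life-threatening"]
            sae_admissions.add(entry["adm"])
    for entry in ade_order:
        if len(sae_admissions) >= 77:
            break
        if entry["grade"] == 3 and entry["adm"] not in sae_admissions:
            entry["sae_flags"] = ["hospitalization"]
            sae_admissions.add(entry["adm"])
    # --- demographics -------------------------------------------------------
    sex_seq = _interleave_counts(STUDY_DEMOGRAPHICS["sex"])
    stage_seq = _interleave_counts(STUDY_DEMOGRAPHICS["tumor_stage"])
    band_seq = _interleave_counts(STUDY_DEMOGRAPHICS["age_bands"])
    type_seq = _interleave_counts(STUDY_DEMOGRAPHICS["tumor_category"])
    digestive_i = 0
    tumor_types: list[str] = []
    for i in range(n):
        if type_seq[i] == "digestive-system":
            tumor_types.append(_DIGESTIVE_CYCLE[digestive_i % len(_DIGESTIVE_CYCLE)])
            digestive_i += 1
        else:
            tumor_types.append(type_seq[i])
    # keep leucovorin-trigger admissions clear of its tumor-type exclusions
    for adm in sorted(t3_no_colorectal):
        if tumor_types[adm] in ("colorectal", "gastric"):
            for j in range(n):
                if j not in t3_no_colorectal and \
                        tumor_types[j] not in ("colorectal", "gastric"):
                    tumor_types[adm], tumor_types[j] = tumor_types[j], tumor_types[adm]
                    break
    comorbidity_sets: list[set[str]] = [set() for _ in range(n)]
    for como, count in STUDY_DEMOGRAPHICS["comorbidity"].items():
        flags = _spread_flags(n, count)
        if como == "diabetes-mellitus":
            assigned = 0
            for i in range(n):
                if assigned < count and flags[i] and i not in no_diabetes:
                    comorbidity_sets[i].add(como)
                    assigned += 1
            i = 0
            while assigned < count:
                if i not in no_diabetes and como not in comorbidity_sets[i]:
                    comorbidity_sets[i].add(como)
                    assigned += 1
                i += 1
        else:
            for i in range(n):
                if flags[i]:
                    comorbidity_sets[i].add(como)
    los_flags = _spread_flags(n, STUDY_PATIENT_DAYS - 6 * n)  # 264 stays of 7 days
    ages = []
    band_pos: dict[tuple, int] = {}
    for i in range(n):
        lo, hi = band_seq[i]
        k = band_pos.get(band_seq[i], 0)
        band_pos[band_seq[i]] = k + 1
        ages.append(lo + k % (hi - lo + 1))
    # --- materialize --------------------------------------------------------
    cohort: Cohort = []
    annotations: list[TriggerAnnotation] = []
    truth: list[tuple[str, str, bool]] = []
    for i in range(n):
        aid = f"rec-{i:04d}"
        admit = date(2020, 6, 1) + timedelta(days=(i * 7) % 330)
        los = 7 if los_flags[i] else 6
        discharge = admit + timedelta(days=los)
        sex = sex_seq[i]
        obs = _Obs()
        base_drug, base_class = _BASE_REGIMEN[i % len(_BASE_REGIMEN)]
        seen_drugs = {base_drug}
        obs.meds.append(MedicationOrder(
            drug_name=base_drug, drug_class=base_class, is_antineoplastic=True,
            start_date=admit + timedelta(days=1),
            stop_date=admit + timedelta(days=3)))
        ade_for_trigger = {e["trigger"]: e for e in ades_by_adm[i]}
        partner_of = {tid: e for e in ades_by_adm[i] for tid in e["partners"]}
        for tid in hits_by_adm[i]:
            entry = ade_for_trigger.get(tid) or partner_of.get(tid)
            grade = entry["grade"] if entry is not None and tid not in MULTI_LINK_TRIGGERS else None
            hit_obs = make_trigger_evidence(tid, admit, discharge, sex, grade)
            obs.labs += hit_obs.labs
            obs.events += hit_obs.events
            obs.meds += hit_obs.meds
            obs.interventions += hit_obs.interventions
            truth.append((aid, tid, entry is not None))
            if entry is not None:
                annotations.append(TriggerAnnotation(
                    admission_id=aid, trigger_id=tid, is_ade=True,
                    ade_term=entry["term"], grade=entry["grade"],
                    answers=_CAUSALITY_ANSWERS[entry["causality"]],
                    suspected_drugs=list(entry["drugs"]),
                    sae_flags=list(entry["sae_flags"])))
        for entry in ades_by_adm[i]:
            for name, cls in entry["drugs"]:
                if name not in seen_drugs:
                    seen_drugs.add(name)
                    obs.meds.append(MedicationOrder(
                        drug_name=name, drug_class=cls, is_antineoplastic=True,
                        start_date=admit + timedelta(days=1),
                        stop_date=admit + timedelta(days=2)))
        cohort.append(AdmissionRecord(
            admission_id=aid, age=ages[i], sex=sex, admit_date=admit,
            discharge_date=discharge, tumor_type=tumor_types[i],
            tumor_stage=stage_seq[i], comorbidities=comorbidity_sets[i],
            prior_chemotherapy_count=i % 5,
            prior_adr_history=(i % 5 == 1), radiotherapy=(i % 7 == 3),
            labs=obs.labs, medications=obs.meds, events=obs.events,
            interventions=obs.interventions))
    fixture = GeneratedCohort(cohort=cohort, annotations=annotations, truth=truth)
    check_fixture(fixture)
    return fixture


def check_fixture(fixture: GeneratedCohort) -> dict:
    """Run the full pipeline on the fixture and verify every target marginal.

    Returns the computed summary; raises :class:`FixtureError` listing the
    violated marginals otherwise.
    """
    cohort = fixture.cohort
    hits = screen_cohort(cohort)
    candidates = adjudicate_hits(cohort, hits, fixture.annotations)
    unique = filter_by_causality(deduplicate_ades(candidates))
    problems: list[str] = []

    def expect(name, got, want):
        if got != want:
            problems.append(f"{name}: got {got!r}, want {want!r}")

    expect("n_admissions", len(cohort), STUDY_N)
    expect("patient_days", sum(a.length_of_stay for a in cohort), STUDY_PATIENT_DAYS)
    pos = {t: 0 for t in TRIGGER_ORDER}
    for h in hits:
        pos[h.trigger_id] += 1
    linked = {t: 0 for t in TRIGGER_ORDER}
    for ade in unique:
        for t in ade.linked_triggers:
            linked[t] += 1
    for t in TRIGGER_ORDER:
        expect(f"positives[{t}]", pos[t], STUDY_TRIGGER_MARGINALS[t][0])
        expect(f"linked[{t}]", linked[t], STUDY_TRIGGER_MARGINALS[t][1])
    expect("hit_admissions", len({h.admission_id for h in hits}), 459)
    expect("ade_admissions", len({a.admission_id for a in unique}), 315)
    expect("unique_ades", len(unique), 680)
    expect("candidate_ades", len(candidates), 715)
    expect("multi_trigger_ades",
           sum(1 for a in unique if len(a.linked_triggers) > 1), 35)
    severity = {g: sum(1 for a in unique if a.ctcae_grade == g) for g in (1, 2, 3, 4, 5)}
    expect("severity_counts", severity, {1: 273, 2: 293, 3: 83, 4: 31, 5: 0})
    per_term: dict[tuple[str, int], int] = {}
    for a in unique:
        per_term[(a.ade_term, a.ctcae_grade)] = per_term.get((a.ade_term, a.ctcae_grade), 0) + 1
    for term, counts in vocab.SEVERITY_COUNTS.items():
        for g, want in zip((1, 2, 3, 4), counts):
            expect(f"severity[{term}][g{g}]", per_term.get((term, g), 0), want)
    causality = {c: sum(1 for a in unique if a.causality == c)
                 for c in STUDY_CAUSALITY_COUNTS}
    expect("causality_counts", causality, STUDY_CAUSALITY_COUNTS)
    expect("sae_admissions", len({a.admission_id for a in unique if a.sae}), 77)
    cat_mentions: dict[str, int] = {}
    for a in unique:
        for _, cls in a.suspected_drugs:
            cat_mentions[cls] = cat_mentions.get(cls, 0) + 1
    want_cats: dict[str, int] = {}
    for _, cls, count in vocab.SUSPECTED_DRUG_WEIGHTS:
        want_cats[cls] = want_cats.get(cls, 0) + count
    expect("drug_category_mentions", cat_mentions, want_cats)
    if problems:
        raise FixtureError("replay fixture self-check failed:\n  " +
                           "\n  ".join(problems))
    return {"hits": len(hits), "unique_ades": len(unique)}
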