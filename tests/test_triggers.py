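"""Trigger engine: registry content, predicate semantics, screening properties."""

from __future__ import annotations

import copy
from datetime import date, timedelta

import numpy as np
import pytest

from oncogtt import (
    ClinicalEvent,
    InterventionEvent,
    MedicationOrder,
    SynthConfig,
    builtin_registry,
    evaluate_trigger,
    generate_cohort,
    screen_cohort,
)
from oncogtt.vocab import default_ref_range

from conftest import ADMIT, make_admission, make_lab

REGISTRY = {d.trigger_id: d for d in builtin_registry()}


def eval_one(trigger_id: str, adm):
    return evaluate_trigger(REGISTRY[trigger_id], adm)


class TestRegistry:
    def test_size_and_module_counts(self):
        regs = builtin_registry()
        assert len(regs) == 37
        counts = {}
        for d in regs:
            counts[d.module] = counts.get(d.module, 0) + 1
        assert counts == {"laboratory": 22, "symptom": 10, "antidote": 3,
                          "intervention": 2}
        assert len({d.trigger_id for d in regs}) == 37

    def test_key_cutoffs_encoded(self):
        assert REGISTRY["L1"].predicate.params == {
            "analyte": "HGB", "direction": "<", "cutoff": 100.0}
        l22 = REGISTRY["L22"].predicate.params["groups"][0]
        assert {c["analyte"]: c["cutoff"] for c in l22} == {"ACTH": 7.2, "COR": 6.02}
        assert REGISTRY["L14"].predicate.params["sex_cutoffs"] == {
            "female": 360.0, "male": 420.0}


#: (trigger, analyte, boundary value, firing value, extra admission kwargs)
BOUNDARY_CASES = [
    ("L1", "HGB", 100.0, 95.0, {}),
    ("L2", "PLT", 100.0, 90.0, {}),
    ("L3", "NEUT", 1.8, 1.6, {}),
    ("L4", "WBC", 4.0, 3.5, {}),
    ("L8", "GLU_FASTING", 8.9, 9.5, {}),
    ("L9", "GLU_FASTING", 3.9, 3.5, {}),
    ("L10", "K", 5.3, 5.9, {}),
    ("L11", "K", 3.5, 3.1, {}),
    ("L12", "CA", 2.52, 2.8, {}),
    ("L13", "CA", 2.11, 1.9, {}),
    ("L14", "UA", 420.0, 460.0, {"sex": "male"}),
    ("L14", "UA", 360.0, 400.0, {"sex": "female"}),
]


class TestLabPredicates:
    @pytest.mark.parametrize("tid,analyte,boundary,firing,kw", BOUNDARY_CASES,
                             ids=lambda v: str(v))
    def test_threshold_boundary_strictness(self, tid, analyte, boundary, firing, kw):
        at_cutoff = make_admission(labs=[make_lab(analyte, boundary)], **kw)
        beyond = make_admission(labs=[make_lab(analyte, firing)], **kw)
        assert eval_one(tid, at_cutoff) is None, "value at cutoff must not fire"
        hit = eval_one(tid, beyond)
        assert hit is not None and hit.evidence

    def test_hit_cites_earliest_qualifying_lab(self):
        adm = make_admission(labs=[make_lab("HGB", 90.0, day=4),
                                   make_lab("HGB", 85.0, day=2)])
        hit = eval_one("L1", adm)
        assert hit.hit_date == ADMIT + timedelta(days=2)

    def test_hepatotoxicity_alt_over_two_uln(self):
        uln = default_ref_range("ALT")[1]
        assert eval_one("L5", make_admission(labs=[make_lab("ALT", 2 * uln)])) is None
        assert eval_one("L5", make_admission(labs=[make_lab("ALT", 2 * uln + 1)]))

    def test_hepatotoxicity_simultaneous_trio(self):
        # AST, ALP, TBIL all above ULN on the same day, one above 2x ULN
        trio = [make_lab("AST", 90.0), make_lab("ALP", 130.0), make_lab("TBIL", 20.0)]
        assert eval_one("L5", make_admission(labs=trio))
        # none above 2x ULN -> no hit
        mild = [make_lab("AST", 45.0), make_lab("ALP", 130.0), make_lab("TBIL", 20.0)]
        assert eval_one("L5", make_admission(labs=mild)) is None
        # split across days -> not simultaneous
        split = [make_lab("AST", 90.0, day=1), make_lab("ALP", 130.0, day=2),
                 make_lab("TBIL", 20.0, day=2)]
        assert eval_one("L5", make_admission(labs=split)) is None

    def test_creatinine_baseline_ratio(self):
        hit = eval_one("L6", make_admission(labs=[
            make_lab("CREA", 60.0, day=0), make_lab("CREA", 95.0, day=2)]))
        assert hit is not None        # 95/60 = 1.58 > 1.5
        assert eval_one("L6", make_admission(labs=[
            make_lab("CREA", 60.0, day=0), make_lab("CREA", 90.0, day=2)])) is None

    def test_gfr_branch(self):
        assert eval_one("L6", make_admission(labs=[make_lab("GFR", 59.0)]))
        assert eval_one("L6", make_admission(labs=[make_lab("GFR", 60.0)])) is None

    def test_bp_requires_previously_normal(self):
        normal_then_high = [make_lab("SBP", 120.0, day=0), make_lab("DBP", 75.0, day=0),
                            make_lab("SBP", 150.0, day=2), make_lab("DBP", 95.0, day=2)]
        hit = eval_one("L7", make_admission(labs=normal_then_high))
        assert hit is not None and hit.hit_date == ADMIT + timedelta(days=2)
        high_only = [make_lab("SBP", 150.0, day=2), make_lab("DBP", 95.0, day=2)]
        assert eval_one("L7", make_admission(labs=high_only)) is None
        high_then_normal = [make_lab("SBP", 150.0, day=0), make_lab("DBP", 95.0, day=0),
                            make_lab("SBP", 120.0, day=2), make_lab("DBP", 75.0, day=2)]
        assert eval_one("L7", make_admission(labs=high_then_normal)) is None

    def test_glucose_triggers_veto_diabetes(self):
        labs = [make_lab("GLU_FASTING", 9.8)]
        assert eval_one("L8", make_admission(labs=labs))
        assert eval_one("L8", make_admission(
            labs=labs, comorbidities={"diabetes-mellitus"})) is None

    def test_proteinuria_qualitative_or_quantitative(self):
        assert eval_one("L15", make_admission(
            labs=[make_lab("UPRO_QUAL", None, qualitative="positive")]))
        assert eval_one("L15", make_admission(
            labs=[make_lab("UPRO_QUAL", None, qualitative="negative")])) is None
        assert eval_one("L15", make_admission(labs=[make_lab("UPRO_24H", 180.0)]))

    def test_myocardial_conjunction(self):
        assert eval_one("L16", make_admission(labs=[make_lab("TNI", 0.04)]))
        # CK-MB high but CK normal: conjunction not met
        assert eval_one("L16", make_admission(
            labs=[make_lab("CKMB", 30.0), make_lab("CK", 150.0)])) is None
        assert eval_one("L16", make_admission(
            labs=[make_lab("CKMB", 30.0), make_lab("CK", 250.0)]))

    def test_thyroid_patterns_distinct(self):
        hypo = [make_lab("TSH", 5.5), make_lab("FT4", 0.6)]
        hyper = [make_lab("TSH", 0.2), make_lab("FT4", 2.2)]
        central = [make_lab("TSH", 0.2), make_lab("FT4", 0.6)]
        for labs, fires in [(hypo, "L18"), (hyper, "L19"), (central, "L21")]:
            adm = make_admission(labs=labs)
            for tid in ("L18", "L19", "L21"):
                assert (eval_one(tid, adm) is not None) == (tid == fires), (labs, tid)

    def test_adrenal_requires_morning_window(self):
        morning = [make_lab("ACTH", 5.0, hour=8), make_lab("COR", 4.0, hour=8)]
        evening = [make_lab("ACTH", 5.0, hour=16), make_lab("COR", 4.0, hour=16)]
        assert eval_one("L22", make_admission(labs=morning))
        assert eval_one("L22", make_admission(labs=evening)) is None


class TestSymptomPredicates:
    def test_fever_threshold_and_missing_attribute(self, caplog):
        hot = make_admission(events=[ClinicalEvent(
            code="fever", onset_date=ADMIT, attributes={"temperature_c": 38.9})])
        at = make_admission(events=[ClinicalEvent(
            code="fever", onset_date=ADMIT, attributes={"temperature_c": 38.2})])
        missing = make_admission(events=[ClinicalEvent(code="fever", onset_date=ADMIT)])
        assert eval_one("S1", hot)
        assert eval_one("S1", at) is None
        with caplog.at_level("WARNING"):
            assert eval_one("S1", missing) is None
        assert "temperature_c" in caplog.text

    def test_diarrhea_composite(self):
        five = make_admission(events=[ClinicalEvent(
            code="diarrhea", onset_date=ADMIT, attributes={"stools_per_day": 5})])
        four = make_admission(events=[ClinicalEvent(
            code="diarrhea", onset_date=ADMIT, attributes={"stools_per_day": 4})])
        with_companion = make_admission(events=[
            ClinicalEvent(code="diarrhea", onset_date=ADMIT,
                          attributes={"stools_per_day": 2}),
            ClinicalEvent(code="bellyache", onset_date=ADMIT)])
        companion_only = make_admission(events=[
            ClinicalEvent(code="bellyache", onset_date=ADMIT)])
        assert eval_one("S3", five)
        assert eval_one("S3", four) is None
        assert eval_one("S3", with_companion)
        assert eval_one("S3", companion_only) is None

    def test_imaging_codes_fire_lung_trigger(self):
        adm = make_admission(events=[ClinicalEvent(code="ct-patchy-nodule",
                                                   onset_date=ADMIT)])
        assert eval_one("L20", adm)


class TestMedAndInterventionPredicates:
    def _med(self, name, cls, start, stop):
        return MedicationOrder(drug_name=name, drug_class=cls,
                               is_antineoplastic=False,
                               start_date=ADMIT + timedelta(days=start),
                               stop_date=ADMIT + timedelta(days=stop))

    def test_steroid_antihistamine_overlap(self):
        overlap = make_admission(medications=[
            self._med("dexamethasone", "glucocorticoid", 1, 3),
            self._med("promethazine", "antihistamine", 3, 4)])
        disjoint = make_admission(medications=[
            self._med("dexamethasone", "glucocorticoid", 1, 2),
            self._med("promethazine", "antihistamine", 4, 5)])
        assert eval_one("T1", overlap)
        assert eval_one("T1", disjoint) is None

    def test_leucovorin_tumor_exclusions(self):
        med = self._med("calcium-leucovorin", "leucovorin", 1, 2)
        for tumor, fires in [("colorectal", False), ("gastric", False),
                             ("lung", True), ("pancreatic", True)]:
            adm = make_admission(tumor_type=tumor, medications=[med])
            assert (eval_one("T3", adm) is not None) == fires, tumor

    def test_regimen_adjustment_requires_toxicity_motive(self):
        toxic = make_admission(interventions=[InterventionEvent(
            kind="dose-reduction", date=ADMIT + timedelta(days=1),
            due_to_toxicity=True)])
        planned = make_admission(interventions=[InterventionEvent(
            kind="dose-reduction", date=ADMIT + timedelta(days=1),
            due_to_toxicity=False)])
        assert eval_one("M2", toxic)
        assert eval_one("M2", planned) is None
        icu = make_admission(interventions=[InterventionEvent(
            kind="icu-transfer", date=ADMIT + timedelta(days=1))])
        assert eval_one("M1", icu)


def _random_lab_cohort(rng, n_adm=25):
    """Random admissions whose threshold-analyte values straddle the cutoffs."""
    spans = {"HGB": (60, 160), "PLT": (10, 300), "NEUT": (0.1, 6.0),
             "WBC": (0.5, 10.0), "K": (2.5, 6.5), "CA": (1.6, 3.1),
             "GLU_FASTING": (2.5, 12.0), "UA": (150, 600)}
    cohort = []
    for i in range(n_adm):
        labs = []
        for analyte, (lo, hi) in spans.items():
            for day in range(1, 1 + rng.integers(1, 4)):
                labs.append(make_lab(analyte, float(np.round(
                    rng.uniform(lo, hi), 2)), day=day))
        cohort.append(make_admission(
            admission_id=f"r{i}", sex=["male", "female"][rng.integers(0, 2)],
            labs=labs))
    return cohort


class TestScreeningProperties:
    def test_oracle_equivalence_simple_thresholds(self):
        """Engine hits equal a brute-force scan of every lab against the cutoff."""
        rng = np.random.default_rng(42)
        checks = {"L1": ("HGB", "<", 100.0), "L2": ("PLT", "<", 100.0),
                  "L3": ("NEUT", "<", 1.8), "L4": ("WBC", "<", 4.0),
                  "L10": ("K", ">", 5.3), "L11": ("K", "<", 3.5),
                  "L12": ("CA", ">", 2.52), "L13": ("CA", "<", 2.11)}
        for _ in range(8):
            cohort = _random_lab_cohort(rng)
            hits = screen_cohort(cohort)
            engine = {(h.admission_id, h.trigger_id) for h in hits
                      if h.trigger_id in checks}
            brute = set()
            for adm in cohort:
                for tid, (analyte, op, cutoff) in checks.items():
                    vals = [l.value for l in adm.labs if l.analyte == analyte]
                    if any(v < cutoff if op == "<" else v > cutoff for v in vals):
                        brute.add((adm.admission_id, tid))
            assert engine == brute

    def test_screen_is_deterministic_and_unique(self):
        gen = generate_cohort(SynthConfig(n_admissions=50, seed=5))
        hits1 = screen_cohort(gen.cohort)
        hits2 = screen_cohort(gen.cohort)
        assert [h.model_dump() for h in hits1] == [h.model_dump() for h in hits2]
        keys = [(h.admission_id, h.trigger_id) for h in hits1]
        assert len(keys) == len(set(keys))

    def test_hits_sorted_by_admission_then_registry_order(self):
        from oncogtt.triggers import TRIGGER_ORDER
        gen = generate_cohort(SynthConfig(n_admissions=30, seed=9))
        hits = screen_cohort(gen.cohort)
        adm_order = {a.admission_id: i for i, a in enumerate(gen.cohort)}
        t_order = {t: i for i, t in enumerate(TRIGGER_ORDER)}
        keys = [(adm_order[h.admission_id], t_order[h.trigger_id]) for h in hits]
        assert keys == sorted(keys)

    def test_disabling_all_triggers_yields_no_hits(self):
        gen = generate_cohort(SynthConfig(n_admissions=20, seed=1))
        registry = [d.model_copy(update={"enabled": False})
                    for d in builtin_registry()]
        assert screen_cohort(gen.cohort, registry) == []

    def test_relaxing_cutoff_never_loses_hits(self):
        """Monotonicity: widening L1's cutoff can only add admissions."""
        rng = np.random.default_rng(7)
        cohort = _random_lab_cohort(rng, n_adm=40)
        tight = copy.deepcopy(REGISTRY["L1"])
        loose = copy.deepcopy(REGISTRY["L1"])
        loose.predicate.params["cutoff"] = 120.0
        tight_hits = {h.admission_id for h in screen_cohort(cohort, [tight])}
        loose_hits = {h.admission_id for h in screen_cohort(cohort, [loose])}
        assert tight_hits <= loose_hits

    def test_adding_trigger_never_removes_hits(self):
        rng = np.random.default_rng(13)
        cohort = _random_lab_cohort(rng, n_adm=30)
        some = [REGISTRY[t] for t in ("L1", "L2", "L3")]
        more = some + [REGISTRY["L4"]]
        base = {(h.admission_id, h.trigger_id) for h in screen_cohort(cohort, some)}
        extended = {(h.admission_id, h.trigger_id)
                    for h in screen_cohort(cohort, more)}
        assert base <= extended
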