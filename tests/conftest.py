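"""Shared fixtures: a minimal-admission factory, the replay fixture and its
pipeline outputs (session-scoped: they are deterministic and moderately
expensive to rebuild per test)."""

from __future__ import annotations

from datetime import date, datetime, time, timedelta

import pytest

from oncogtt import (
    AdmissionRecord,
    LabResult,
    MedicationOrder,
    adjudicate_hits,
    build_replay_fixture,
    compute_cohort_metrics,
    deduplicate_ades,
    filter_by_causality,
    screen_cohort,
)
from oncogtt.vocab import canonical_unit, default_ref_range

ADMIT = date(2021, 3, 1)


def make_lab(analyte: str, value, day: int = 1, hour: int = 8, minute: int = 0,
             qualitative=None, **kw) -> LabResult:
    lo, hi = default_ref_range(analyte)
    return LabResult(
        analyte=analyte, value=value, unit=canonical_unit(analyte),
        collected_at=datetime.combine(ADMIT + timedelta(days=day), time(hour, minute)),
        ref_low=kw.pop("ref_low", lo), ref_high=kw.pop("ref_high", hi),
        qualitative_result=qualitative, **kw)


def make_admission(admission_id="adm-001", age=60, sex="male", los=6,
                   tumor_type="lung", with_chemo=True, **kw) -> AdmissionRecord:
    meds = kw.pop("medications", [])
    if with_chemo:
        meds = meds + [MedicationOrder(
            drug_name="cisplatin", drug_class="platinum", is_antineoplastic=True,
            start_date=ADMIT + timedelta(days=1),
            stop_date=ADMIT + timedelta(days=2))]
    return AdmissionRecord(
        admission_id=admission_id, age=age, sex=sex, admit_date=ADMIT,
        discharge_date=ADMIT + timedelta(days=los), tumor_type=tumor_type,
        medications=meds, **kw)


@pytest.fixture(scope="session")
def replay():
    return build_replay_fixture()


@pytest.fixture(scope="session")
def replay_pipeline(replay):
    hits = screen_cohort(replay.cohort)
    candidates = adjudicate_hits(replay.cohort, hits, replay.annotations)
    unique = filter_by_causality(deduplicate_ades(candidates))
    metrics = compute_cohort_metrics(replay.cohort, hits, unique)
    return {"cohort": replay.cohort, "annotations": replay.annotations,
            "hits": hits, "candidates": candidates, "ades": unique,
            "metrics": metrics}
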