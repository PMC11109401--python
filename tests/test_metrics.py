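"""Metrics: rates, PPV accounting, distributions, univariate and logistic fits."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from oncogtt import (
    SynthConfig,
    ade_rates,
    adjudicate_hits,
    deduplicate_ades,
    filter_by_causality,
    fit_logistic,
    fit_risk_model,
    generate_cohort,
    positive_trigger_rate,
    ppv_table,
    screen_cohort,
    summarize_ades,
    univariate_screen,
)
from oncogtt.adjudication import ADERecord
from oncogtt.metrics import UndefinedMetricError, chi_square, format_ppv
from oncogtt.triggers import TriggerHit

from conftest import make_admission


def _hit(adm, tid):
    return TriggerHit(trigger_id=tid, admission_id=adm, evidence=["x:y"],
                      hit_date=date(2021, 3, 2))


def _ade(seq, adm, triggers, term="anemia", grade=2, sae=False):
    return ADERecord(ade_id=f"a{seq}", admission_id=adm, ade_term=term,
                     system_organ_class="hematologic", causality="probable",
                     ctcae_grade=grade, sae=sae, linked_triggers=set(triggers),
                     onset_date=date(2021, 3, 2),
                     suspected_drugs=[("cisplatin", "platinum")])


class TestGammaAndPPV:
    def test_gamma_counts_admissions_not_hits(self):
        cohort = [make_admission(admission_id=f"a{i}") for i in range(4)]
        hits = [_hit("a0", "L1"), _hit("a0", "L2"), _hit("a1", "L1")]
        assert positive_trigger_rate(cohort, hits) == 50.0
        assert positive_trigger_rate(cohort, []) == 0.0
        with pytest.raises(UndefinedMetricError):
            positive_trigger_rate([], hits)

    def test_ppv_accounting_and_multi_trigger_links(self):
        hits = [_hit("a0", "L1"), _hit("a1", "L1"), _hit("a0", "M2")]
        ades = [_ade(1, "a0", {"L1", "M2"})]
        rows, overall = ppv_table(hits, ades)
        by_id = {r.trigger_id: r for r in rows}
        assert by_id["L1"].positives == 2 and by_id["L1"].linked_ades == 1
        assert by_id["M2"].positives == 1 and by_id["M2"].linked_ades == 1
        # one ADE linked to two triggers counts twice in the numerator
        assert overall == pytest.approx(100.0 * 2 / 3)
        assert by_id["L2"].undefined and by_id["L2"].ppv == 0.0

    def test_overall_equals_positives_weighted_mean(self, replay_pipeline):
        rows = replay_pipeline["metrics"].per_trigger
        overall = replay_pipeline["metrics"].overall_ppv
        num = sum(r.ppv * r.positives for r in rows)
        den = sum(r.positives for r in rows)
        assert overall == pytest.approx(num / den)

    def test_orphan_link_is_a_consistency_error(self):
        with pytest.raises(ValueError, match="no hit"):
            ppv_table([_hit("a0", "L1")], [_ade(1, "a1", {"L1"})])

    def test_display_convention(self):
        assert format_ppv(91.6) == "92"
        assert format_ppv(2.857) == "2.9"
        assert format_ppv(0.0) == "0.0"


class TestRates:
    def test_rate_arithmetic(self):
        cohort = [make_admission(admission_id=f"a{i}", los=5) for i in range(20)]
        ades = [_ade(i, f"a{i % 5}", {"L1"}) for i in range(10)]
        out = ade_rates(ades, cohort)
        assert out["ades_per_100_admissions"].rate == pytest.approx(50.0)
        assert out["ades_per_1000_patient_days"].rate == pytest.approx(100.0)
        assert out["pct_admissions_with_ade"] == pytest.approx(25.0)

    def test_empty_cohort_raises(self):
        with pytest.raises(UndefinedMetricError):
            ade_rates([], [])

    @pytest.mark.parametrize("method", ["normal", "poisson"])
    def test_ci_contains_point_estimate(self, method):
        cohort = [make_admission(admission_id=f"a{i}") for i in range(30)]
        ades = [_ade(i, f"a{i % 30}", {"L1"}) for i in range(40)]
        out = ade_rates(ades, cohort, ci_method=method)
        for key in ("ades_per_100_admissions", "ades_per_1000_patient_days"):
            r = out[key]
            assert r.ci_low <= r.rate <= r.ci_high

    def test_ci_width_shrinks_like_sqrt_n(self):
        widths = {}
        for n in (200, 800):
            gen = generate_cohort(SynthConfig(n_admissions=n, seed=21))
            hits = screen_cohort(gen.cohort)
            ades = filter_by_causality(deduplicate_ades(
                adjudicate_hits(gen.cohort, hits, gen.annotations)))
            r = ade_rates(ades, gen.cohort)["ades_per_100_admissions"]
            widths[n] = r.ci_high - r.ci_low
        ratio = widths[200] / widths[800]
        assert 1.4 < ratio < 2.9        # ideal sqrt(4) = 2


class TestDistributions:
    def test_single_ade_is_its_whole_distribution(self):
        dists = summarize_ades([_ade(1, "a0", {"L1"})])
        assert dists["soc"]["hematologic"] == (1, 100.0)
        assert dists["severity"]["grade-2"] == (1, 100.0)
        assert dists["drug_category"]["platinum"] == (1, 100.0)

    def test_drug_mentions_can_exceed_ade_count(self):
        ade = _ade(1, "a0", {"L1"})
        ade.suspected_drugs = [("cisplatin", "platinum"),
                               ("fluorouracil", "antimetabolite")]
        dists = summarize_ades([ade])
        total_mentions = sum(c for c, _ in dists["drug_category"].values())
        assert total_mentions == 2 > 1

    def test_severity_and_soc_conserve_ade_count(self, replay_pipeline):
        m = replay_pipeline["metrics"]
        assert sum(c for c, _ in m.severity_distribution.values()) == m.n_unique_ades
        assert sum(c for c, _ in m.soc_distribution.values()) == m.n_unique_ades
        # per-100-admissions x N / 100 recovers the count exactly
        assert m.ades_per_100_admissions.rate * m.n_admissions / 100 == \
            pytest.approx(m.n_unique_ades)


class TestUnivariate:
    def test_chi_square_against_hand_formula(self):
        # brute force: sum (O-E)^2/E for [[20,30],[40,10]] = 16.667
        stat, p = chi_square([[20, 30], [40, 10]], yates=False)
        assert stat == pytest.approx(16.6667, abs=1e-3)
        assert p < 0.001

    def test_identical_groups_are_not_significant(self):
        stat, p = chi_square([[25, 25], [25, 25]])
        assert p == pytest.approx(1.0)

    def test_screen_runs_on_generated_cohort(self):
        gen = generate_cohort(SynthConfig(n_admissions=120, seed=3))
        hits = screen_cohort(gen.cohort)
        ades = filter_by_causality(deduplicate_ades(
            adjudicate_hits(gen.cohort, hits, gen.annotations)))
        res = univariate_screen(gen.cohort, ades, outcome="ADE")
        assert {"age", "sex", "n_combined_drugs"} <= set(res)
        for stat, p in res.values():
            assert np.isfinite(stat) and 0.0 <= p <= 1.0


def _simulate_logistic(rng, n, beta0, betas):
    X = pd.DataFrame({
        f"x{j}": rng.integers(0, 2, n) if j == 0 else rng.normal(size=n)
        for j in range(len(betas))})
    eta = beta0 + X.values @ np.array(betas)
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    return X, y.astype(int)


class TestLogistic:
    def test_planted_or_recovered_within_ci(self):
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(30):
            X, y = _simulate_logistic(rng, 1000, -0.5, [np.log(2.0), 0.3])
            fit = fit_logistic(X, y)
            or_, lo, hi, _ = fit["terms"]["x0"]
            if lo <= 2.0 <= hi:
                hits += 1
        assert hits >= 24        # nominal coverage 95%

    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(8)
        X, y = _simulate_logistic(rng, 4000, 0.0, [0.0])
        or_, lo, hi, p = fit_logistic(X, y)["terms"]["x0"]
        assert lo <= 1.0 <= hi
        assert 0.7 < or_ < 1.4

    def test_no_outcome_variation_raises(self):
        X = pd.DataFrame({"x0": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="variation"):
            fit_logistic(X, np.ones(4))

    def test_complete_separation_is_flagged(self):
        X = pd.DataFrame({"x0": [0.0] * 20 + [1.0] * 20})
        y = np.array([0] * 20 + [1] * 20)
        fit = fit_logistic(X, y)
        assert "x0" in fit["separation_flags"]
        assert "x0" not in fit["terms"]

    def test_risk_model_end_to_end(self):
        gen = generate_cohort(SynthConfig(n_admissions=150, seed=29))
        hits = screen_cohort(gen.cohort)
        ades = filter_by_causality(deduplicate_ades(
            adjudicate_hits(gen.cohort, hits, gen.annotations)))
        res = fit_risk_model(gen.cohort, ades, outcome="ADE",
                             variables=["age", "n_combined_drugs"])
        assert res.outcome == "ADE" and res.n == 150
        for or_, lo, hi, p in res.model_terms.values():
            assert 0 < lo <= or_ <= hi
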