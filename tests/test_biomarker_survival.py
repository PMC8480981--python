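import math

import numpy as np
import pytest

from chlymph.cohort_io import Compartment, Variant
from chlymph.biomarker_survival import (
    ConfusionTable,
    SurvivalRecord,
    call_multihit_tet2,
    chn_free_analysis,
    cox_hr_binary,
    diagnostic_metrics,
    km_estimate,
    logrank_test,
    reconstruct_confusion,
)
from chlymph.synthetic_cohort import simulate_survival_groups


def _ch(gene, vaf, tier=1, pos=100):
    return Variant(
        patient_id="P1", compartment=Compartment.BMPB, gene=gene, chrom="4",
        pos=pos, ref="C", alt="T", vaf=vaf, tier=tier,
    )


def _rec(time, event, group="x", pid=None):
    return SurvivalRecord(pid or f"p{time}_{event}", time, event, group)


class TestBiomarkerCall:
    def test_two_high_burden_pathogenic_tet2_is_positive(self):
        call = call_multihit_tet2([_ch("TET2", 0.20, pos=1), _ch("TET2", 0.18, pos=2)])
        assert call.positive and call.n_qualifying_tet2 == 2

    def test_each_variant_must_clear_the_vaf_bar(self):
        call = call_multihit_tet2([_ch("TET2", 0.20, pos=1), _ch("TET2", 0.10, pos=2)])
        assert not call.positive

    def test_rule_is_gene_specific(self):
        call = call_multihit_tet2(
            [_ch("TET2", 0.40, pos=1), _ch("DNMT3A", 0.30, pos=2),
             _ch("DNMT3A", 0.30, pos=3)]
        )
        assert not call.positive

    def test_vaf_threshold_inclusive_at_fifteen_percent(self):
        call = call_multihit_tet2([_ch("TET2", 0.15, pos=1), _ch("TET2", 0.15, pos=2)])
        assert call.positive

    def test_non_pathogenic_tiers_do_not_count(self):
        call = call_multihit_tet2([_ch("TET2", 0.3, tier=3, pos=1),
                                   _ch("TET2", 0.3, tier=None, pos=2)])
        assert call.n_qualifying_tet2 == 0

    def test_empty_input_is_negative(self):
        assert not call_multihit_tet2([]).positive


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        recs = [_rec(t, 0) for t in (3, 6, 9, 12, 15)]
        km = km_estimate(recs)
        assert np.all(km.survival == 1.0)

    def test_single_event_among_four(self):
        recs = [_rec(10, 1), _rec(12, 0), _rec(15, 0), _rec(20, 0)]
        km = km_estimate(recs)
        assert km.survival[np.searchsorted(km.times, 10)] == pytest.approx(0.75)

    def test_worked_product_limit_example(self):
        # hand computation: S(5)=5/6, S(12)=5/6*2/4=5/12, S(30)=0
        recs = [_rec(5, 1), _rec(8, 0), _rec(12, 1, pid="c"), _rec(12, 1, pid="d"),
                _rec(20, 0), _rec(30, 1)]
        km = km_estimate(recs)
        lookup = dict(zip(km.times, km.survival))
        assert lookup[5.0] == pytest.approx(5 / 6)
        assert lookup[12.0] == pytest.approx(5 / 12)
        assert lookup[30.0] == pytest.approx(0.0)
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            _rec(-1, 0)


class TestLogrank:
    def test_identical_groups_score_zero(self):
        a = [_rec(5, 1), _rec(10, 0), _rec(15, 1)]
        out = logrank_test(a, list(a))
        assert out["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert out["p_value"] == pytest.approx(1.0)

    def test_worked_example_matches_hand_computation(self):
        # O_A=2, E_A=0.5+0.4+2/3, V=0.25+0.24+2/9 -> chi2=0.26365, p=0.6076
        a = [_rec(5, 1), _rec(10, 0), _rec(15, 1)]
        b = [_rec(7, 1), _rec(15, 1), _rec(20, 0)]
        out = logrank_test(a, b)
        assert out["chi2"] == pytest.approx(0.2636505, abs=1e-6)
        assert out["p_value"] == pytest.approx(0.607623, abs=1e-5)

    def test_zero_events_warns_p_one(self):
        with pytest.warns(UserWarning):
            out = logrank_test([_rec(5, 0)], [_rec(7, 0)])
        assert out["p_value"] == 1.0

    def test_large_hazard_ratio_detected(self):
        hits = 0
        for seed in range(20):
            recs = simulate_survival_groups(100, 14.0, seed=seed)
            a = [r for r in recs if r.group == "high_burden"]
            b = [r for r in recs if r.group == "low_or_absent"]
            if logrank_test(a, b)["p_value"] < 0.001:
                hits += 1
        assert hits == 20


class TestCox:
    def test_exchangeable_groups_give_unit_hazard(self):
        recs = simulate_survival_groups(200, 1.0, seed=3)
        res = cox_hr_binary(recs)
        assert res.ci_low < 1.0 < res.ci_high

    def test_time_rescaling_leaves_hr_invariant(self):
        recs = simulate_survival_groups(100, 5.0, seed=4)
        scaled = [
            SurvivalRecord(r.patient_id, r.time_months * 10, r.event, r.group)
            for r in recs
        ]
        assert cox_hr_binary(recs).hr == pytest.approx(cox_hr_binary(scaled).hr,
                                                       rel=1e-6)

    def test_zero_events_rejected(self):
        recs = [_rec(5, 0, "a"), _rec(7, 0, "b")]
        with pytest.raises(ValueError):
            cox_hr_binary(recs)

    def test_complete_separation_flagged(self):
        recs = [SurvivalRecord(f"h{i}", 5.0 + i, 1, "high_burden") for i in range(5)]
        recs += [SurvivalRecord(f"l{i}", 50.0 + i, 0, "low_or_absent") for i in range(5)]
        res = cox_hr_binary(recs)
        assert res.monotone_likelihood
        assert math.isinf(res.ci_high)


class TestConfusion:
    def test_reconstruction_unique_for_printed_metrics(self):
        tables = reconstruct_confusion(47, 72.7, 97.2)
        assert tables == [ConfusionTable(tp=8, fp=1, fn=3, tn=35)]

    def test_metrics_of_reconstructed_table(self):
        m = diagnostic_metrics(ConfusionTable(tp=8, fp=1, fn=3, tn=35))
        assert m == {"sensitivity": 72.7, "specificity": 97.2,
                     "ppv": 88.9, "npv": 92.1}

    def test_perfect_classifier(self):
        m = diagnostic_metrics(ConfusionTable(tp=5, fp=0, fn=0, tn=5))
        assert all(v == 100.0 for v in m.values())

    def test_zero_denominator_reported_as_missing(self):
        m = diagnostic_metrics(ConfusionTable(tp=0, fp=0, fn=2, tn=5))
        assert m["ppv"] is None

    def test_perfect_metrics_force_empty_error_cells(self):
        for t in reconstruct_confusion(4, 100.0, 100.0):
            assert t.fn == 0 and t.fp == 0

    def test_impossible_metrics_give_no_tables(self):
        assert reconstruct_confusion(3, 50.0, 50.0) == []

    def test_reconstruction_roundtrips_through_metrics(self):
        for n, sens, spec in [(47, 72.7, 97.2), (20, 75.0, 90.0), (10, 50.0, 50.0)]:
            for t in reconstruct_confusion(n, sens, spec):
                m = diagnostic_metrics(t)
                assert m["sensitivity"] == sens and m["specificity"] == spec


class TestFullAnalysis:
    def test_all_negative_cohort_skips_comparisons(self):
        from chlymph.biomarker_survival import BiomarkerCall

        recs = [_rec(10, 1, pid="a"), _rec(20, 0, pid="b")]
        calls = {p: BiomarkerCall(p, False, 0, ()) for p in ("a", "b")}
        with pytest.warns(UserWarning):
            report = chn_free_analysis(recs, calls)
        assert report["logrank"] is None and report["cox"] is None

    def test_groups_with_strong_effect_produce_full_report(self):
        from chlymph.biomarker_survival import BiomarkerCall

        recs = simulate_survival_groups(60, 14.0, seed=6)
        calls = {
            r.patient_id: BiomarkerCall(r.patient_id, r.group == "high_burden", 2, ())
            for r in recs
        }
        report = chn_free_analysis(recs, calls)
        assert report["logrank"]["p_value"] < 0.001
        assert report["cox"].hr > 1
        assert report["confusion"].total == 120
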