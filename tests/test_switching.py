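"""Contrast intersection and switch-toward-non-tumor classification."""

import math
from itertools import product

import pytest

from spliceswitch import (
    ContrastResult,
    DifferentialCall,
    classify_switch,
    intersect_contrasts,
    overlap_significance,
    switch_summary,
    switched_category_enrichment,
)
from spliceswitch.models import SwitchCall


def _call(event_id, dpsi, significant=True, category="SE", testable=True):
    if not testable:
        return DifferentialCall(
            event_id=event_id, category=category, gene_id=f"g_{event_id}",
            bf=math.nan, delta_psi_pooled=math.nan, replicate_delta_psis=(),
            direction="none", significant=False, testable=False,
        )
    direction = (
        ("included" if dpsi > 0 else "excluded") if significant else "none"
    )
    return DifferentialCall(
        event_id=event_id, category=category, gene_id=f"g_{event_id}",
        bf=40.0 if significant else 2.0, delta_psi_pooled=dpsi,
        replicate_delta_psis=(dpsi,) * 3, direction=direction,
        significant=significant,
    )


def _contrast(label, calls):
    return ContrastResult(contrast_label=label, calls=calls)


class TestIntersect:
    def test_overlap_by_event_id(self):
        treatment = _contrast("t", [_call("e1", 0.3), _call("e2", 0.2)])
        disease = _contrast("d", [_call("e2", -0.4), _call("e3", 0.1)])
        shared = intersect_contrasts(treatment, disease)
        assert [s["event_id"] for s in shared] == ["e2"]
        assert shared[0]["treat_dpsi"] == 0.2
        assert shared[0]["disease_dpsi"] == -0.4

    def test_identical_sets_share_everything(self):
        calls = [_call("e1", 0.3), _call("e2", -0.2)]
        shared = intersect_contrasts(_contrast("t", calls), _contrast("d", calls))
        assert len(shared) == 2

    def test_empty_disease_set_yields_empty_intersection(self):
        treatment = _contrast("t", [_call("e1", 0.3)])
        disease = _contrast("d", [_call("e1", 0.3, significant=False)])
        assert intersect_contrasts(treatment, disease) == []

    def test_disjoint_event_spaces_warn_and_return_empty(self, caplog):
        treatment = _contrast("t", [_call("e1", 0.3)])
        disease = _contrast("d", [_call("x9", 0.3)])
        with caplog.at_level("WARNING"):
            assert intersect_contrasts(treatment, disease) == []
        assert any("share no event ids" in r.message for r in caplog.records)


class TestClassify:
    def test_opposed_signs_switch(self):
        calls = classify_switch(
            [{"event_id": "e", "category": "SE", "treat_dpsi": -0.3, "disease_dpsi": 0.4}]
        )
        assert calls[0].switched

    def test_same_signs_do_not_switch(self):
        calls = classify_switch(
            [{"event_id": "e", "category": "SE", "treat_dpsi": 0.3, "disease_dpsi": 0.4}]
        )
        assert not calls[0].switched

    def test_all_sign_combinations_brute_force(self):
        """Exactly the two opposed sign pairs switch; zeros never do."""
        for t, d in product((-0.3, 0.0, 0.3), repeat=2):
            rec = {"event_id": "e", "category": "SE", "treat_dpsi": t, "disease_dpsi": d}
            expected = t != 0 and d != 0 and (t > 0) != (d > 0)
            assert classify_switch([rec])[0].switched == expected

    def test_magnitude_restoration_mode_vetoes_partial_switches(self):
        recs = [
            {"event_id": "a", "category": "SE", "treat_dpsi": -0.38, "disease_dpsi": 0.4},
            {"event_id": "b", "category": "SE", "treat_dpsi": -0.05, "disease_dpsi": 0.4},
        ]
        loose = classify_switch(recs)
        strict = classify_switch(recs, require_magnitude_restoration=True,
                                 magnitude_tolerance=0.1)
        assert [c.switched for c in loose] == [True, True]
        assert [c.switched for c in strict] == [True, False]

    def test_negating_both_contrasts_preserves_switch_set(self):
        recs = [
            {"event_id": f"e{i}", "category": "SE",
             "treat_dpsi": t, "disease_dpsi": d}
            for i, (t, d) in enumerate([(0.2, -0.3), (0.2, 0.3), (-0.1, -0.4)])
        ]
        flipped = [
            {**r, "treat_dpsi": -r["treat_dpsi"], "disease_dpsi": -r["disease_dpsi"]}
            for r in recs
        ]
        assert [c.switched for c in classify_switch(recs)] == [
            c.switched for c in classify_switch(flipped)
        ]

    def test_negating_one_contrast_complements_switch_set(self):
        recs = [
            {"event_id": f"e{i}", "category": "SE",
             "treat_dpsi": t, "disease_dpsi": d}
            for i, (t, d) in enumerate([(0.2, -0.3), (0.2, 0.3), (-0.1, -0.4)])
        ]
        flipped = [{**r, "treat_dpsi": -r["treat_dpsi"]} for r in recs]
        assert [c.switched for c in classify_switch(recs)] == [
            not c.switched for c in classify_switch(flipped)
        ]


class TestSummary:
    def test_printed_count_arithmetic(self):
        """254 switched of 406 shared of 2409 treatment-affected events."""
        summary = switch_summary(2409, 406, 254)
        assert summary.pct_shared_of_treatment == pytest.approx(16.85, abs=0.01)
        assert summary.pct_switched_of_shared == pytest.approx(62.56, abs=0.01)
        assert round(summary.pct_shared_of_treatment) == 17
        assert round(summary.pct_switched_of_shared) == 63

    def test_zero_switched(self):
        assert switch_summary(100, 10, 0).pct_switched_of_shared == 0.0

    def test_all_switched(self):
        assert switch_summary(100, 10, 10).pct_switched_of_shared == 100.0

    def test_zero_denominators_are_undefined(self):
        summary = switch_summary(0, 0, 0)
        assert math.isnan(summary.pct_shared_of_treatment)
        assert math.isnan(summary.pct_switched_of_shared)

    def test_partition_of_shared_events(self, sim_main):
        treatment, disease = sim_main["treatment"], sim_main["disease"]
        shared = intersect_contrasts(treatment, disease)
        calls = classify_switch(shared)
        n_switched = sum(c.switched for c in calls)
        n_not = sum(not c.switched for c in calls)
        assert n_switched + n_not == len(shared)
        summary = switch_summary(treatment, shared, calls)
        assert summary.n_switched <= summary.n_shared <= summary.n_treatment_significant


class TestCategoryEnrichment:
    def test_identical_distributions_are_null(self):
        calls = [
            SwitchCall(f"e{i}", cat, -0.3, 0.4, True)
            for i, cat in enumerate(["SE"] * 40 + ["RI"] * 40)
        ]
        out = switched_category_enrichment(calls, {"SE": 400, "RI": 400})
        assert out["SE"][1] == pytest.approx(1.0, abs=0.05)
        assert out["RI"][1] == pytest.approx(1.0, abs=0.05)

    def test_concentrated_category_is_flagged(self):
        calls = [SwitchCall(f"e{i}", "RI", -0.3, 0.4, True) for i in range(60)]
        disease_counts = {c: 100 for c in ("SE", "RI", "A5SS", "A3SS", "MXE", "AFE", "ALE")}
        out = switched_category_enrichment(calls, disease_counts)
        assert out["RI"][1] < 0.05
        # cross-check against Fisher on the same 2x2 table
        from scipy.stats import fisher_exact
        fisher_p = fisher_exact([[60, 0], [100, 600]])[1]
        assert fisher_p < 0.05

    def test_no_switched_events_is_untested(self):
        out = switched_category_enrichment([], {"SE": 10})
        assert math.isnan(out["SE"][0])

    def test_absent_category_is_untested(self):
        calls = [SwitchCall("e1", "SE", -0.3, 0.4, True)] * 1
        out = switched_category_enrichment(calls, {"SE": 10, "MXE": 0})
        assert math.isnan(out["MXE"][0])


class TestRecoveryAndOverlap:
    def test_planted_switch_fraction_recovered(self, sim_switch):
        """With 60% of jointly differential events planted as switches, the
        switched share of the shared set lands within 5 points of 60."""
        joint = [
            t for t in sim_switch["truth"]
            if t.is_differential_treatment and t.is_differential_disease
        ]
        assert len(joint) >= 1000
        shared = intersect_contrasts(sim_switch["treatment"], sim_switch["disease"])
        calls = classify_switch(shared)
        summary = switch_summary(sim_switch["treatment"], shared, calls)
        assert abs(summary.pct_switched_of_shared - 60.0) <= 5.0

    def test_overlap_counts_reflect_the_contrasts(self, sim_switch):
        """The shared-set test runs at event granularity on the universe of
        events testable in both contrasts; the simulator plants the two
        contrasts independently, so the overlap sits at chance level."""
        treatment, disease = sim_switch["treatment"], sim_switch["disease"]
        res = overlap_significance(treatment, disease)
        universe = {c.event_id for c in treatment.calls if c.testable} & {
            c.event_id for c in disease.calls if c.testable
        }
        assert res.N == len(universe)
        assert res.n == len(
            {c.event_id for c in treatment.significant_calls()} & universe
        )
        assert res.K == len(
            {c.event_id for c in disease.significant_calls()} & universe
        )
        assert res.k == len(intersect_contrasts(treatment, disease))
        assert res.p_value > 1e-6  # no planted correlation between contrasts

    def test_constructed_excess_overlap_is_extreme(self):
        """When the significant sets coincide far beyond chance the
        event-level hypergeometric p collapses, the published p < 2.2e-16
        situation."""
        treatment_calls = [
            _call(f"e{i}", 0.3, significant=(i < 100)) for i in range(1000)
        ]
        disease_calls = [
            _call(f"e{i}", -0.3, significant=(i < 100)) for i in range(1000)
        ]
        res = overlap_significance(
            _contrast("t", treatment_calls), _contrast("d", disease_calls)
        )
        assert res.k == 100
        assert res.p_value < 2.2e-16
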