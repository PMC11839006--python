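"""Cohort selection, silver standards, metrics, and error tallies."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from notefact.errors import PatternError, SpecError, UnitMismatchError
from notefact.evaluate import (
    GOLD,
    PRED,
    SILVER,
    AnnotationSet,
    ConfusionCounts,
    DxRecord,
    ErrorRecord,
    EvalSpec,
    MetricReport,
    PRF,
    Sampling,
    aggregate,
    build_report,
    compare_gold_silver,
    confusion,
    cross_site_report,
    derive_silver,
    f1_from_pr,
    match_code_pattern,
    prf_from_counts,
    render_report,
    round3,
    select_cohort,
    tally_errors,
)

# ICD wildcard patterns used in published cohort definitions
COHORT_PATTERNS = ("F11.*", "F14.*", "F15.*", "T40.*", "T43.6*")


class TestMatchCodePattern:
    @pytest.mark.parametrize(
        "code,pattern,expected",
        [
            ("F11.20", "F11.*", True),
            ("T43.61", "T43.6*", True),
            ("T43.8", "T43.6*", False),
            ("G90.51", "G90.5*", True),
            ("F14.10", "F14.*", True),
            ("F13.10", "F14.*", False),
            ("337.21", "337.2*", True),
            ("350.1", "350.1", True),
            ("350.11", "350.1", False),  # literal pattern, no wildcard
            ("f11.20", "F11.*", True),  # case-insensitive
            ("F11", "F11.*", True),  # dot-aware bare stem
            ("F112", "F11.*", False),
        ],
    )
    def test_prefix_semantics(self, code, pattern, expected):
        assert match_code_pattern(code, pattern) is expected

    def test_star_must_be_final(self):
        with pytest.raises(PatternError):
            match_code_pattern("F11.20", "F1*.20")


class TestSelectCohort:
    DX = [
        DxRecord(1, "E11.9"),
        DxRecord(2, "F14.10"),
        DxRecord(2, "I10"),
        DxRecord(3, "Z00.00"),
    ]

    def test_one_matching_patient(self):
        spec = EvalSpec(cohort_patterns=COHORT_PATTERNS)
        assert select_cohort(self.DX, spec) == [2]

    def test_no_matches_warns_empty(self, caplog):
        spec = EvalSpec(cohort_patterns=("Q99.*",))
        with caplog.at_level("WARNING"):
            assert select_cohort(self.DX, spec) == []
        assert any("no patients" in r.message for r in caplog.records)

    def test_random_sampling_is_seeded(self):
        dx = [DxRecord(i, "F11.20") for i in range(50)]
        spec = EvalSpec(
            cohort_patterns=("F11.*",),
            sampling=Sampling(method="random_n", n=10, seed=5),
        )
        first = select_cohort(dx, spec)
        assert len(first) == 10
        assert select_cohort(dx, spec) == first

    def test_empty_pattern_list_rejected(self):
        with pytest.raises(SpecError):
            EvalSpec(cohort_patterns=())


class TestDeriveSilver:
    DX = [
        DxRecord(1, "T40.1X1A"),
        DxRecord(1, "I10"),
        DxRecord(2, "E11.9"),
        DxRecord(3, "F11.20"),
    ]
    RULE = {"T40.*": "OOD", "F11.*": "OUD"}

    def test_labels_from_structured_codes(self):
        spec = EvalSpec(cohort_patterns=COHORT_PATTERNS)
        silver = derive_silver(self.DX, spec, self.RULE)
        assert silver.standard == SILVER and silver.unit == "document"
        assert silver.labels[("1", "OOD")] == 1
        assert silver.labels[("1", "OUD")] == 0
        assert silver.labels[("2", "OOD")] == 0  # no qualifying codes
        assert silver.labels[("3", "OUD")] == 1

    def test_pure_function_of_inputs(self):
        spec = EvalSpec(cohort_patterns=COHORT_PATTERNS)
        assert derive_silver(self.DX, spec, self.RULE) == derive_silver(
            self.DX, spec, self.RULE
        )

    def test_contradictory_rules_rejected(self):
        spec = EvalSpec(cohort_patterns=COHORT_PATTERNS)
        with pytest.raises(SpecError, match="contradictory"):
            derive_silver(
                self.DX, spec, [("T40.*", "OOD"), ("t40.*", "NOT_OOD")]
            )


def _doc_set(positives, negatives=(), standard=GOLD):
    labels = {key: 1 for key in positives}
    labels.update({key: 0 for key in negatives})
    return AnnotationSet(standard, "document", labels)


class TestConfusion:
    def test_identity(self):
        ref = _doc_set({(f"d{i}", "C") for i in range(10)})
        pred = _doc_set(ref.positives(), standard=PRED)
        per, pooled = confusion(pred, ref)
        assert pooled == ConfusionCounts(tp=10)

    def test_empty_prediction(self):
        ref = _doc_set({(f"d{i}", "C") for i in range(4)})
        pred = AnnotationSet(PRED, "document", {})
        _, pooled = confusion(pred, ref)
        assert (pooled.tp, pooled.fn, pooled.fp) == (0, 4, 0)

    def test_hand_built_8_2_2(self):
        ref = _doc_set({(f"d{i}", "C") for i in range(10)})
        pred_keys = {(f"d{i}", "C") for i in range(8)} | {("x1", "C"), ("x2", "C")}
        _, pooled = confusion(_doc_set(pred_keys, standard=PRED), ref)
        assert (pooled.tp, pooled.fp, pooled.fn) == (8, 2, 2)
        assert prf_from_counts(pooled) == pytest.approx(PRF(0.8, 0.8, 0.8))

    def test_unit_mismatch(self):
        pred = AnnotationSet(PRED, "mention", {("d1", 0, 3, "C"): 1})
        ref = _doc_set({("d1", "C")})
        with pytest.raises(UnitMismatchError):
            confusion(pred, ref)

    def test_mention_overlap_vs_exact(self):
        ref = AnnotationSet(GOLD, "mention", {("d1", 10, 17, "C"): 1})
        pred = AnnotationSet(PRED, "mention", {("d1", 12, 20, "C"): 1})
        _, loose = confusion(pred, ref)
        assert loose.tp == 1
        _, strict = confusion(pred, ref, exact_span=True)
        assert (strict.tp, strict.fp, strict.fn) == (0, 1, 1)

    def test_mention_concept_must_agree(self):
        ref = AnnotationSet(GOLD, "mention", {("d1", 10, 17, "C"): 1})
        pred = AnnotationSet(PRED, "mention", {("d1", 10, 17, "D"): 1})
        _, pooled = confusion(pred, ref)
        assert (pooled.tp, pooled.fp, pooled.fn) == (0, 1, 1)


class TestMetricArithmetic:
    def test_prf_zero_convention(self):
        assert prf_from_counts(ConfusionCounts()) == PRF(0.0, 0.0, 0.0)

    def test_prf_perfect(self):
        assert prf_from_counts(ConfusionCounts(tp=10)) == PRF(1.0, 1.0, 1.0)

    def test_f1_zero_when_both_zero(self):
        assert f1_from_pr(0.0, 0.0) == 0.0

    def test_f1_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            f1_from_pr(1.2, 0.5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
    )
    def test_f1_consistent_and_bounded(self, tp, fp, fn):
        """f1_from_pr agrees with prf_from_counts and F1 lies between
        min and max of precision and recall."""
        p, r, f = prf_from_counts(ConfusionCounts(tp=tp, fp=fp, fn=fn))
        assert f1_from_pr(p, r) == pytest.approx(f)
        assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12


class TestAggregate:
    def test_single_concept_micro_equals_macro(self):
        per = {"C": ConfusionCounts(tp=8, fp=2, fn=2)}
        assert aggregate(per, "micro") == aggregate(per, "macro")

    def test_two_concept_hand_arithmetic(self):
        per = {
            "A": ConfusionCounts(tp=10, fp=0, fn=0),
            "B": ConfusionCounts(tp=0, fp=10, fn=10),
        }
        micro = aggregate(per, "micro")
        macro = aggregate(per, "macro")
        assert micro.precision == pytest.approx(0.5)
        assert macro.precision == pytest.approx(0.5)

    def test_imbalanced_fixture_separates_micro_from_macro(self):
        per = {
            "A": ConfusionCounts(tp=90, fp=10, fn=0),  # p=0.9
            "B": ConfusionCounts(tp=1, fp=9, fn=0),  # p=0.1
        }
        micro = aggregate(per, "micro")
        macro = aggregate(per, "macro")
        assert micro.precision == pytest.approx(91 / 110)
        assert macro.precision == pytest.approx(0.5)
        assert micro != macro

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate({}, "micro")


class TestCompareGoldSilver:
    def test_identical_sets_agree_fully(self):
        gold = _doc_set({("d1", "C"), ("d2", "C")}, negatives={("d3", "C")})
        silver = _doc_set(
            {("d1", "C"), ("d2", "C")}, negatives={("d3", "C")}, standard=SILVER
        )
        rep = compare_gold_silver(gold, silver)
        assert rep.percent_agreement == 1.0
        assert rep.precision == 1.0 and rep.recall == 1.0

    def test_silver_missing_one_of_ten(self):
        gold = _doc_set({(f"d{i}", "C") for i in range(10)})
        silver = _doc_set(
            {(f"d{i}", "C") for i in range(9)},
            negatives={("d9", "C")},
            standard=SILVER,
        )
        rep = compare_gold_silver(gold, silver)
        assert rep.recall == pytest.approx(0.9)

    def test_disjoint_doc_sets_raise(self):
        gold = _doc_set({("a", "C")})
        silver = _doc_set({("b", "C")}, standard=SILVER)
        with pytest.raises(ValueError, match="disjoint"):
            compare_gold_silver(gold, silver)


class TestErrorTaxonomy:
    def test_empty_tally_is_zero_filled(self):
        assert tally_errors([]) == {
            "LOGIC": 0, "LINGUISTIC": 0, "CONTEXTUAL": 0, "ANNOTATION": 0,
        }

    def test_counts_sum_and_zero_fill(self):
        records = [
            ErrorRecord("LOGIC", "d1"),
            ErrorRecord("LOGIC", "d2"),
            ErrorRecord("CONTEXTUAL", "d3"),
        ]
        counts = tally_errors(records)
        assert counts == {
            "LOGIC": 2, "LINGUISTIC": 0, "CONTEXTUAL": 1, "ANNOTATION": 0,
        }
        assert sum(counts.values()) == len(records)

    def test_unknown_category_rejected_at_ingest(self):
        with pytest.raises(ValueError):
            ErrorRecord("OTHER", "d1")

    def test_breakdown_by_task(self):
        records = [
            ErrorRecord("LOGIC", "d1", task="sleep"),
            ErrorRecord("LINGUISTIC", "d2", task="housing"),
        ]
        nested = tally_errors(records, by="task")
        assert nested["sleep"]["LOGIC"] == 1
        assert nested["housing"]["LINGUISTIC"] == 1


def _report(site, tp, fp, fn):
    per = {"C": ConfusionCounts(tp=tp, fp=fp, fn=fn)}
    return MetricReport(
        site_id=site,
        per_concept={"C": prf_from_counts(per["C"])},
        micro=aggregate(per, "micro"),
        macro=aggregate(per, "macro"),
    )


class TestCrossSiteReport:
    def test_three_site_table(self):
        table = cross_site_report(
            [_report("Pitt", 9, 1, 1), _report("UF", 8, 2, 2), _report("UTH", 7, 3, 3)]
        )
        assert list(table.columns) == ["Pitt", "UF", "UTH"]
        assert list(table.index) == ["F1", "Recall", "Precision"]

    def test_single_site_matches_its_report(self):
        rep = _report("solo", 8, 2, 2)
        table = cross_site_report([rep])
        assert table.loc["Precision", "solo"] == round3(rep.micro.precision)

    def test_duplicate_site_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cross_site_report([_report("A", 1, 0, 0), _report("A", 2, 0, 0)])

    def test_rounding_is_half_up(self):
        assert round3(0.95779) == 0.958
        assert round3(0.0005) == 0.001  # half-up, not banker's
        assert f"{round3(0.95779):.3f}" == "0.958"

    def test_render_uses_three_decimals(self):
        text = render_report(cross_site_report([_report("A", 8, 2, 2)]))
        assert "0.800" in text


def test_build_report_from_annotation_sets():
    ref = _doc_set({("d1", "A"), ("d2", "B")}, negatives={("d3", "A")})
    pred = _doc_set({("d1", "A"), ("d3", "A")}, standard=PRED)
    rep = build_report("site1", pred, ref)
    assert rep.per_concept["A"].precision == pytest.approx(0.5)
    assert rep.micro.recall == pytest.approx(0.5)


def test_annotation_set_csv_round_trip(tmp_path):
    gold = AnnotationSet(
        GOLD, "mention", {("d1", 3, 10, "SLEEP:SNORING"): 1, ("d2", 0, 4, "X:Y"): 1}
    )
    path = tmp_path / "gold.csv"
    gold.to_csv(path)
    assert AnnotationSet.from_csv(path) == gold
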