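"""observation_fact encoding: templates, round-trips, instance grouping."""

from __future__ import annotations

import random
from datetime import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_doc

from notefact.cdm import (
    EncodeOptions,
    NOT_NLP,
    NoteTypeCode,
    NumericAttribute,
    ObservationFact,
    emit_sql,
    encode_concept_cd,
    encode_mentions,
    encode_modifier_cd,
    mention_to_facts,
    parse_concept_cd,
    partition_codes,
    read_facts,
    write_facts,
)
from notefact.errors import ConceptParseError, EncodingError
from notefact.extract import Mention
from notefact.ruleset import ConceptRef


class TestEncodeConceptCd:
    def test_standard_template(self):
        ref = ConceptRef.standard("ICD-10-CM", "S92.4")
        assert encode_concept_cd(ref, "001") == "NLP|001|ICD-10-CM:S92.4"

    def test_custom_template(self):
        ref = ConceptRef.custom("SLEEP", "SNORING")
        assert encode_concept_cd(ref, "001") == "NLP|001|CUSTOM|SLEEP:SNORING"

    def test_over_length_is_error_not_truncation(self):
        ref = ConceptRef.custom("SLEEP", "X" * 60)
        with pytest.raises(EncodingError, match="exceeds"):
            encode_concept_cd(ref, "001")
        assert len(encode_concept_cd(ref, "001", max_len=100)) > 50

    def test_non_digit_project_num(self):
        with pytest.raises(EncodingError):
            encode_concept_cd(ConceptRef.custom("SLEEP", "SNORING"), "0a1")


class TestParseConceptCd:
    def test_standard(self):
        ref, num = parse_concept_cd("NLP|001|ICD-10-CM:S92.4")
        assert ref == ConceptRef.standard("ICD-10-CM", "S92.4")
        assert num == "001"

    def test_structured_code_is_not_nlp(self):
        assert parse_concept_cd("ICD10CM:S92.4") is NOT_NLP

    @pytest.mark.parametrize(
        "bad",
        [
            "NLP|001|CUSTOM|SLEEP",  # missing :CONCEPT
            "NLP|001",  # too few parts
            "NLP|001|A|B|C",  # too many parts
            "NLP|ab1|ICD-10-CM:S92.4",  # non-digit project
            "NLP|001|ICD-10-CM",  # missing :code
        ],
    )
    def test_malformed_nlp_codes_raise(self, bad):
        with pytest.raises(ConceptParseError):
            parse_concept_cd(bad)

    def test_prefix_filter_partitions_mixed_table(self):
        nlp_codes = ["NLP|001|CUSTOM|SLEEP:SNORING", "NLP|002|ICD-10-CM:S92.4"]
        structured = ["ICD10CM:S92.4", "LOINC:59258-4", "DEM|SEX:F"]
        got_nlp, got_other = partition_codes(nlp_codes + structured)
        assert got_nlp == nlp_codes
        assert got_other == structured


@st.composite
def concept_refs(draw):
    token = st.from_regex(r"[A-Z0-9][A-Z0-9_]{0,7}", fullmatch=True)
    if draw(st.booleans()):
        vocab = draw(st.sampled_from(["ICD-10-CM", "ICD-9-CM", "LOINC", "RXNORM"]))
        code = draw(
            st.text(
                alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789.-",
                min_size=1,
                max_size=8,
            )
        )
        return ConceptRef.standard(vocab, code)
    return ConceptRef.custom(draw(token), draw(token))


@settings(max_examples=300, deadline=None, derandomize=True)
@given(concept_refs(), st.integers(min_value=0, max_value=999))
def test_encode_parse_round_trip(ref, num):
    project = f"{num:03d}"
    assert parse_concept_cd(encode_concept_cd(ref, project)) == (ref, project)


class TestModifierCd:
    def test_experiencer_patient(self):
        assert encode_modifier_cd("EXPERIENCER", "PATIENT") == "NLP|EXPERIENCER:PATIENT"

    def test_certainty_negated(self):
        assert encode_modifier_cd("CERTAINTY", "NEGATED") == "NLP|CERTAINTY:NEGATED"

    @pytest.mark.parametrize("attr,val", [("", "X"), ("X", ""), ("A|B", "X"), ("A", "B:C")])
    def test_bad_tokens_raise(self, attr, val):
        with pytest.raises(EncodingError):
            encode_modifier_cd(attr, val)


def _mention(doc=None, concept=None, **attrs) -> Mention:
    doc = doc or make_doc("Patient denies snoring today.")
    concept = concept or ConceptRef.custom("SLEEP", "SNORING")
    return Mention(
        doc=doc,
        start=15,
        end=22,
        matched_text=doc.text[15:22],
        concept=concept,
        sentence_snippet=doc.text,
        **attrs,
    )


class TestMentionToFacts:
    def test_base_plus_one_row_per_attribute(self):
        facts = mention_to_facts(_mention(), EncodeOptions(project_num="001"))
        assert len(facts) == 4  # 1 base + 3 contextual attributes
        assert facts[0].modifier_cd == "@"
        modifiers = {f.modifier_cd for f in facts[1:]}
        assert modifiers == {
            "NLP|CERTAINTY:POSITIVE",
            "NLP|EXPERIENCER:PATIENT",
            "NLP|TEMPORALITY:PRESENT",
        }
        assert len({
            (f.patient_num, f.encounter_num, f.concept_cd, f.start_date, f.instance_num)
            for f in facts
        }) == 1

    def test_blob_policy(self):
        m = _mention()
        off = mention_to_facts(m, EncodeOptions(project_num="001"))
        assert all(f.observation_blob == "" for f in off)
        on = mention_to_facts(
            m, EncodeOptions(project_num="001", include_blob=True)
        )
        assert on[0].observation_blob == m.sentence_snippet
        assert all(f.observation_blob == "" for f in on[1:])

    def test_numeric_attribute_row(self):
        facts = mention_to_facts(
            _mention(concept=ConceptRef.custom("MEDS", "ASPIRIN")),
            EncodeOptions(project_num="001"),
            numeric_attributes=(NumericAttribute("DOSE", 325.0, "mg", "325 mg QD PO"),),
        )
        (dose_row,) = [f for f in facts if f.valtype_cd == "N"]
        assert dose_row.modifier_cd == "NLP|DOSE:VALUE"
        assert dose_row.nval_num == 325.0
        assert dose_row.tval_char == "mg"

    def test_extended_columns_carry_query_id_and_note_type(self):
        facts = mention_to_facts(
            _mention(),
            EncodeOptions(project_num="001", cohort_query_id="Q1234"),
        )
        assert all(f.cohort_query_id == "Q1234" for f in facts)
        assert all(f.note_type_cd == "CUS|PROGRESS" for f in facts)
        plain = mention_to_facts(
            _mention(),
            EncodeOptions(project_num="001", cohort_query_id="Q1234",
                          extended_columns=False),
        )
        assert all(f.cohort_query_id == "" and f.note_type_cd == "" for f in plain)


def test_instance_num_counts_per_mention_group():
    """Grouping an encoded table by (patient, encounter, concept_cd,
    start_date, instance_num) recovers exactly one group per mention."""
    doc = make_doc("snoring early then snoring again then snoring late.")
    concept = ConceptRef.custom("SLEEP", "SNORING")
    mentions = [
        Mention(doc=doc, start=s, end=s + 7, matched_text="snoring", concept=concept)
        for s in (0, 19, 38)
    ]
    facts = encode_mentions(mentions, EncodeOptions(project_num="001"))
    groups = {
        (f.patient_num, f.encounter_num, f.concept_cd, f.start_date, f.instance_num)
        for f in facts
    }
    assert len(groups) == len(mentions)
    assert sorted(g[-1] for g in groups) == [1, 2, 3]


def _random_fact(rng: random.Random) -> ObservationFact:
    ref = (
        ConceptRef.custom("SLEEP", rng.choice(["SNORING", "DAY_SLEEP", "INSOMNIA"]))
        if rng.random() < 0.5
        else ConceptRef.standard("ICD-10-CM", f"S{rng.randrange(100)}.{rng.randrange(10)}")
    )
    numeric = rng.random() < 0.3
    return ObservationFact(
        patient_num=rng.randrange(10_000),
        encounter_num=rng.randrange(10_000),
        concept_cd=encode_concept_cd(ref, f"{rng.randrange(1000):03d}"),
        start_date=datetime(2024, rng.randrange(1, 13), rng.randrange(1, 28),
                            rng.randrange(24), rng.randrange(60)),
        modifier_cd=rng.choice(["@", "NLP|CERTAINTY:NEGATED", "NLP|DOSE:VALUE"]),
        instance_num=rng.randrange(1, 5),
        valtype_cd="N" if numeric else "",
        tval_char="mg" if numeric else "",
        nval_num=round(rng.uniform(0, 500), 3) if numeric else None,
        observation_blob=rng.choice(["", 'quoted "snippet", with commas']),
        cohort_query_id=rng.choice(["", "Q42"]),
        note_type_cd=rng.choice(["", "STD|LOINC:59258-4", "CUS|PROGRESS"]),
    )


class TestFactsIO:
    def test_write_then_read_identity_on_random_table(self, tmp_path):
        rng = random.Random(20240601)
        facts = [_random_fact(rng) for _ in range(1000)]
        path = tmp_path / "facts.csv"
        assert write_facts(facts, path) == 1000
        assert read_facts(path) == facts

    def test_empty_table_is_header_only(self, tmp_path):
        path = tmp_path / "facts.csv"
        write_facts([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("patient_num,")
        assert read_facts(path) == []

    def test_vanilla_schema_without_extension_columns(self, tmp_path):
        rng = random.Random(7)
        facts = [_random_fact(rng) for _ in range(5)]
        path = tmp_path / "facts.csv"
        write_facts(facts, path, extended=False)
        header = path.read_text().splitlines()[0]
        assert "cohort_query_id" not in header and "note_type_cd" not in header
        back = read_facts(path)
        assert [f.concept_cd for f in back] == [f.concept_cd for f in facts]
        assert all(f.cohort_query_id == "" for f in back)

    def test_schema_mismatch_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_num,concept_cd\n1,NLP|001|CUSTOM|A:B\n")
        with pytest.raises(EncodingError, match="missing columns"):
            read_facts(path)


class TestNoteTypeCode:
    def test_std_rendering(self):
        assert NoteTypeCode("STD", "59258-4", "LOINC").render() == "STD|LOINC:59258-4"

    def test_cus_rendering_and_parse(self):
        assert NoteTypeCode.parse("CUS|ED_NOTE") == NoteTypeCode("CUS", "ED_NOTE")
        rendered = NoteTypeCode("STD", "59258-4", "LOINC").render()
        assert NoteTypeCode.parse(rendered).render() == rendered

    def test_bad_scheme(self):
        with pytest.raises(ValueError):
            NoteTypeCode("LOCAL", "X")


def test_emit_sql_renders_one_insert_per_row():
    facts = mention_to_facts(_mention(), EncodeOptions(project_num="001"))
    sql = emit_sql(facts)
    assert sql.count("INSERT INTO observation_fact") == len(facts)
    assert "NLP|001|CUSTOM|SLEEP:SNORING" in sql
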