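"""Encoding of mentions as i2b2 ``observation_fact`` rows.

The i2b2 entity-attribute-value model stores one fact per row. NLP-derived
facts are distinguished from structured EHR data by the ``NLP|`` prefix on
``concept_cd`` and follow two templates:

* standard terminology: ``NLP|<PROJECT_NUM>|<VOCAB_PREFIX>:<CODE>``
  (e.g. ``NLP|001|ICD-10-CM:S92.4``)
* custom terminology: ``NLP|<PROJECT_NUM>|CUSTOM|<PROJECT_NAME>:<CONCEPT>``
  (e.g. ``NLP|001|CUSTOM|SLEEP:SNORING``)

Each mention becomes one base row (``modifier_cd="@"``) plus one row per
contextual attribute, encoded as ``NLP|<ATTRIBUTE>:<VALUE>`` in
``modifier_cd`` (e.g. ``NLP|EXPERIENCER:PATIENT``), and one row per numeric
attribute (dose-style values routed to ``nval_num`` with
``valtype_cd="N"``). All rows of one mention share ``patient_num``,
``encounter_num``, ``concept_cd``, ``start_date`` and ``instance_num``, so
grouping by that tuple recovers the source mentions.

Two optional columns extend the vanilla i2b2 schema: ``cohort_query_id``
(the network-wide query id of the cohort the extractor ran on) and
``note_type_cd`` (the rendered note-type code, ``STD|<vocab>:<code>`` or
``CUS|<code>``). Text snippets go to ``observation_blob`` only when
explicitly enabled, because snippets may contain protected health
information.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields as dc_fields
from datetime import datetime
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from .context import ATTRIBUTES
from .errors import ConceptParseError, EncodingError
from .ruleset import ConceptRef, Mode

if TYPE_CHECKING:  # pragma: no cover
    from .extract import Mention

NLP_PREFIX = "NLP|"

#: sentinel returned by parse_concept_cd for structured (non-NLP) codes
NOT_NLP = object()

BASE_MODIFIER = "@"

FACT_COLUMNS = (
    "patient_num",
    "encounter_num",
    "concept_cd",
    "provider_id",
    "start_date",
    "modifier_cd",
    "instance_num",
    "valtype_cd",
    "tval_char",
    "nval_num",
    "observation_blob",
)
EXTENDED_COLUMNS = ("cohort_query_id", "note_type_cd")


def _check_token(token: str, what: str) -> None:
    if not token:
        raise EncodingError(f"{what} must be non-empty")
    if "|" in token or ":" in token:
        raise EncodingError(f"{what} must not contain '|' or ':' ({token!r})")


@dataclass(frozen=True)
class NoteTypeCode:
    """A note-type code in the STD (standard vocabulary) or CUS scheme."""

    scheme: str  # "STD" | "CUS"
    code: str
    vocabulary: str = ""

    def __post_init__(self) -> None:
        if self.scheme not in ("STD", "CUS"):
            raise ValueError(f"scheme must be STD or CUS, got {self.scheme!r}")
        if not self.code:
            raise ValueError("note-type code must be non-empty")
        if self.scheme == "STD" and not self.vocabulary:
            raise ValueError("STD note types require a vocabulary")
        if self.scheme == "CUS" and self.vocabulary:
            raise ValueError("CUS note types carry no vocabulary")

    def render(self) -> str:
        if self.scheme == "STD":
            return f"STD|{self.vocabulary}:{self.code}"
        return f"CUS|{self.code}"

    @classmethod
    def parse(cls, s: str) -> "NoteTypeCode":
        if s.startswith("STD|"):
            rest = s[4:]
            if ":" not in rest:
                raise ValueError(f"STD note type needs '<vocab>:<code>': {s!r}")
            vocab, code = rest.split(":", 1)
            return cls("STD", code, vocab)
        if s.startswith("CUS|"):
            return cls("CUS", s[4:])
        raise ValueError(f"note type must start with 'STD|' or 'CUS|': {s!r}")


@dataclass(frozen=True)
class NumericAttribute:
    """A numeric attribute of a mention, e.g. a drug dose of 325 mg."""

    name: str
    value: float
    unit: str = ""
    raw_text: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("numeric attribute value must be finite")


@dataclass(frozen=True)
class ObservationFact:
    """One row of the i2b2 observation_fact table (plus the two
    ENACT-convention extension columns)."""

    patient_num: int
    encounter_num: int
    concept_cd: str
    start_date: datetime
    provider_id: str = "NLP@"
    modifier_cd: str = BASE_MODIFIER
    instance_num: int = 1
    valtype_cd: str = ""  # "" | "T" | "N"
    tval_char: str = ""
    nval_num: float | None = None
    observation_blob: str = ""
    cohort_query_id: str = ""
    note_type_cd: str = ""

    def __post_init__(self) -> None:
        if self.valtype_cd not in ("", "T", "N"):
            raise ValueError(f"valtype_cd must be '', 'T' or 'N', got {self.valtype_cd!r}")
        if self.valtype_cd == "N" and self.nval_num is None:
            raise ValueError("valtype_cd 'N' requires nval_num")


@dataclass(frozen=True)
class EncodeOptions:
    """Knobs for mention encoding."""

    project_num: str
    cohort_query_id: str = ""
    include_blob: bool = False
    provider_id: str = "NLP@"
    concept_len_limit: int = 50
    extended_columns: bool = True


def encode_concept_cd(
    c: ConceptRef, project_num: str, max_len: int = 50
) -> str:
    """Render a concept reference as an NLP concept_cd string.

    Over-length codes raise :class:`EncodingError` rather than being
    truncated: silent truncation would corrupt codes.
    """
    if not project_num.isdigit():
        raise EncodingError(f"project_num must be digits, got {project_num!r}")
    if c.mode == Mode.STANDARD:
        s = f"NLP|{project_num}|{c.vocab_prefix}:{c.code}"
    else:
        s = f"NLP|{project_num}|CUSTOM|{c.project_name}:{c.concept}"
    if len(s) > max_len:
        raise EncodingError(
            f"concept_cd {s!r} exceeds the {max_len}-character limit"
        )
    return s


def is_nlp_code(s: str) -> bool:
    """The prefix test that partitions NLP-derived from structured codes."""
    return s.startswith(NLP_PREFIX)


def partition_codes(codes: Iterable[str]) -> tuple[list[str], list[str]]:
    """Split codes into (NLP-derived, structured) by the prefix test."""
    nlp: list[str] = []
    other: list[str] = []
    for s in codes:
        (nlp if is_nlp_code(s) else other).append(s)
    return nlp, other


def parse_concept_cd(s: str):
    """Invert :func:`encode_concept_cd`.

    Returns ``(ConceptRef, project_num)`` for well-formed NLP codes, the
    :data:`NOT_NLP` sentinel for codes without the ``NLP|`` prefix
    (structured EHR data), and raises :class:`ConceptParseError` for
    malformed ``NLP|`` strings.
    """
    if not is_nlp_code(s):
        return NOT_NLP
    parts = s.split("|")
    try:
        if len(parts) == 3:
            _, project_num, rest = parts
            if ":" not in rest:
                raise ConceptParseError(
                    f"standard concept_cd needs '<vocab>:<code>': {s!r}"
                )
            vocab, code = rest.split(":", 1)
            ref = ConceptRef.standard(vocab, code)
        elif len(parts) == 4 and parts[2] == "CUSTOM":
            _, project_num, _, rest = parts
            if ":" not in rest:
                raise ConceptParseError(
                    f"custom concept_cd needs '<PROJECT>:<CONCEPT>': {s!r}"
                )
            project_name, concept = rest.split(":", 1)
            ref = ConceptRef.custom(project_name, concept)
        else:
            raise ConceptParseError(f"concept_cd matches neither template: {s!r}")
    except ValueError as exc:
        raise ConceptParseError(f"invalid tokens in concept_cd {s!r}: {exc}") from exc
    if not project_num.isdigit():
        raise ConceptParseError(f"project_num must be digits in {s!r}")
    return ref, project_num


def encode_modifier_cd(attribute: str, value: str) -> str:
    """Render a contextual attribute as ``NLP|<ATTRIBUTE>:<VALUE>``."""
    _check_token(attribute, "attribute")
    _check_token(value, "value")
    return f"NLP|{attribute}:{value}"


def parse_modifier_cd(s: str) -> tuple[str, str]:
    """Invert :func:`encode_modifier_cd`."""
    if not s.startswith(NLP_PREFIX) or ":" not in s[4:]:
        raise ConceptParseError(f"modifier_cd matches no template: {s!r}")
    attribute, value = s[4:].split(":", 1)
    if not attribute or not value:
        raise ConceptParseError(f"empty attribute or value in {s!r}")
    return attribute, value


def mention_to_facts(
    m: "Mention",
    opts: EncodeOptions,
    instance_num: int = 1,
    numeric_attributes: Sequence[NumericAttribute] = (),
) -> list[ObservationFact]:
    """Encode one mention as its base row plus modifier rows.

    All returned rows share (patient_num, encounter_num, concept_cd,
    start_date, instance_num). The base row carries ``modifier_cd="@"`` and,
    when ``opts.include_blob``, the sentence snippet in
    ``observation_blob``.
    """
    doc = m.doc
    concept_cd = encode_concept_cd(
        m.concept, opts.project_num, opts.concept_len_limit
    )
    common = dict(
        patient_num=doc.patient_num,
        encounter_num=doc.encounter_num,
        concept_cd=concept_cd,
        start_date=doc.note_datetime,
        provider_id=opts.provider_id,
        instance_num=instance_num,
        cohort_query_id=opts.cohort_query_id if opts.extended_columns else "",
        note_type_cd=(
            doc.note_type.render()
            if opts.extended_columns and doc.note_type is not None
            else ""
        ),
    )
    facts = [
        ObservationFact(
            modifier_cd=BASE_MODIFIER,
            observation_blob=m.sentence_snippet if opts.include_blob else "",
            **common,
        )
    ]
    values = {
        "CERTAINTY": m.certainty,
        "EXPERIENCER": m.experiencer,
        "TEMPORALITY": m.temporality,
    }
    for attribute in ATTRIBUTES:
        facts.append(
            ObservationFact(
                modifier_cd=encode_modifier_cd(attribute, values[attribute]),
                **common,
            )
        )
    for na in numeric_attributes:
        facts.append(
            ObservationFact(
                modifier_cd=encode_modifier_cd(na.name, "VALUE"),
                valtype_cd="N",
                nval_num=na.value,
                tval_char=na.unit,
                **common,
            )
        )
    return facts


def encode_mentions(
    mentions: Iterable["Mention"], opts: EncodeOptions
) -> list[ObservationFact]:
    """Encode a batch of mentions, assigning ``instance_num`` as a running
    counter (starting at 1) within each (patient, encounter, concept_cd,
    start_date) group so co-occurring mentions stay distinguishable."""
    counters: dict[tuple, int] = {}
    facts: list[ObservationFact] = []
    for m in mentions:
        concept_cd = encode_concept_cd(
            m.concept, opts.project_num, opts.concept_len_limit
        )
        key = (
            m.doc.patient_num,
            m.doc.encounter_num,
            concept_cd,
            m.doc.note_datetime,
        )
        counters[key] = counters.get(key, 0) + 1
        facts.extend(mention_to_facts(m, opts, instance_num=counters[key]))
    return facts


def _fact_to_row(f: ObservationFact, extended: bool) -> list[str]:
    row = [
        str(f.patient_num),
        str(f.encounter_num),
        f.concept_cd,
        f.provider_id,
        f.start_date.isoformat(sep=" "),
        f.modifier_cd,
        str(f.instance_num),
        f.valtype_cd,
        f.tval_char,
        "" if f.nval_num is None else repr(f.nval_num),
        f.observation_blob,
    ]
    if extended:
        row += [f.cohort_query_id, f.note_type_cd]
    return row


def write_facts(
    facts: Sequence[ObservationFact], path: str | Path, extended: bool = True
) -> int:
    """Write facts as an RFC 4180 CSV; returns the number of data rows."""
    path = Path(path)
    columns = FACT_COLUMNS + (EXTENDED_COLUMNS if extended else ())
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for f in facts:
            writer.writerow(_fact_to_row(f, extended))
    return len(facts)


def read_facts(path: str | Path) -> list[ObservationFact]:
    """Read a fact CSV written by :func:`write_facts` (extended columns
    optional). ``read_facts(write_facts(...))`` is the identity."""
    path = Path(path)
    facts: list[ObservationFact] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in FACT_COLUMNS if c not in header]
        if missing:
            raise EncodingError(
                f"{path}: fact CSV is missing columns {missing}"
            )
        for rec in reader:
            facts.append(
                ObservationFact(
                    patient_num=int(rec["patient_num"]),
                    encounter_num=int(rec["encounter_num"]),
                    concept_cd=rec["concept_cd"],
                    provider_id=rec["provider_id"],
                    start_date=datetime.fromisoformat(rec["start_date"]),
                    modifier_cd=rec["modifier_cd"],
                    instance_num=int(rec["instance_num"]),
                    valtype_cd=rec["valtype_cd"],
                    tval_char=rec["tval_char"],
                    nval_num=(
                        float(rec["nval_num"]) if rec["nval_num"] else None
                    ),
                    observation_blob=rec["observation_blob"],
                    cohort_query_id=rec.get("cohort_query_id", ""),
                    note_type_cd=rec.get("note_type_cd", ""),
                )
            )
    return facts


def emit_sql(
    facts: Sequence[ObservationFact],
    table: str = "observation_fact",
    extended: bool = True,
) -> str:
    """Render facts as SQL INSERT statements (one per row)."""
    columns = FACT_COLUMNS + (EXTENDED_COLUMNS if extended else ())
    stmts = []
    for f in facts:
        raw = _fact_to_row(f, extended)
        rendered = []
        for col, val in zip(columns, raw):
            if col in ("patient_num", "encounter_num", "instance_num"):
                rendered.append(val)
            elif col == "nval_num":
                rendered.append(val if val else "NULL")
            else:
                rendered.append("'" + val.replace("'", "''") + "'")
        stmts.append(
            f"INSERT INTO {table} ({', '.join(columns)})"
            f" VALUES ({', '.join(rendered)});"
        )
    return "\n".join(stmts) + ("\n" if stmts else "")
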