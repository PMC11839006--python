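"""Corpus, mention, and diagnosis file formats.

Corpora travel as CSV or JSON-lines with the columns ``note_id``,
``patient_num``, ``encounter_num``, ``note_type`` (rendered, e.g.
``STD|LOINC:59258-4``), ``note_datetime`` (ISO 8601) and ``text``.
Mentions travel as JSON-lines carrying the document identifiers they were
extracted from, so they can be encoded into facts without re-reading the
notes. Diagnoses are a three-column CSV (patient_num, code, date).
"""

from __future__ import annotations

import csv
import json
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

from .cdm import NoteTypeCode
from .evaluate import DxRecord
from .extract import Document, Mention
from .ruleset import ConceptRef, Mode

CORPUS_COLUMNS = (
    "note_id",
    "patient_num",
    "encounter_num",
    "note_type",
    "note_datetime",
    "text",
)


def _doc_from_record(rec: dict) -> Document:
    note_type = (
        NoteTypeCode.parse(rec["note_type"]) if rec.get("note_type") else None
    )
    return Document(
        note_id=str(rec["note_id"]),
        patient_num=int(rec["patient_num"]),
        encounter_num=int(rec["encounter_num"]),
        note_type=note_type,
        note_datetime=datetime.fromisoformat(str(rec["note_datetime"])),
        text=str(rec.get("text", "") or ""),
    )


def read_corpus(path: str | Path) -> list[Document]:
    """Read documents from ``.csv`` or ``.jsonl`` (decided by suffix)."""
    path = Path(path)
    docs: list[Document] = []
    if path.suffix.lower() in (".jsonl", ".json"):
        for line in path.read_text(encoding="utf-8").splitlines():
            if line.strip():
                docs.append(_doc_from_record(json.loads(line)))
    else:
        with path.open("r", encoding="utf-8", newline="") as fh:
            for rec in csv.DictReader(fh):
                docs.append(_doc_from_record(rec))
    return docs


def write_corpus(docs: Sequence[Document], path: str | Path) -> int:
    """Write documents as CSV (or JSONL when the suffix says so)."""
    path = Path(path)

    def record(d: Document) -> dict:
        return {
            "note_id": d.note_id,
            "patient_num": d.patient_num,
            "encounter_num": d.encounter_num,
            "note_type": d.note_type.render() if d.note_type else "",
            "note_datetime": d.note_datetime.isoformat(sep=" "),
            "text": d.text,
        }

    if path.suffix.lower() in (".jsonl", ".json"):
        with path.open("w", encoding="utf-8") as fh:
            for d in docs:
                fh.write(json.dumps(record(d)) + "\n")
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CORPUS_COLUMNS)
            writer.writeheader()
            for d in docs:
                writer.writerow(record(d))
    return len(docs)


def _concept_to_json(c: ConceptRef) -> dict:
    if c.mode == Mode.STANDARD:
        return {"mode": "STANDARD", "vocab_prefix": c.vocab_prefix, "code": c.code}
    return {"mode": "CUSTOM", "project_name": c.project_name, "concept": c.concept}


def _concept_from_json(rec: dict) -> ConceptRef:
    if rec["mode"] == "STANDARD":
        return ConceptRef.standard(rec["vocab_prefix"], rec["code"])
    return ConceptRef.custom(rec["project_name"], rec["concept"])


def write_mentions(mentions: Sequence[Mention], path: str | Path) -> int:
    """Write mentions as JSON-lines, one object per mention."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(
                json.dumps(
                    {
                        "note_id": m.doc.note_id,
                        "patient_num": m.doc.patient_num,
                        "encounter_num": m.doc.encounter_num,
                        "note_type": (
                            m.doc.note_type.render() if m.doc.note_type else ""
                        ),
                        "note_datetime": m.doc.note_datetime.isoformat(sep=" "),
                        "start": m.start,
                        "end": m.end,
                        "matched_text": m.matched_text,
                        "concept": _concept_to_json(m.concept),
                        "certainty": m.certainty,
                        "experiencer": m.experiencer,
                        "temporality": m.temporality,
                        "sentence_snippet": m.sentence_snippet,
                    }
                )
                + "\n"
            )
    return len(mentions)


def read_mentions(path: str | Path) -> list[Mention]:
    """Read mentions written by :func:`write_mentions`.

    The original note text is not stored, so the rebuilt documents carry
    ``text=None`` stubs; span/text consistency is only checkable against
    the source corpus.
    """
    path = Path(path)
    mentions: list[Mention] = []
    doc_cache: dict[str, Document] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        doc = doc_cache.get(rec["note_id"])
        if doc is None:
            doc = Document(
                note_id=rec["note_id"],
                patient_num=int(rec["patient_num"]),
                encounter_num=int(rec["encounter_num"]),
                note_type=(
                    NoteTypeCode.parse(rec["note_type"])
                    if rec.get("note_type")
                    else None
                ),
                note_datetime=datetime.fromisoformat(rec["note_datetime"]),
                text=None,
            )
            doc_cache[rec["note_id"]] = doc
        mentions.append(
            Mention(
                doc=doc,
                start=int(rec["start"]),
                end=int(rec["end"]),
                matched_text=rec["matched_text"],
                concept=_concept_from_json(rec["concept"]),
                certainty=rec["certainty"],
                experiencer=rec["experiencer"],
                temporality=rec["temporality"],
                sentence_snippet=rec.get("sentence_snippet", ""),
            )
        )
    return mentions


def write_diagnoses(records: Iterable[DxRecord], path: str | Path) -> int:
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_num", "code", "date"])
        for dx in records:
            writer.writerow([str(dx.patient_num), dx.code, dx.date])
            n += 1
    return n


def read_diagnoses(path: str | Path) -> list[DxRecord]:
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        return [
            DxRecord(int(rec["patient_num"]), rec["code"], rec.get("date", ""))
            for rec in csv.DictReader(fh)
        ]
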