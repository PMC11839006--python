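"""Shared fixtures: toy rulesets, tiny corpora, and the naive matcher oracle."""

from __future__ import annotations

import re
from datetime import datetime

import pytest

from notefact.cdm import NoteTypeCode
from notefact.extract import Document
from notefact.ruleset import ConceptRef, LexiconEntry, Ruleset
from notefact.synthnotes import toy_sleep_ruleset

_WORD = "A-Za-z0-9_"


def naive_match_oracle(text: str, rs: Ruleset) -> list[tuple[int, int, ConceptRef]]:
    """Brute-force reference matcher: test every substring against the
    lexicon (case-folded, word-bounded), then greedily keep the longest
    non-overlapping matches (ties: leftmost start, then lexicon order);
    identical spans mapping to different concepts are all kept.

    Independent of the production matcher: no regex search, no shared
    selection code path beyond the documented policy.
    """
    lexicon: dict[str, list[tuple[int, ConceptRef]]] = {}
    for idx, e in enumerate(rs.entries):
        assert not e.is_regex, "oracle only covers literal surfaces"
        key = e.surface if e.case_sensitive else e.surface.casefold()
        lexicon.setdefault(key, []).append((idx, e.concept))

    def word_bounded(i: int, j: int) -> bool:
        before_ok = i == 0 or not re.match(f"[{_WORD}]", text[i - 1])
        after_ok = j == len(text) or not re.match(f"[{_WORD}]", text[j])
        return before_ok and after_ok

    candidates = []
    n = len(text)
    for i in range(n):
        for j in range(i + 1, n + 1):
            sub = text[i:j]
            for key in (sub, sub.casefold()):
                for idx, concept in lexicon.get(key, []):
                    entry = rs.entries[idx]
                    matches_case = (
                        sub == entry.surface
                        if entry.case_sensitive
                        else sub.casefold() == entry.surface.casefold()
                    )
                    if matches_case and word_bounded(i, j):
                        candidates.append((i, j, concept, idx))
    # dedupe identical (span, concept) from the two key lookups
    candidates = sorted(set(candidates), key=lambda c: (-(c[1] - c[0]), c[0], c[3]))
    kept: list[tuple[int, int, ConceptRef, int]] = []
    for c in candidates:
        blocked = False
        for k in kept:
            if c[0] < k[1] and k[0] < c[1]:
                if (c[0], c[1]) == (k[0], k[1]):
                    if c[2] == k[2]:
                        blocked = True
                        break
                    continue
                blocked = True
                break
        if not blocked:
            kept.append(c)
    kept.sort(key=lambda c: (c[0], c[1], c[3]))
    return [(i, j, concept) for i, j, concept, _ in kept]


def make_doc(text: str, note_id: str = "n1", patient: int = 1) -> Document:
    return Document(
        note_id=note_id,
        patient_num=patient,
        encounter_num=patient + 100,
        note_type=NoteTypeCode("CUS", "PROGRESS"),
        note_datetime=datetime(2024, 6, 1, 9, 30),
        text=text,
    )


@pytest.fixture
def sleep_ruleset() -> Ruleset:
    return toy_sleep_ruleset()


@pytest.fixture
def doc_factory():
    return make_doc


@pytest.fixture
def oracle():
    return naive_match_oracle


@pytest.fixture
def mini_ruleset() -> Ruleset:
    """Two-entry ruleset where one surface extends the other."""
    return Ruleset(
        project_num="001",
        project_name="SLEEP",
        entries=(
            LexiconEntry("sleep", ConceptRef.custom("SLEEP", "A")),
            LexiconEntry("sleep problems", ConceptRef.custom("SLEEP", "B")),
        ),
    )
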