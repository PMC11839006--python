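"""Sentence-scoped dictionary matching plus contextual-attribute assignment.

The pipeline is deliberately simple and deterministic:

1. :func:`segment_sentences` splits a note into sentence spans (rule-based:
   terminal punctuation followed by whitespace, or a newline).
2. :func:`match_lexicon` finds every word-bounded occurrence of a lexicon
   surface (case-insensitive by default) and resolves overlaps greedily:
   longest match wins, ties broken by leftmost start, then lexicon order.
   Candidates sharing the exact same span but mapping to different concepts
   are all emitted; same-span same-concept duplicates are suppressed.
3. :func:`apply_context` assigns certainty, experiencer and temporality to
   each match from trigger phrases in the same sentence (forward triggers
   scope from the trigger to sentence end, backward ones to sentence start,
   clipped at termination phrases); the nearest in-scope trigger per
   attribute wins, and mentions outside any scope get POSITIVE / PATIENT /
   PRESENT.

All offsets are 0-based, half-open character offsets into the raw note
text, so snippets round-trip exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from functools import lru_cache

from .cdm import NoteTypeCode
from .context import (
    ATTR_CERTAINTY,
    ATTR_EXPERIENCER,
    ATTR_TEMPORALITY,
    ATTRIBUTES,
    ContextTriggerSet,
    DEFAULT_VALUES,
    VALUE_SETS,
)
from .ruleset import ConceptRef, Ruleset

# re-exported here because triggers are part of the extraction surface
__all__ = [
    "Document",
    "Mention",
    "RawMatch",
    "ContextTriggerSet",
    "segment_sentences",
    "match_lexicon",
    "apply_context",
    "extract",
]

_SENTENCE_PUNCT = ".!?"
_WORD_CHARS = "A-Za-z0-9_"


@dataclass(frozen=True)
class Document:
    """One clinical note: identifiers, note type, timestamp, and raw text."""

    note_id: str
    patient_num: int
    encounter_num: int
    note_type: NoteTypeCode | None
    note_datetime: datetime
    text: str


@dataclass(frozen=True)
class Mention:
    """One extracted concept mention with its contextual attributes."""

    doc: Document
    start: int
    end: int
    matched_text: str
    concept: ConceptRef
    certainty: str = "POSITIVE"
    experiencer: str = "PATIENT"
    temporality: str = "PRESENT"
    sentence_snippet: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span [{self.start}, {self.end})")
        if self.doc.text is not None:
            if self.end > len(self.doc.text):
                raise ValueError("span extends past the document text")
            if self.doc.text[self.start : self.end] != self.matched_text:
                raise ValueError("matched_text disagrees with the span")
        if self.certainty not in VALUE_SETS[ATTR_CERTAINTY]:
            raise ValueError(f"bad certainty {self.certainty!r}")
        if self.experiencer not in VALUE_SETS[ATTR_EXPERIENCER]:
            raise ValueError(f"bad experiencer {self.experiencer!r}")
        if self.temporality not in VALUE_SETS[ATTR_TEMPORALITY]:
            raise ValueError(f"bad temporality {self.temporality!r}")


@dataclass(frozen=True)
class RawMatch:
    """A lexicon hit before contextual attributes are assigned."""

    start: int
    end: int
    concept: ConceptRef
    entry_index: int


def segment_sentences(text: str) -> list[tuple[int, int]]:
    """Split text into sentence spans.

    A sentence ends at a run of ``.!?`` followed by whitespace or the end
    of text, or at a newline. Returned spans are disjoint, ordered, include
    the terminal punctuation, and cover all non-whitespace text.
    """
    spans: list[tuple[int, int]] = []
    n = len(text)
    i = 0
    cur_start: int | None = None

    def close(end: int) -> None:
        nonlocal cur_start
        if cur_start is not None:
            trimmed = cur_start + len(text[cur_start:end].rstrip())
            if trimmed > cur_start:
                spans.append((cur_start, trimmed))
            cur_start = None

    while i < n:
        ch = text[i]
        if cur_start is None:
            if not ch.isspace():
                cur_start = i
            i += 1
            continue
        if ch == "\n":
            close(i)
            i += 1
            continue
        if ch in _SENTENCE_PUNCT:
            j = i
            while j < n and text[j] in _SENTENCE_PUNCT:
                j += 1
            if j >= n or text[j].isspace():
                close(j)
            i = j
            continue
        i += 1
    close(n)
    return spans


@lru_cache(maxsize=4096)
def _phrase_pattern(phrase: str, case_sensitive: bool) -> re.Pattern:
    flags = 0 if case_sensitive else re.IGNORECASE
    return re.compile(
        rf"(?<![{_WORD_CHARS}]){re.escape(phrase)}(?![{_WORD_CHARS}])", flags
    )


def _select_matches(candidates: list[RawMatch]) -> list[RawMatch]:
    """Greedy longest-first overlap resolution shared with the test oracle's
    definition: longest span wins, then leftmost start, then lexicon order;
    identical spans for different concepts are all kept."""
    ordered = sorted(
        candidates, key=lambda c: (-(c.end - c.start), c.start, c.entry_index)
    )
    kept: list[RawMatch] = []
    for c in ordered:
        conflict = False
        for k in kept:
            if c.start < k.end and k.start < c.end:  # overlap
                if (c.start, c.end) == (k.start, k.end):
                    if c.concept == k.concept:
                        conflict = True  # same-span duplicate
                        break
                    continue  # same span, different concept: keep both
                conflict = True
                break
        if not conflict:
            kept.append(c)
    kept.sort(key=lambda c: (c.start, c.end, c.entry_index))
    return kept


def match_lexicon(doc: Document, rs: Ruleset) -> list[RawMatch]:
    """Find lexicon matches in the note text (word-bounded, longest wins)."""
    text = doc.text
    if not text:
        return []
    candidates: list[RawMatch] = []
    for idx, entry in enumerate(rs.entries):
        if entry.is_regex:
            flags = 0 if entry.case_sensitive else re.IGNORECASE
            pattern = re.compile(entry.surface, flags)
        else:
            pattern = _phrase_pattern(entry.surface, entry.case_sensitive)
        for m in pattern.finditer(text):
            if m.end() > m.start():
                candidates.append(
                    RawMatch(m.start(), m.end(), entry.concept, idx)
                )
    return _select_matches(candidates)


def _occurrences(
    text: str, phrase: str, lo: int, hi: int
) -> list[tuple[int, int]]:
    return [
        (m.start(), m.end())
        for m in _phrase_pattern(phrase, False).finditer(text, lo, hi)
    ]


def apply_context(
    doc: Document,
    matches: list[RawMatch],
    sentence_spans: list[tuple[int, int]],
    triggers: ContextTriggerSet,
) -> list[Mention]:
    """Assign certainty/experiencer/temporality to each raw match.

    Trigger scope never crosses a sentence boundary or a termination
    phrase; the nearest applicable trigger per attribute wins; defaults are
    POSITIVE / PATIENT / PRESENT.
    """
    text = doc.text
    mentions: list[Mention] = []
    for s_start, s_end in sentence_spans:
        # a match belongs to the sentence its start falls in; sentence spans
        # cover all non-whitespace text, so every match lands somewhere
        in_sentence = [m for m in matches if s_start <= m.start < s_end]
        if not in_sentence:
            continue
        trig_spans = [
            (span, trig)
            for trig in triggers.triggers
            for span in _occurrences(text, trig.phrase, s_start, s_end)
        ]
        term_spans = [
            span
            for phrase in triggers.terminations
            for span in _occurrences(text, phrase, s_start, s_end)
        ]
        snippet = text[s_start:s_end]
        for m in in_sentence:
            values = dict(DEFAULT_VALUES)
            for attribute in ATTRIBUTES:
                best: tuple[int, str] | None = None  # (distance, value)
                for (t_start, t_end), trig in trig_spans:
                    if trig.attribute != attribute:
                        continue
                    if t_start < m.end and m.start < t_end:
                        continue  # trigger overlaps the mention itself
                    forward_ok = trig.direction in ("forward", "bidirectional")
                    backward_ok = trig.direction in ("backward", "bidirectional")
                    if forward_ok and t_end <= m.start:
                        if not any(
                            t_end <= x_start and x_end <= m.start
                            for x_start, x_end in term_spans
                        ):
                            dist = m.start - t_end
                            if best is None or dist < best[0]:
                                best = (dist, trig.value)
                    if backward_ok and t_start >= m.end:
                        if not any(
                            m.end <= x_start and x_end <= t_start
                            for x_start, x_end in term_spans
                        ):
                            dist = t_start - m.end
                            if best is None or dist < best[0]:
                                best = (dist, trig.value)
                if best is not None:
                    values[attribute] = best[1]
            mentions.append(
                Mention(
                    doc=doc,
                    start=m.start,
                    end=m.end,
                    matched_text=text[m.start : m.end],
                    concept=m.concept,
                    certainty=values[ATTR_CERTAINTY],
                    experiencer=values[ATTR_EXPERIENCER],
                    temporality=values[ATTR_TEMPORALITY],
                    sentence_snippet=snippet,
                )
            )
    mentions.sort(key=lambda m: (m.start, m.end))
    return mentions


def extract(doc: Document, rs: Ruleset) -> list[Mention]:
    """Run the full pipeline on one document: match, segment, contextualize."""
    matches = match_lexicon(doc, rs)
    if not matches:
        return []
    spans = segment_sentences(doc.text)
    return apply_context(doc, matches, spans, rs.trigger_set())


def extract_corpus(docs, rs: Ruleset) -> list[Mention]:
    """Extract mentions from every document, in corpus order."""
    out: list[Mention] = []
    for doc in docs:
        out.extend(extract(doc, rs))
    return out
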