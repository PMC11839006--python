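"""Synthetic clinical-note corpora with planted, ground-truth mentions.

Real clinical notes cannot be shipped, so every other module is exercised
against generated corpora whose ground truth is known by construction.
Sentences are built from fixed slot-filling templates (subject, cue
phrase, planted term, tail) rather than free generation, which keeps exact
character-span bookkeeping trivial: the generator records each planted
term's span, concept and intended contextual attributes, and emits
structured diagnosis records alongside so cohort selection and silver
standards are testable too.

Cue phrases are drawn from the same default trigger list the extractor
ships; :func:`inject_noise` swaps them for held-out synonyms the extractor
does not know, plants length-preserving typos, and flips gold labels —
each corruption logged with the error-taxonomy class it is meant to
produce (LINGUISTIC for typos, CONTEXTUAL for cue swaps, ANNOTATION for
label flips).

All randomness flows from the single seed in :class:`GenSpec`.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Iterable, Mapping

from .cdm import NoteTypeCode
from .errors import SpecError
from .evaluate import GOLD, UNIT_MENTION, AnnotationSet, DxRecord
from .extract import Document
from .ruleset import ConceptRef, LexiconEntry, Ruleset

# template classes and the attribute triple each one plants
_CLASS_ATTRS = {
    "default": ("POSITIVE", "PATIENT", "PRESENT"),
    "NEGATED": ("NEGATED", "PATIENT", "PRESENT"),
    "POSSIBLE": ("POSSIBLE", "PATIENT", "PRESENT"),
    "OTHER": ("POSITIVE", "OTHER", "PRESENT"),
    "HISTORICAL": ("POSITIVE", "PATIENT", "HISTORICAL"),
    "HYPOTHETICAL": ("POSITIVE", "PATIENT", "HYPOTHETICAL"),
}

# (template, cue) pairs; {cue} is a phrase from the default trigger list,
# {term} is the planted lexicon surface. Terms never open a sentence, so
# surface casing is preserved.
_TEMPLATES: dict[str, list[tuple[str, str | None]]] = {
    "default": [
        ("Patient reports {term} at night.", None),
        ("The patient describes {term} lately.", None),
        ("Assessment notes {term} on review.", None),
    ],
    "NEGATED": [
        ("Patient {cue} {term} at this time.", "denies"),
        ("There is {cue} {term} currently.", "no evidence of"),
    ],
    "POSSIBLE": [
        ("{cue} {term} was reported by staff.", "Possible"),
        ("There is {cue} {term} today.", "concern for"),
    ],
    "OTHER": [
        ("{cue} had {term} for years.", "Father"),
        ("{cue} reports {term} as well.", "Mother"),
    ],
    "HISTORICAL": [
        ("{cue} {term} in the past.", "History of"),
        ("Remote {cue} {term} noted.", "history of"),
    ],
    "HYPOTHETICAL": [
        ("Return {cue} {term} develops.", "if"),
        ("{cue} {term} going forward.", "Monitor for"),
    ],
}

# synonyms the shipped trigger list does NOT contain, used by
# inject_noise to create honest CONTEXTUAL errors
_HELD_OUT_CUES = {
    "denies": "disputes",
    "no evidence of": "nothing to indicate",
    "possible": "conceivable",
    "concern for": "wondering about",
    "father": "their dad",
    "mother": "their mom",
    "history of": "longstanding",
    "if": "when",
    "monitor for": "tracking",
}

_DISTRACTOR_POOL = (
    "vitals stable exam unremarkable medications reviewed plan discussed "
    "labs within normal limits gait steady appetite fair mood euthymic "
    "alert oriented breathing comfortably afebrile ambulating hydrated "
    "tolerating diet well skin intact neuro grossly benign chart updated "
    "scheduled routine pending results clinic blood pressure controlled "
    "heart rate regular abdomen soft extremities warm"
).split()

_DEFAULT_NOTE_TYPES = (
    (NoteTypeCode("STD", "59258-4", "LOINC"), 0.6),
    (NoteTypeCode("CUS", "PROGRESS"), 0.4),
)

_DEFAULT_DX_RULES = {
    "F11.20": 0.15,  # opioid dependence, uncomplicated
    "T43.611A": 0.05,  # poisoning by caffeine, initial encounter
    "G90.50": 0.05,  # complex regional pain syndrome I
    "E11.9": 0.40,  # type 2 diabetes, background noise
    "I10": 0.50,  # essential hypertension, background noise
}


def toy_sleep_ruleset() -> Ruleset:
    """The default toy ruleset: a sleep-phenotyping project with custom
    concepts (snoring, daytime sleep, sleep problems, ...)."""
    project = "SLEEP"

    def entry(surface: str, concept: str) -> LexiconEntry:
        return LexiconEntry(surface, ConceptRef.custom(project, concept))

    return Ruleset(
        project_num="001",
        project_name=project,
        entries=(
            entry("snoring", "SNORING"),
            entry("daytime sleepiness", "DAY_SLEEP"),
            entry("napping", "DAY_SLEEP"),
            entry("sleep problems", "SLEEP_PROBLEMS"),
            entry("insomnia", "SLEEP_PROBLEMS"),
            entry("poor sleep quality", "SLEEP_QUALITY_BAD"),
            entry("nocturnal awakenings", "NOCT_AWAKENING"),
        ),
    )


@dataclass(frozen=True)
class GenSpec:
    """Generator parameters; the defaults define the standard conditions
    used throughout the test-suite and acceptance runs."""

    seed: int = 0
    n_docs: int = 200
    ruleset: Ruleset | None = None  # toy sleep ruleset when None
    #: per-concept probability of planting one mention per document;
    #: a float applies to every concept, a mapping is keyed by concept key
    mention_rate: float | Mapping[str, float] = 0.3
    #: probability that a planted mention uses each cue class; the
    #: remainder uses the trigger-free default template
    cue_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "NEGATED": 0.2,
            "POSSIBLE": 0.1,
            "OTHER": 0.1,
            "HISTORICAL": 0.1,
            "HYPOTHETICAL": 0.1,
        }
    )
    distractor_vocab_size: int = 40
    distractors_per_doc: tuple[int, int] = (1, 3)
    note_type_mix: tuple[tuple[NoteTypeCode, float], ...] = _DEFAULT_NOTE_TYPES
    #: structured-diagnosis planting: ICD code -> per-patient probability
    dx_rules: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DX_RULES)
    )

    def __post_init__(self) -> None:
        if self.n_docs < 0:
            raise SpecError("n_docs must be >= 0")
        rates = (
            [self.mention_rate]
            if isinstance(self.mention_rate, float)
            else list(self.mention_rate.values())
        )
        rates += list(self.cue_rates.values()) + list(self.dx_rules.values())
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise SpecError("all rates must lie in [0, 1]")
        if sum(self.cue_rates.values()) > 1.0 + 1e-9:
            raise SpecError("cue rates must sum to at most 1")
        unknown = set(self.cue_rates) - (set(_CLASS_ATTRS) - {"default"})
        if unknown:
            raise SpecError(f"unknown cue classes {sorted(unknown)}")

    def resolved_ruleset(self) -> Ruleset:
        return self.ruleset if self.ruleset is not None else toy_sleep_ruleset()

    def rate_for(self, concept: ConceptRef) -> float:
        if isinstance(self.mention_rate, float):
            return self.mention_rate
        return float(self.mention_rate.get(concept.key(), 0.0))


@dataclass(frozen=True)
class GoldMention:
    """Ground truth for one planted mention."""

    doc_id: str
    start: int
    end: int
    surface: str
    concept: ConceptRef
    certainty: str
    experiencer: str
    temporality: str
    cue_class: str = "default"
    cue_start: int | None = None
    cue_end: int | None = None


@dataclass(frozen=True)
class SynthCorpus:
    """A generated corpus: documents, gold mentions, structured diagnoses."""

    documents: tuple[Document, ...]
    gold: tuple[GoldMention, ...]
    diagnoses: tuple[DxRecord, ...]

    def gold_annotation(self) -> AnnotationSet:
        return AnnotationSet(
            GOLD,
            UNIT_MENTION,
            {(g.doc_id, g.start, g.end, g.concept.key()): 1 for g in self.gold},
        )


def _safe_distractor_words(rs: Ruleset, size: int) -> list[str]:
    """Distractor vocabulary guaranteed not to re-create lexicon surfaces:
    any word occurring inside any surface is excluded, so no sequence of
    distractor words can spell a surface."""
    surface_words = {
        w.casefold() for e in rs.entries for w in e.surface.split()
    }
    pool = [w for w in _DISTRACTOR_POOL if w.casefold() not in surface_words]
    return pool[: max(size, 5)]


def _pick_cue_class(rng: random.Random, cue_rates: Mapping[str, float]) -> str:
    roll = rng.random()
    acc = 0.0
    for cls in ("NEGATED", "POSSIBLE", "OTHER", "HISTORICAL", "HYPOTHETICAL"):
        acc += cue_rates.get(cls, 0.0)
        if roll < acc:
            return cls
    return "default"


def _build_planted(
    rng: random.Random, surface: str, cue_class: str
) -> tuple[str, int, int, int | None, int | None]:
    """Render a template; returns (sentence, term_start, term_end,
    cue_start, cue_end) with offsets local to the sentence."""
    template, cue = rng.choice(_TEMPLATES[cue_class])
    before_term, after_term = template.split("{term}")
    cue_span = None
    if cue is not None:
        cue_pos = before_term.index("{cue}")
        before_term = before_term.replace("{cue}", cue)
        cue_span = (cue_pos, cue_pos + len(cue))
    sentence = before_term + surface + after_term
    term_start = len(before_term)
    return (
        sentence,
        term_start,
        term_start + len(surface),
        cue_span[0] if cue_span else None,
        cue_span[1] if cue_span else None,
    )


def generate_corpus(spec: GenSpec) -> SynthCorpus:
    """Generate documents, exact-span gold mentions, and diagnoses.

    Deterministic per seed. Every planted mention is recorded in the gold
    set with its intended attributes; running the extractor with the same
    ruleset on the uncorrupted corpus reproduces the gold set exactly.
    """
    rng = random.Random(spec.seed)
    rs = spec.resolved_ruleset()
    surfaces_by_concept: dict[ConceptRef, list[str]] = {}
    for e in rs.entries:
        surfaces_by_concept.setdefault(e.concept, []).append(e.surface)
    distractors = _safe_distractor_words(rs, spec.distractor_vocab_size)
    type_codes = [t for t, _ in spec.note_type_mix]
    type_weights = [w for _, w in spec.note_type_mix]
    base_date = datetime(2024, 1, 1)

    documents: list[Document] = []
    gold: list[GoldMention] = []
    diagnoses: list[DxRecord] = []

    for i in range(spec.n_docs):
        doc_id = f"note-{i:05d}"
        patient_num = 1000 + i
        encounter_num = 5000 + i
        note_type = rng.choices(type_codes, weights=type_weights, k=1)[0]
        note_dt = base_date + timedelta(
            days=rng.randrange(365), minutes=rng.randrange(1440)
        )

        # planted sentences: (sentence, term_span, cue_span, concept, class)
        planted = []
        for concept in rs.concepts():
            if rng.random() < spec.rate_for(concept):
                cue_class = _pick_cue_class(rng, spec.cue_rates)
                surface = rng.choice(surfaces_by_concept[concept])
                planted.append(
                    (_build_planted(rng, surface, cue_class), concept, cue_class)
                )
        lo, hi = spec.distractors_per_doc
        filler = [
            (
                " ".join(
                    [rng.choice(distractors).capitalize()]
                    + [rng.choice(distractors) for _ in range(rng.randrange(3, 7))]
                )
                + ".",
                None,
                None,
            )
            for _ in range(rng.randint(lo, hi))
        ]
        items = [
            (sent, (t0, t1, c0, c1), concept, cls)
            for (sent, t0, t1, c0, c1), concept, cls in planted
        ] + [(sent, None, None, None) for sent, _, _ in filler]
        rng.shuffle(items)

        offset = 0
        pieces = []
        for sent, spans, concept, cls in items:
            if spans is not None:
                t0, t1, c0, c1 = spans
                cert, exp, temp = _CLASS_ATTRS[cls]
                gold.append(
                    GoldMention(
                        doc_id=doc_id,
                        start=offset + t0,
                        end=offset + t1,
                        surface=sent[t0:t1],
                        concept=concept,
                        certainty=cert,
                        experiencer=exp,
                        temporality=temp,
                        cue_class=cls,
                        cue_start=None if c0 is None else offset + c0,
                        cue_end=None if c1 is None else offset + c1,
                    )
                )
            pieces.append(sent)
            offset += len(sent) + 1  # single-space joiner
        text = " ".join(pieces)

        documents.append(
            Document(
                note_id=doc_id,
                patient_num=patient_num,
                encounter_num=encounter_num,
                note_type=note_type,
                note_datetime=note_dt,
                text=text,
            )
        )
        for code, prob in spec.dx_rules.items():
            if rng.random() < prob:
                diagnoses.append(
                    DxRecord(patient_num, code, note_dt.date().isoformat())
                )

    gold.sort(key=lambda g: (g.doc_id, g.start))
    return SynthCorpus(tuple(documents), tuple(gold), tuple(diagnoses))


@dataclass(frozen=True)
class NoiseSpec:
    """Corruption rates for :func:`inject_noise`."""

    typo_rate: float = 0.0
    cue_swap_rate: float = 0.0
    gold_flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.typo_rate, self.cue_swap_rate, self.gold_flip_rate):
            if not (0.0 <= r <= 1.0):
                raise SpecError("noise rates must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseEvent:
    """One applied corruption and the error class it should produce."""

    error_type: str  # LINGUISTIC | CONTEXTUAL | ANNOTATION
    doc_id: str
    detail: str


def _typo(word: str) -> str:
    """Length-preserving corruption: swap the first differing adjacent
    letter pair, else overwrite the first character."""
    chars = list(word)
    for k in range(len(chars) - 1):
        if chars[k] != chars[k + 1] and chars[k].isalpha() and chars[k + 1].isalpha():
            chars[k], chars[k + 1] = chars[k + 1], chars[k]
            return "".join(chars)
    return ("q" if word[0] != "q" else "x") + word[1:]


def inject_noise(
    corpus: SynthCorpus, noise: NoiseSpec
) -> tuple[SynthCorpus, list[NoiseEvent]]:
    """Corrupt a corpus at the given rates; the manifest records every
    corruption with its intended error-taxonomy class.

    Cue swaps replace a trigger phrase with a held-out synonym (gold keeps
    the originally intended attributes, so the extractor now disagrees:
    a CONTEXTUAL error). Typos corrupt planted surfaces in place
    (LINGUISTIC). Gold flips alter the gold certainty without touching the
    text (ANNOTATION). All rates 0 returns the corpus unchanged.
    """
    rng = random.Random(noise.seed)
    manifest: list[NoiseEvent] = []
    texts = {d.note_id: d.text for d in corpus.documents}
    gold = [replace(g) for g in corpus.gold]

    # pass 1: cue swaps (may change text length; later spans are shifted)
    for idx, g in enumerate(gold):
        if g.cue_start is None or rng.random() >= noise.cue_swap_rate:
            continue
        text = texts[g.doc_id]
        cue_text = text[g.cue_start : g.cue_end]
        synonym = _HELD_OUT_CUES.get(cue_text.lower())
        if synonym is None:
            continue
        if cue_text[0].isupper():
            synonym = synonym[0].upper() + synonym[1:]
        delta = len(synonym) - len(cue_text)
        texts[g.doc_id] = text[: g.cue_start] + synonym + text[g.cue_end :]
        swap_at = g.cue_end
        for j, h in enumerate(gold):
            if h.doc_id != g.doc_id:
                continue
            shifts = {}
            if h.start >= swap_at:
                shifts["start"] = h.start + delta
                shifts["end"] = h.end + delta
            if h.cue_start is not None and h.cue_start >= swap_at:
                shifts["cue_start"] = h.cue_start + delta
                shifts["cue_end"] = h.cue_end + delta
            if shifts:
                gold[j] = replace(h, **shifts)
        gold[idx] = replace(gold[idx], cue_start=None, cue_end=None)
        manifest.append(
            NoiseEvent(
                "CONTEXTUAL",
                g.doc_id,
                f"cue {cue_text!r} -> {synonym!r} before {g.surface!r}",
            )
        )

    # pass 2: length-preserving typos on planted surfaces
    for g in gold:
        if rng.random() >= noise.typo_rate:
            continue
        text = texts[g.doc_id]
        corrupted = _typo(text[g.start : g.end])
        texts[g.doc_id] = text[: g.start] + corrupted + text[g.end :]
        manifest.append(
            NoiseEvent(
                "LINGUISTIC", g.doc_id, f"typo {g.surface!r} -> {corrupted!r}"
            )
        )

    # pass 3: gold label flips (text untouched)
    for idx, g in enumerate(gold):
        if rng.random() >= noise.gold_flip_rate:
            continue
        flipped = "POSITIVE" if g.certainty == "NEGATED" else "NEGATED"
        gold[idx] = replace(g, certainty=flipped)
        manifest.append(
            NoiseEvent(
                "ANNOTATION",
                g.doc_id,
                f"gold certainty {g.certainty} -> {flipped} for {g.surface!r}",
            )
        )

    documents = tuple(
        replace(d, text=texts[d.note_id]) for d in corpus.documents
    )
    return SynthCorpus(documents, tuple(gold), corpus.diagnoses), manifest
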