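"""Contextual-attribute trigger vocabularies and the default trigger list.

Mentions carry three contextual attributes — certainty, experiencer and
temporality — assigned by a trigger-phrase algorithm in the ConText family:
a trigger phrase opens a scope that runs forward to the end of the sentence
(or backward to its start), clipped at termination phrases, and every
concept mention inside the scope receives the trigger's attribute value.
Mentions outside any scope receive the defaults POSITIVE / PATIENT /
PRESENT.

This module holds the closed attribute vocabularies, the trigger data
types, a TSV loader/writer, and the default English trigger list shipped
with the package. Rulesets may override the default list with their own
trigger file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import RulesetError

ATTR_CERTAINTY = "CERTAINTY"
ATTR_EXPERIENCER = "EXPERIENCER"
ATTR_TEMPORALITY = "TEMPORALITY"
ATTRIBUTES = (ATTR_CERTAINTY, ATTR_EXPERIENCER, ATTR_TEMPORALITY)

CERTAINTY_VALUES = ("POSITIVE", "NEGATED", "POSSIBLE")
EXPERIENCER_VALUES = ("PATIENT", "OTHER")
TEMPORALITY_VALUES = ("PRESENT", "HISTORICAL", "HYPOTHETICAL")

VALUE_SETS = {
    ATTR_CERTAINTY: CERTAINTY_VALUES,
    ATTR_EXPERIENCER: EXPERIENCER_VALUES,
    ATTR_TEMPORALITY: TEMPORALITY_VALUES,
}

#: attribute value assigned when no trigger is in scope
DEFAULT_VALUES = {
    ATTR_CERTAINTY: "POSITIVE",
    ATTR_EXPERIENCER: "PATIENT",
    ATTR_TEMPORALITY: "PRESENT",
}

DIRECTIONS = ("forward", "backward", "bidirectional")


@dataclass(frozen=True)
class ContextTrigger:
    """One trigger phrase with the attribute value it assigns in scope."""

    phrase: str
    attribute: str
    value: str
    direction: str = "forward"

    def __post_init__(self) -> None:
        if not self.phrase or not self.phrase.strip():
            raise ValueError("trigger phrase must be non-empty")
        if self.attribute not in ATTRIBUTES:
            raise ValueError(f"unknown attribute {self.attribute!r}")
        if self.value not in VALUE_SETS[self.attribute]:
            raise ValueError(
                f"value {self.value!r} not allowed for {self.attribute}"
            )
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class ContextTriggerSet:
    """Trigger phrases plus the termination phrases that clip their scope."""

    triggers: tuple[ContextTrigger, ...] = ()
    terminations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for t in self.terminations:
            if not t or not t.strip():
                raise ValueError("termination phrase must be non-empty")

    @classmethod
    def default(cls) -> "ContextTriggerSet":
        return DEFAULT_TRIGGER_SET


def _fwd(phrase: str, attribute: str, value: str) -> ContextTrigger:
    return ContextTrigger(phrase, attribute, value, "forward")


def _bwd(phrase: str, attribute: str, value: str) -> ContextTrigger:
    return ContextTrigger(phrase, attribute, value, "backward")


DEFAULT_TRIGGERS: tuple[ContextTrigger, ...] = (
    # certainty: negation
    _fwd("denies", ATTR_CERTAINTY, "NEGATED"),
    _fwd("denied", ATTR_CERTAINTY, "NEGATED"),
    _fwd("no evidence of", ATTR_CERTAINTY, "NEGATED"),
    _fwd("no signs of", ATTR_CERTAINTY, "NEGATED"),
    _fwd("no complaints of", ATTR_CERTAINTY, "NEGATED"),
    _fwd("negative for", ATTR_CERTAINTY, "NEGATED"),
    _fwd("without", ATTR_CERTAINTY, "NEGATED"),
    _fwd("no", ATTR_CERTAINTY, "NEGATED"),
    _fwd("not", ATTR_CERTAINTY, "NEGATED"),
    _fwd("absence of", ATTR_CERTAINTY, "NEGATED"),
    _fwd("free of", ATTR_CERTAINTY, "NEGATED"),
    _bwd("ruled out", ATTR_CERTAINTY, "NEGATED"),
    _bwd("unlikely", ATTR_CERTAINTY, "NEGATED"),
    # certainty: hedging
    _fwd("possible", ATTR_CERTAINTY, "POSSIBLE"),
    _fwd("probable", ATTR_CERTAINTY, "POSSIBLE"),
    _fwd("suspected", ATTR_CERTAINTY, "POSSIBLE"),
    _fwd("question of", ATTR_CERTAINTY, "POSSIBLE"),
    _fwd("concern for", ATTR_CERTAINTY, "POSSIBLE"),
    _fwd("suspicious for", ATTR_CERTAINTY, "POSSIBLE"),
    _fwd("may have", ATTR_CERTAINTY, "POSSIBLE"),
    # experiencer: someone other than the patient
    _fwd("father", ATTR_EXPERIENCER, "OTHER"),
    _fwd("mother", ATTR_EXPERIENCER, "OTHER"),
    _fwd("brother", ATTR_EXPERIENCER, "OTHER"),
    _fwd("sister", ATTR_EXPERIENCER, "OTHER"),
    _fwd("sibling", ATTR_EXPERIENCER, "OTHER"),
    _fwd("spouse", ATTR_EXPERIENCER, "OTHER"),
    _fwd("husband", ATTR_EXPERIENCER, "OTHER"),
    _fwd("wife", ATTR_EXPERIENCER, "OTHER"),
    _fwd("son", ATTR_EXPERIENCER, "OTHER"),
    _fwd("daughter", ATTR_EXPERIENCER, "OTHER"),
    _fwd("family history of", ATTR_EXPERIENCER, "OTHER"),
    # temporality: historical
    _fwd("history of", ATTR_TEMPORALITY, "HISTORICAL"),
    _fwd("h/o", ATTR_TEMPORALITY, "HISTORICAL"),
    _fwd("past history of", ATTR_TEMPORALITY, "HISTORICAL"),
    _fwd("previously had", ATTR_TEMPORALITY, "HISTORICAL"),
    # temporality: hypothetical / conditional
    _fwd("if", ATTR_TEMPORALITY, "HYPOTHETICAL"),
    _fwd("return if", ATTR_TEMPORALITY, "HYPOTHETICAL"),
    _fwd("should", ATTR_TEMPORALITY, "HYPOTHETICAL"),
    _fwd("in case", ATTR_TEMPORALITY, "HYPOTHETICAL"),
    _fwd("monitor for", ATTR_TEMPORALITY, "HYPOTHETICAL"),
    _fwd("watch for", ATTR_TEMPORALITY, "HYPOTHETICAL"),
    _fwd("risk of", ATTR_TEMPORALITY, "HYPOTHETICAL"),
)

DEFAULT_TERMINATIONS: tuple[str, ...] = (
    "but",
    "however",
    "although",
    "though",
    "except",
    "aside from",
    "which",
)

DEFAULT_TRIGGER_SET = ContextTriggerSet(DEFAULT_TRIGGERS, DEFAULT_TERMINATIONS)

_TERMINATION_TAG = "TERMINATION"


def load_triggers(path: str | Path) -> ContextTriggerSet:
    """Load a trigger lexicon from a tab-delimited file.

    Lines are either ``phrase<TAB>ATTRIBUTE<TAB>VALUE[<TAB>direction]`` or
    ``phrase<TAB>TERMINATION``. ``#`` comments and blank lines are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise RulesetError(f"trigger file not found: {path}")
    triggers: list[ContextTrigger] = []
    terminations: list[str] = []
    for lineno, raw in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 2 and fields[1].strip().upper() == _TERMINATION_TAG:
            terminations.append(fields[0].strip())
            continue
        if len(fields) not in (3, 4):
            raise RulesetError(
                f"{path}:{lineno}: expected 'phrase<TAB>ATTRIBUTE<TAB>VALUE"
                f"[<TAB>direction]' or 'phrase<TAB>TERMINATION', got {raw!r}"
            )
        phrase = fields[0].strip()
        attribute = fields[1].strip().upper()
        value = fields[2].strip().upper()
        direction = fields[3].strip().lower() if len(fields) == 4 else "forward"
        try:
            triggers.append(ContextTrigger(phrase, attribute, value, direction))
        except ValueError as exc:
            raise RulesetError(f"{path}:{lineno}: {exc}") from exc
    return ContextTriggerSet(tuple(triggers), tuple(terminations))


def save_triggers(ts: ContextTriggerSet, path: str | Path) -> None:
    """Write a trigger set in the format accepted by :func:`load_triggers`."""
    path = Path(path)
    lines = ["# phrase<TAB>ATTRIBUTE<TAB>VALUE<TAB>direction"]
    for t in ts.triggers:
        lines.append(f"{t.phrase}\t{t.attribute}\t{t.value}\t{t.direction}")
    for term in ts.terminations:
        lines.append(f"{term}\t{_TERMINATION_TAG}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
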