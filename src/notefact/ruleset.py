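"""Project rulesets: the lexicon, terminology mode, and context triggers.

A ruleset couples a project identity (a zero-padded project number plus an
uppercase project name) with the dictionary used for concept matching and,
optionally, a project-specific context trigger list. Concepts are either
drawn from a standard terminology (a vocabulary prefix plus a code, e.g.
``ICD-10-CM:S92.4``) or from the project's custom terminology (an
uppercase concept token such as ``SNORING``).

File format
-----------
A ruleset on disk is a small YAML config next to one or two tab-delimited
lexicon files::

    project_num: "001"
    project_name: SLEEP
    project_num_width: 3        # optional, default 3
    case_sensitive_default: false
    lexicon: lexicon.tsv        # relative to the config file
    triggers: triggers.tsv      # optional; package default list if absent

Each lexicon line is ``surface<TAB>concept[<TAB>flags]``; a concept field
containing ``:`` is a standard ``VOCAB:CODE`` reference, otherwise it is a
custom concept token under the project's name. Flags are a comma-separated
subset of ``cs`` (case-sensitive) and ``regex``. ``#`` comments and blank
lines are ignored.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import yaml

from .context import ContextTriggerSet, load_triggers, save_triggers
from .errors import Issue, RulesetError

log = logging.getLogger(__name__)

_CUSTOM_TOKEN_RE = re.compile(r"^[A-Z0-9][A-Z0-9_]*$")


class Mode(str, Enum):
    STANDARD = "STANDARD"
    CUSTOM = "CUSTOM"


def _check_token(token: str, what: str, *, allow_lower: bool = True) -> None:
    if not token:
        raise ValueError(f"{what} must be non-empty")
    if "|" in token or ":" in token:
        raise ValueError(f"{what} must not contain '|' or ':' ({token!r})")
    if not allow_lower and not _CUSTOM_TOKEN_RE.match(token):
        raise ValueError(
            f"{what} must be an uppercase token (A-Z, 0-9, '_'), got {token!r}"
        )


@dataclass(frozen=True, order=True)
class ConceptRef:
    """Reference to a concept in a standard or custom terminology.

    Exactly one of (``vocab_prefix``, ``code``) — STANDARD mode — or
    (``project_name``, ``concept``) — CUSTOM mode — is populated.
    """

    mode: Mode
    vocab_prefix: str = ""
    code: str = ""
    project_name: str = ""
    concept: str = ""

    def __post_init__(self) -> None:
        if self.mode == Mode.STANDARD:
            _check_token(self.vocab_prefix, "vocab_prefix")
            _check_token(self.code, "code")
            if self.project_name or self.concept:
                raise ValueError("STANDARD refs must not carry custom fields")
        elif self.mode == Mode.CUSTOM:
            _check_token(self.project_name, "project_name", allow_lower=False)
            _check_token(self.concept, "concept", allow_lower=False)
            if self.vocab_prefix or self.code:
                raise ValueError("CUSTOM refs must not carry standard fields")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def standard(cls, vocab_prefix: str, code: str) -> "ConceptRef":
        return cls(Mode.STANDARD, vocab_prefix=vocab_prefix, code=code)

    @classmethod
    def custom(cls, project_name: str, concept: str) -> "ConceptRef":
        return cls(Mode.CUSTOM, project_name=project_name, concept=concept)

    def key(self) -> str:
        """Stable ``PREFIX:TOKEN`` identifier used in reports and gold files."""
        if self.mode == Mode.STANDARD:
            return f"{self.vocab_prefix}:{self.code}"
        return f"{self.project_name}:{self.concept}"


@dataclass(frozen=True)
class LexiconEntry:
    """One dictionary entry: a surface form (or regex) mapped to a concept."""

    surface: str
    concept: ConceptRef
    case_sensitive: bool = False
    is_regex: bool = False

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("lexicon surface must be non-empty")
        if self.is_regex:
            try:
                re.compile(self.surface)
            except re.error as exc:
                raise ValueError(
                    f"regex surface {self.surface!r} does not compile: {exc}"
                ) from exc


@dataclass(frozen=True)
class Ruleset:
    """A validated project ruleset ready for extraction and encoding."""

    project_num: str
    project_name: str
    entries: tuple[LexiconEntry, ...] = ()
    context_triggers: ContextTriggerSet | None = None
    num_width: int = 3
    case_sensitive_default: bool = False

    def __post_init__(self) -> None:
        if not self.project_num.isdigit() or len(self.project_num) != self.num_width:
            raise ValueError(
                f"project_num must be {self.num_width} digits, got"
                f" {self.project_num!r}"
            )
        _check_token(self.project_name, "project_name", allow_lower=False)

    def trigger_set(self) -> ContextTriggerSet:
        return self.context_triggers or ContextTriggerSet.default()

    def concepts(self) -> tuple[ConceptRef, ...]:
        """Distinct concepts in lexicon order of first appearance."""
        seen: dict[ConceptRef, None] = {}
        for e in self.entries:
            seen.setdefault(e.concept, None)
        return tuple(seen)


def _parse_concept_field(field_text: str, project_name: str) -> ConceptRef:
    field_text = field_text.strip()
    if ":" in field_text:
        vocab, code = field_text.split(":", 1)
        return ConceptRef.standard(vocab.strip(), code.strip())
    return ConceptRef.custom(project_name, field_text.upper())


def _parse_lexicon(
    path: Path, project_name: str, case_sensitive_default: bool
) -> tuple[LexiconEntry, ...]:
    if not path.exists():
        raise RulesetError(f"lexicon file not found: {path}")
    entries: list[LexiconEntry] = []
    for lineno, raw in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (2, 3):
            raise RulesetError(
                f"{path}:{lineno}: expected 'surface<TAB>concept[<TAB>flags]',"
                f" got {raw!r}"
            )
        surface = fields[0].strip()
        flags = set()
        if len(fields) == 3:
            flags = {f.strip().lower() for f in fields[2].split(",") if f.strip()}
            unknown = flags - {"cs", "regex"}
            if unknown:
                raise RulesetError(
                    f"{path}:{lineno}: unknown flags {sorted(unknown)}"
                )
        try:
            entries.append(
                LexiconEntry(
                    surface=surface,
                    concept=_parse_concept_field(fields[1], project_name),
                    case_sensitive="cs" in flags or case_sensitive_default,
                    is_regex="regex" in flags,
                )
            )
        except ValueError as exc:
            raise RulesetError(f"{path}:{lineno}: {exc}") from exc
    if not entries:
        log.warning("lexicon file %s contains no entries", path)
    return tuple(entries)


def load_ruleset(path: str | Path) -> Ruleset:
    """Load and validate a ruleset from its YAML config file.

    Raises :class:`RulesetError` for missing files, malformed lines (the
    message names the file and line number), or error-severity validation
    issues such as one surface mapped to two different concepts.
    Same-concept duplicate surfaces are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise RulesetError(f"ruleset config not found: {path}")
    try:
        cfg = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    except yaml.YAMLError as exc:
        raise RulesetError(f"{path}: config does not parse: {exc}") from exc
    if not isinstance(cfg, dict):
        raise RulesetError(f"{path}: config must be a mapping")
    try:
        project_name = str(cfg["project_name"]).upper()
        num_width = int(cfg.get("project_num_width", 3))
        project_num = str(cfg["project_num"]).zfill(num_width)
    except KeyError as exc:
        raise RulesetError(f"{path}: missing config key {exc}") from exc
    case_default = bool(cfg.get("case_sensitive_default", False))

    lexicon_rel = cfg.get("lexicon", "lexicon.tsv")
    entries = _parse_lexicon(
        path.parent / lexicon_rel, project_name, case_default
    )
    # drop exact same-concept duplicates (case-folded), keeping first
    seen: dict[str, ConceptRef] = {}
    kept: list[LexiconEntry] = []
    for e in entries:
        folded = e.surface.casefold()
        if folded in seen and seen[folded] == e.concept:
            log.warning("duplicate lexicon surface %r dropped", e.surface)
            continue
        seen.setdefault(folded, e.concept)
        kept.append(e)

    triggers = None
    if cfg.get("triggers"):
        triggers = load_triggers(path.parent / cfg["triggers"])

    try:
        rs = Ruleset(
            project_num=project_num,
            project_name=project_name,
            entries=tuple(kept),
            context_triggers=triggers,
            num_width=num_width,
            case_sensitive_default=case_default,
        )
    except ValueError as exc:
        raise RulesetError(f"{path}: {exc}") from exc
    errors = [i for i in validate_ruleset(rs) if i.severity == "error"]
    if errors:
        raise RulesetError(
            f"{path}: ruleset fails validation: "
            + "; ".join(f"{i.location}: {i.message}" for i in errors)
        )
    return rs


def validate_ruleset(rs: Ruleset) -> list[Issue]:
    """Check ruleset invariants; returns an empty list iff all hold."""
    issues: list[Issue] = []
    by_surface: dict[str, set[ConceptRef]] = {}
    per_concept_seen: set[tuple[str, ConceptRef]] = set()
    for idx, e in enumerate(rs.entries):
        loc = f"entry[{idx}] {e.surface!r}"
        for bad, name in (("|", "'|'"), ("\t", "tab"), ("\n", "newline")):
            if bad in e.surface:
                issues.append(
                    Issue("error", loc, f"surface contains forbidden {name}")
                )
        folded = e.surface.casefold()
        key = (folded, e.concept)
        if key in per_concept_seen:
            issues.append(
                Issue("warning", loc, "duplicate surface for the same concept")
            )
        per_concept_seen.add(key)
        by_surface.setdefault(folded, set()).add(e.concept)
    for folded, concepts in sorted(by_surface.items()):
        if len(concepts) > 1:
            issues.append(
                Issue(
                    "error",
                    f"surface {folded!r}",
                    "ambiguous: mapped to "
                    + ", ".join(sorted(c.key() for c in concepts)),
                )
            )
    return issues


def save_ruleset(
    rs: Ruleset, directory: str | Path, config_name: str = "config.yaml"
) -> Path:
    """Write a ruleset as config + lexicon (+ triggers) files; returns the
    config path. ``load_ruleset(save_ruleset(rs, d))`` preserves content."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lexicon_name = "lexicon.tsv"
    lines = ["# surface<TAB>concept[<TAB>flags]"]
    for e in rs.entries:
        concept_field = (
            f"{e.concept.vocab_prefix}:{e.concept.code}"
            if e.concept.mode == Mode.STANDARD
            else e.concept.concept
        )
        flags = []
        if e.case_sensitive and not rs.case_sensitive_default:
            flags.append("cs")
        if e.is_regex:
            flags.append("regex")
        row = [e.surface, concept_field]
        if flags:
            row.append(",".join(flags))
        lines.append("\t".join(row))
    (directory / lexicon_name).write_text(
        "\n".join(lines) + "\n", encoding="utf-8"
    )
    cfg = {
        "project_num": rs.project_num,
        "project_name": rs.project_name,
        "project_num_width": rs.num_width,
        "case_sensitive_default": rs.case_sensitive_default,
        "lexicon": lexicon_name,
    }
    if rs.context_triggers is not None:
        cfg["triggers"] = "triggers.tsv"
        save_triggers(rs.context_triggers, directory / "triggers.tsv")
    config_path = directory / config_name
    config_path.write_text(
        yaml.safe_dump(cfg, sort_keys=False), encoding="utf-8"
    )
    return config_path
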