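"""Exception types and the issue record shared by the validators."""

from __future__ import annotations

from dataclasses import dataclass


class NotefactError(Exception):
    """Base class for all package-specific errors."""


class RulesetError(NotefactError):
    """A ruleset file is missing, malformed, or internally inconsistent."""


class EncodingError(NotefactError):
    """A mention cannot be rendered as a valid observation_fact code."""


class ConceptParseError(NotefactError):
    """An ``NLP|``-prefixed concept_cd does not match either template."""


class PatternError(NotefactError):
    """An ICD wildcard pattern is syntactically invalid."""


class SpecError(NotefactError):
    """An evaluation spec (cohort, sampling, silver rule) is invalid."""


class UnitMismatchError(NotefactError):
    """Two annotation sets with different units were compared."""


@dataclass(frozen=True)
class Issue:
    """One validation finding. Issues are data, not exceptions."""

    severity: str  # "error" | "warning"
    location: str
    message: str

    def __post_init__(self) -> None:
        if self.severity not in ("error", "warning"):
            raise ValueError(f"unknown severity {self.severity!r}")
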