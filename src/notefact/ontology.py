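"""i2b2 metadata (ontology) table generation for NLP-derived data.

Two query ontologies are generated as flat lists of metadata-table rows:

* **Clinical Concepts by Project** — one folder per project ruleset with
  one leaf per distinct concept; each leaf's ``c_basecode`` is exactly the
  ``concept_cd`` the encoder writes to the fact table, which is the join
  that makes NLP-derived facts queryable.
* **Note Types** — the five LOINC document-ontology axes (type of service,
  kind of document, setting, role, subject matter domain), one folder per
  axis and one leaf per controlled term, with leaf basecodes in the
  rendered note-type form (``STD|<vocab>:<code>`` or ``CUS|<code>``).

Paths are backslash-delimited with a leading and trailing backslash, and
``c_hlevel`` equals the number of path segments minus one. Generation is
deterministic: rebuilding from the same ruleset is byte-identical.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .cdm import NoteTypeCode, encode_concept_cd, parse_concept_cd
from .errors import Issue
from .ruleset import ConceptRef, Mode, Ruleset

log = logging.getLogger(__name__)

DEFAULT_ROOT = "\\ENACT\\NLP\\"
NOTE_TYPE_ROOT = "\\ENACT\\NLP\\Note Types\\"

ONTOLOGY_COLUMNS = (
    "c_hlevel",
    "c_fullname",
    "c_name",
    "c_basecode",
    "c_visualattributes",
    "c_tooltip",
    "c_facttablecolumn",
    "c_tablename",
    "c_columnname",
    "c_operator",
    "c_dimcode",
)

AXIS_NAMES = (
    "type_of_service",
    "kind_of_document",
    "setting",
    "role",
    "subject_matter_domain",
)


def path_level(fullname: str) -> int:
    """c_hlevel implied by a ``\\``-delimited path: segments minus one."""
    return len([s for s in fullname.split("\\") if s]) - 1


def parent_path(fullname: str) -> str:
    segments = [s for s in fullname.split("\\") if s]
    return "\\" + "\\".join(segments[:-1]) + "\\" if len(segments) > 1 else ""


@dataclass(frozen=True)
class OntologyNode:
    """One row of an i2b2 metadata table."""

    c_hlevel: int
    c_fullname: str
    c_name: str
    c_basecode: str = ""
    c_visualattributes: str = "LA"
    c_tooltip: str = ""
    c_facttablecolumn: str = "concept_cd"
    c_tablename: str = "concept_dimension"
    c_columnname: str = "concept_path"
    c_operator: str = "LIKE"
    c_dimcode: str = ""


def _folder(fullname: str, name: str, tooltip: str = "") -> OntologyNode:
    return OntologyNode(
        c_hlevel=path_level(fullname),
        c_fullname=fullname,
        c_name=name,
        c_basecode="",
        c_visualattributes="FA",
        c_tooltip=tooltip or fullname,
        c_dimcode=fullname,
    )


def _leaf(fullname: str, name: str, basecode: str, tooltip: str = "") -> OntologyNode:
    return OntologyNode(
        c_hlevel=path_level(fullname),
        c_fullname=fullname,
        c_name=name,
        c_basecode=basecode,
        c_visualattributes="LA",
        c_tooltip=tooltip or fullname,
        c_dimcode=fullname,
    )


def _display_name(c: ConceptRef) -> str:
    if c.mode == Mode.CUSTOM:
        return c.concept.replace("_", " ").title()
    return f"{c.vocab_prefix} {c.code}"


def _path_segment(c: ConceptRef) -> str:
    if c.mode == Mode.CUSTOM:
        return c.concept
    return f"{c.vocab_prefix} {c.code}"


def _disambiguate(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out: list[str] = []
    for name in names:
        seen[name] = seen.get(name, 0) + 1
        if seen[name] > 1:
            log.warning("duplicate display name %r disambiguated", name)
            out.append(f"{name} ({seen[name]})")
        else:
            out.append(name)
    return out


def build_project_subtree(
    rs: Ruleset, root: str = DEFAULT_ROOT
) -> list[OntologyNode]:
    """One folder for the project plus one leaf per distinct concept.

    Leaf basecodes equal :func:`~notefact.cdm.encode_concept_cd` of the
    concept, closing the join with the fact table. Leaves are ordered by
    concept key for deterministic output.
    """
    if not (root.startswith("\\") and root.endswith("\\")):
        raise ValueError(r"root must start and end with '\'")
    folder_path = f"{root}{rs.project_name}\\"
    nodes = [
        _folder(
            folder_path,
            rs.project_name.replace("_", " ").title(),
            f"Project {rs.project_num}: {rs.project_name}",
        )
    ]
    concepts = sorted(set(rs.concepts()), key=lambda c: c.key())
    names = _disambiguate([_display_name(c) for c in concepts])
    segments = _disambiguate([_path_segment(c) for c in concepts])
    for c, name, segment in zip(concepts, names, segments):
        basecode = encode_concept_cd(c, rs.project_num)
        nodes.append(_leaf(f"{folder_path}{segment}\\", name, basecode))
    return nodes


@dataclass(frozen=True)
class NoteTypeTerm:
    """One controlled term of a document-ontology axis."""

    name: str
    code: NoteTypeCode


@dataclass(frozen=True)
class NoteTypeAxes:
    """The five controlled-term lists of the LOINC document ontology."""

    type_of_service: tuple[NoteTypeTerm, ...]
    kind_of_document: tuple[NoteTypeTerm, ...]
    setting: tuple[NoteTypeTerm, ...]
    role: tuple[NoteTypeTerm, ...]
    subject_matter_domain: tuple[NoteTypeTerm, ...]

    def __post_init__(self) -> None:
        for axis in AXIS_NAMES:
            terms = getattr(self, axis)
            if not terms:
                raise ValueError(f"axis {axis!r} must be non-empty")
            names = [t.name for t in terms]
            if len(set(names)) != len(names):
                raise ValueError(f"axis {axis!r} has duplicate terms")

    @classmethod
    def from_dict(cls, data: dict) -> "NoteTypeAxes":
        """Build axes from a plain mapping (e.g. parsed YAML).

        Each axis maps to a list whose items are either bare strings
        (rendered as CUS codes from the upper-cased name) or mappings with
        ``name``, ``scheme``, ``code`` and, for STD, ``vocabulary``.
        """
        kwargs = {}
        for axis in AXIS_NAMES:
            terms = []
            for item in data.get(axis, []):
                if isinstance(item, str):
                    code = NoteTypeCode(
                        "CUS", item.upper().replace(" ", "_")
                    )
                    terms.append(NoteTypeTerm(item, code))
                else:
                    code = NoteTypeCode(
                        item.get("scheme", "CUS"),
                        str(item["code"]),
                        item.get("vocabulary", ""),
                    )
                    terms.append(NoteTypeTerm(item["name"], code))
            kwargs[axis] = tuple(terms)
        return cls(**kwargs)


def build_note_type_subtree(
    axes: NoteTypeAxes, root: str = NOTE_TYPE_ROOT
) -> list[OntologyNode]:
    """One folder per document-ontology axis, one leaf per term."""
    if not (root.startswith("\\") and root.endswith("\\")):
        raise ValueError(r"root must start and end with '\'")
    nodes: list[OntologyNode] = []
    for axis in AXIS_NAMES:
        axis_display = axis.replace("_", " ").title()
        axis_path = f"{root}{axis_display}\\"
        nodes.append(_folder(axis_path, axis_display))
        for term in getattr(axes, axis):
            nodes.append(
                _leaf(
                    f"{axis_path}{term.name}\\",
                    term.name,
                    term.code.render(),
                )
            )
    return nodes


def validate_hierarchy(nodes: Sequence[OntologyNode]) -> list[Issue]:
    """Table-wide structural checks; empty iff all node invariants hold.

    Nodes at the table's minimum level are treated as subtree roots and are
    exempt from the orphan check (their parents live in the wider network
    ontology)."""
    issues: list[Issue] = []
    if not nodes:
        return issues
    paths: dict[str, int] = {}
    min_level = min(n.c_hlevel for n in nodes)
    for n in nodes:
        loc = n.c_fullname
        expected = path_level(n.c_fullname)
        if n.c_hlevel != expected:
            issues.append(
                Issue(
                    "error",
                    loc,
                    f"c_hlevel {n.c_hlevel} != {expected} implied by the path",
                )
            )
        if n.c_visualattributes not in ("FA", "LA"):
            issues.append(
                Issue("error", loc, f"bad c_visualattributes {n.c_visualattributes!r}")
            )
        if n.c_visualattributes == "LA" and not n.c_basecode:
            issues.append(Issue("error", loc, "leaf with empty c_basecode"))
        if n.c_visualattributes == "FA" and n.c_basecode:
            issues.append(Issue("error", loc, "folder carries a c_basecode"))
        paths[n.c_fullname] = paths.get(n.c_fullname, 0) + 1
    for path, count in paths.items():
        if count > 1:
            issues.append(Issue("error", path, f"duplicate c_fullname x{count}"))
    for n in nodes:
        if n.c_hlevel > min_level and parent_path(n.c_fullname) not in paths:
            issues.append(Issue("error", n.c_fullname, "orphan: parent path missing"))
    return issues


def join_closure(
    concept_cds: Iterable[str], nodes: Sequence[OntologyNode]
) -> dict[str, int]:
    """Map each distinct fact-table concept_cd to the number of ontology
    leaves whose basecode equals it (queryability holds iff every count is
    exactly 1)."""
    leaf_counts: dict[str, int] = {}
    for n in nodes:
        if n.c_visualattributes == "LA" and n.c_basecode:
            leaf_counts[n.c_basecode] = leaf_counts.get(n.c_basecode, 0) + 1
    return {cd: leaf_counts.get(cd, 0) for cd in set(concept_cds)}


def write_ontology(nodes: Sequence[OntologyNode], path: str | Path) -> int:
    """Write metadata rows as CSV; returns the row count."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ONTOLOGY_COLUMNS)
        for n in nodes:
            writer.writerow(
                [
                    str(n.c_hlevel),
                    n.c_fullname,
                    n.c_name,
                    n.c_basecode,
                    n.c_visualattributes,
                    n.c_tooltip,
                    n.c_facttablecolumn,
                    n.c_tablename,
                    n.c_columnname,
                    n.c_operator,
                    n.c_dimcode,
                ]
            )
    return len(nodes)


def read_ontology(path: str | Path) -> list[OntologyNode]:
    path = Path(path)
    nodes: list[OntologyNode] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        for rec in csv.DictReader(fh):
            nodes.append(
                OntologyNode(
                    c_hlevel=int(rec["c_hlevel"]),
                    c_fullname=rec["c_fullname"],
                    c_name=rec["c_name"],
                    c_basecode=rec["c_basecode"],
                    c_visualattributes=rec["c_visualattributes"],
                    c_tooltip=rec["c_tooltip"],
                    c_facttablecolumn=rec["c_facttablecolumn"],
                    c_tablename=rec["c_tablename"],
                    c_columnname=rec["c_columnname"],
                    c_operator=rec["c_operator"],
                    c_dimcode=rec["c_dimcode"],
                )
            )
    return nodes
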