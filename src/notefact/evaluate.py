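"""Federated evaluation: cohorts, silver standards, metrics, error taxonomy.

The evaluation framework mirrors a federated validation workflow: a
development site defines a cohort (ICD wildcard patterns over structured
diagnoses), a note type, and a sampling method; manual review yields a
*gold* standard there, while a *silver* standard computable from
structured data alone lets validation sites evaluate without annotation
capacity. Per-concept precision/recall/F1 are reported together with both
micro (pooled counts) and macro (averaged metrics) aggregates, because
site reports in the wild mix the two conventions.

Error analysis uses a four-class taxonomy: LOGIC (rule/flow defects),
LINGUISTIC (lexical variation, typos), CONTEXTUAL (wrong certainty,
experiencer or temporality), and ANNOTATION (reference-label mistakes).

Conventions fixed here: precision, recall and F1 are all 0 when their
denominators are 0; report tables round half-up to 3 decimals;
mention-level matching counts a true positive when concepts agree and the
spans share at least one character (strict span equality by flag).
"""

from __future__ import annotations

import csv
import logging
import random
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import PatternError, SpecError, UnitMismatchError

log = logging.getLogger(__name__)

GOLD = "GOLD"
SILVER = "SILVER"
PRED = "PRED"
STANDARDS = (GOLD, SILVER, PRED)

UNIT_DOCUMENT = "document"
UNIT_MENTION = "mention"

ERROR_TYPES = ("LOGIC", "LINGUISTIC", "CONTEXTUAL", "ANNOTATION")


# ---------------------------------------------------------------------------
# cohort selection from structured diagnoses


def match_code_pattern(code: str, pattern: str) -> bool:
    """Test an ICD code against a literal or trailing-wildcard pattern.

    ``F11.*`` matches every code starting with ``F11.`` and also the bare
    stem ``F11`` (the dot-aware reading of ICD family patterns);
    comparison is case-insensitive. A ``*`` anywhere but the final
    position raises :class:`PatternError`.
    """
    if not pattern:
        raise PatternError("empty pattern")
    star = pattern.find("*")
    if star != -1 and star != len(pattern) - 1:
        raise PatternError(f"'*' only allowed in final position: {pattern!r}")
    code_cf = code.strip().casefold()
    if star == -1:
        return code_cf == pattern.strip().casefold()
    prefix = pattern[:-1].strip().casefold()
    if code_cf.startswith(prefix):
        return True
    return prefix.endswith(".") and code_cf == prefix[:-1]


@dataclass(frozen=True)
class Sampling:
    """How to sample notes/patients: everything, or a seeded random n."""

    method: str = "all"  # "all" | "random_n"
    n: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("all", "random_n"):
            raise SpecError(f"unknown sampling method {self.method!r}")
        if self.method == "random_n" and self.n <= 0:
            raise SpecError("random_n sampling requires n > 0")


@dataclass(frozen=True)
class EvalSpec:
    """A shareable evaluation spec: cohort patterns, note type, sampling."""

    cohort_patterns: tuple[str, ...]
    note_type: object | None = None  # NoteTypeCode, kept untyped to stay light
    sampling: Sampling = Sampling()

    def __post_init__(self) -> None:
        if not self.cohort_patterns:
            raise SpecError("cohort_patterns must be non-empty")
        for p in self.cohort_patterns:
            match_code_pattern("X", p)  # syntax check only


@dataclass(frozen=True)
class DxRecord:
    """One structured diagnosis: patient, ICD code, date string."""

    patient_num: int
    code: str
    date: str = ""


def _iter_dx(diagnoses: Iterable) -> Iterable[DxRecord]:
    for rec in diagnoses:
        if isinstance(rec, DxRecord):
            yield rec
        elif isinstance(rec, (tuple, list)):
            yield DxRecord(int(rec[0]), str(rec[1]), str(rec[2]) if len(rec) > 2 else "")
        else:
            yield DxRecord(int(rec.patient_num), str(rec.code), str(getattr(rec, "date", "")))


def select_cohort(diagnoses: Iterable, spec: EvalSpec) -> list[int]:
    """Patients with at least one diagnosis code matching at least one
    cohort pattern, sorted; sampling applied afterwards with the spec's
    seed (deterministic)."""
    matched = {
        dx.patient_num
        for dx in _iter_dx(diagnoses)
        if any(match_code_pattern(dx.code, p) for p in spec.cohort_patterns)
    }
    cohort = sorted(matched)
    if not cohort:
        log.warning("cohort selection matched no patients")
    if spec.sampling.method == "random_n" and len(cohort) > spec.sampling.n:
        rng = random.Random(spec.sampling.seed)
        cohort = sorted(rng.sample(cohort, spec.sampling.n))
    return cohort


# ---------------------------------------------------------------------------
# annotation sets


@dataclass(frozen=True)
class AnnotationSet:
    """A reference or prediction set at document or mention granularity.

    ``labels`` maps ``(doc_id, concept)`` to 0/1 for the document unit and
    ``(doc_id, start, end, concept)`` to 1 for the mention unit (mention
    sets list positives only). Patient-level silver standards use the
    patient number rendered as the doc_id.
    """

    standard: str
    unit: str
    labels: Mapping[tuple, int]

    def __post_init__(self) -> None:
        if self.standard not in STANDARDS:
            raise ValueError(f"standard must be one of {STANDARDS}")
        if self.unit not in (UNIT_DOCUMENT, UNIT_MENTION):
            raise ValueError(f"unit must be document or mention")
        width = 2 if self.unit == UNIT_DOCUMENT else 4
        for key, value in self.labels.items():
            if len(key) != width:
                raise ValueError(
                    f"{self.unit}-unit keys must have {width} fields: {key!r}"
                )
            if value not in (0, 1):
                raise ValueError(f"labels must be 0/1, got {value!r}")

    def doc_ids(self) -> set[str]:
        return {key[0] for key in self.labels}

    def positives(self) -> set[tuple]:
        return {key for key, value in self.labels.items() if value == 1}

    def to_csv(self, path: str | Path) -> int:
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["doc_id", "start", "end", "concept", "label", "standard"])
            for key in sorted(self.labels):
                if self.unit == UNIT_DOCUMENT:
                    doc_id, concept = key
                    row = [doc_id, "", "", concept]
                else:
                    doc_id, start, end, concept = key
                    row = [doc_id, str(start), str(end), concept]
                writer.writerow(row + [str(self.labels[key]), self.standard])
        return len(self.labels)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnnotationSet":
        path = Path(path)
        labels: dict[tuple, int] = {}
        units: set[str] = set()
        standards: set[str] = set()
        with path.open("r", encoding="utf-8", newline="") as fh:
            for rec in csv.DictReader(fh):
                standards.add(rec["standard"])
                if rec["start"]:
                    units.add(UNIT_MENTION)
                    key = (
                        rec["doc_id"],
                        int(rec["start"]),
                        int(rec["end"]),
                        rec["concept"],
                    )
                else:
                    units.add(UNIT_DOCUMENT)
                    key = (rec["doc_id"], rec["concept"])
                labels[key] = int(rec["label"])
        if len(units) > 1:
            raise UnitMismatchError(f"{path}: mixed units in one annotation set")
        if len(standards) > 1:
            raise ValueError(f"{path}: mixed standards in one annotation set")
        return cls(
            standard=standards.pop() if standards else GOLD,
            unit=units.pop() if units else UNIT_DOCUMENT,
            labels=labels,
        )


def mention_annotation(mentions: Iterable, standard: str = PRED) -> AnnotationSet:
    """Mention-unit annotation set from extractor output."""
    labels = {
        (m.doc.note_id, m.start, m.end, m.concept.key()): 1 for m in mentions
    }
    return AnnotationSet(standard, UNIT_MENTION, labels)


def document_annotation_from_mentions(
    mentions: Iterable, positive_only: bool = True, standard: str = PRED
) -> AnnotationSet:
    """Document-unit positives from mentions; with ``positive_only`` a
    document counts as positive for a concept only if some mention is
    affirmed, about the patient, and present-tense."""
    labels: dict[tuple, int] = {}
    for m in mentions:
        if positive_only and not (
            m.certainty == "POSITIVE"
            and m.experiencer == "PATIENT"
            and m.temporality == "PRESENT"
        ):
            continue
        labels[(m.doc.note_id, m.concept.key())] = 1
    return AnnotationSet(standard, UNIT_DOCUMENT, labels)


def derive_silver(
    diagnoses: Iterable,
    spec: EvalSpec,
    rule: Mapping[str, str] | Iterable[tuple[str, str]],
) -> AnnotationSet:
    """Compute a document(patient)-level silver standard from structured
    codes alone.

    ``rule`` maps ICD wildcard patterns to concept labels; a patient is
    positive for a label iff some diagnosis code matches some pattern of
    that label. Every patient in ``diagnoses`` receives an explicit 0/1
    for every label. Passing the same normalized pattern twice with
    different labels raises :class:`SpecError`. Purely a function of its
    inputs: same input, same output.
    """
    pairs = list(rule.items()) if isinstance(rule, Mapping) else list(rule)
    if not pairs:
        raise SpecError("silver rule must contain at least one pattern")
    seen: dict[str, str] = {}
    for pattern, label in pairs:
        match_code_pattern("X", pattern)  # syntax check
        norm = pattern.strip().casefold()
        if norm in seen and seen[norm] != label:
            raise SpecError(
                f"contradictory rules for pattern {pattern!r}:"
                f" {seen[norm]!r} vs {label!r}"
            )
        seen[norm] = label
    records = list(_iter_dx(diagnoses))
    patients = sorted({dx.patient_num for dx in records})
    label_names = sorted({label for _, label in pairs})
    labels: dict[tuple, int] = {}
    for patient in patients:
        codes = [dx.code for dx in records if dx.patient_num == patient]
        for label in label_names:
            patterns = [p for p, l in pairs if l == label]
            hit = any(
                match_code_pattern(code, p) for code in codes for p in patterns
            )
            labels[(str(patient), label)] = 1 if hit else 0
    return AnnotationSet(SILVER, UNIT_DOCUMENT, labels)


# ---------------------------------------------------------------------------
# confusion counts and metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


class PRF(NamedTuple):
    precision: float
    recall: float
    f1: float


def prf_from_counts(c: ConfusionCounts) -> PRF:
    """precision = tp/(tp+fp), recall = tp/(tp+fn), F1 their harmonic
    mean; all three are 0 when their denominator is 0."""
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    return PRF(p, r, f)


def f1_from_pr(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= p <= 1.0) or not (0.0 <= r <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    return 2 * p * r / (p + r) if (p + r) else 0.0


def _match_mentions(
    pred: set[tuple], ref: set[tuple], exact_span: bool
) -> tuple[int, int, int]:
    """Greedy one-to-one span matching within one (doc, concept) group."""
    pred_sorted = sorted(pred)
    ref_sorted = sorted(ref)
    used: set[tuple] = set()
    tp = 0
    for r_key in ref_sorted:
        _, r_start, r_end, _ = r_key
        for p_key in pred_sorted:
            if p_key in used:
                continue
            _, p_start, p_end, _ = p_key
            if exact_span:
                hit = (p_start, p_end) == (r_start, r_end)
            else:
                hit = p_start < r_end and r_start < p_end
            if hit:
                used.add(p_key)
                tp += 1
                break
    return tp, len(pred_sorted) - tp, len(ref_sorted) - tp


def confusion(
    pred: AnnotationSet,
    ref: AnnotationSet,
    exact_span: bool = False,
) -> tuple[dict[str, ConfusionCounts], ConfusionCounts]:
    """Per-concept and pooled confusion counts of predictions vs reference.

    Document unit: keys missing from one side count as label 0 there; tn
    is counted over explicitly labelled keys only. Mention unit: a true
    positive needs concept agreement plus span overlap (or equality with
    ``exact_span``).
    """
    if pred.unit != ref.unit:
        raise UnitMismatchError(
            f"cannot compare {pred.unit}-unit predictions with"
            f" {ref.unit}-unit reference"
        )
    per_concept: dict[str, ConfusionCounts] = {}
    if pred.unit == UNIT_DOCUMENT:
        keys = set(pred.labels) | set(ref.labels)
        for key in keys:
            concept = key[1]
            p = pred.labels.get(key, 0)
            r = ref.labels.get(key, 0)
            c = per_concept.get(concept, ConfusionCounts())
            per_concept[concept] = c + ConfusionCounts(
                tp=int(p == 1 and r == 1),
                fp=int(p == 1 and r == 0),
                fn=int(p == 0 and r == 1),
                tn=int(p == 0 and r == 0),
            )
    else:
        groups: dict[tuple[str, str], tuple[set, set]] = {}
        for key in pred.positives():
            doc_concept = (key[0], key[3])
            groups.setdefault(doc_concept, (set(), set()))[0].add(key)
        for key in ref.positives():
            doc_concept = (key[0], key[3])
            groups.setdefault(doc_concept, (set(), set()))[1].add(key)
        for (_, concept), (p_set, r_set) in groups.items():
            tp, fp, fn = _match_mentions(p_set, r_set, exact_span)
            c = per_concept.get(concept, ConfusionCounts())
            per_concept[concept] = c + ConfusionCounts(tp=tp, fp=fp, fn=fn)
    pooled = sum(per_concept.values(), ConfusionCounts())
    return per_concept, pooled


def aggregate(
    per_concept: Mapping[str, ConfusionCounts], mode: str = "micro"
) -> PRF:
    """Site-level metrics from per-concept counts.

    ``micro`` pools the counts and computes metrics once; ``macro``
    averages the per-concept metrics (the F1s are averaged, not
    recomputed from averaged precision/recall).
    """
    if not per_concept:
        raise ValueError("aggregate requires at least one concept")
    if mode == "micro":
        return prf_from_counts(sum(per_concept.values(), ConfusionCounts()))
    if mode == "macro":
        metrics = [prf_from_counts(c) for c in per_concept.values()]
        n = len(metrics)
        return PRF(
            sum(m.precision for m in metrics) / n,
            sum(m.recall for m in metrics) / n,
            sum(m.f1 for m in metrics) / n,
        )
    raise ValueError(f"unknown aggregation mode {mode!r}")


@dataclass(frozen=True)
class MetricReport:
    """Per-concept and aggregate precision/recall/F1 for one site."""

    site_id: str
    per_concept: Mapping[str, PRF]
    micro: PRF
    macro: PRF


def build_report(
    site_id: str,
    pred: AnnotationSet,
    ref: AnnotationSet,
    exact_span: bool = False,
) -> MetricReport:
    """Evaluate predictions against a reference and package the result."""
    per_counts, _ = confusion(pred, ref, exact_span=exact_span)
    return MetricReport(
        site_id=site_id,
        per_concept={k: prf_from_counts(c) for k, c in sorted(per_counts.items())},
        micro=aggregate(per_counts, "micro"),
        macro=aggregate(per_counts, "macro"),
    )


# ---------------------------------------------------------------------------
# gold/silver agreement


@dataclass(frozen=True)
class GoldSilverReport:
    """Agreement of a silver standard with gold, gold taken as truth."""

    percent_agreement: float
    counts: Mapping[str, int]  # both_pos, both_neg, gold_only, silver_only
    precision: float  # of silver vs gold
    recall: float
    n_units: int


def compare_gold_silver(
    gold: AnnotationSet, silver: AnnotationSet
) -> GoldSilverReport:
    """Percent agreement and silver-vs-gold precision/recall over the
    shared documents; raises if the document sets are disjoint."""
    if gold.unit != silver.unit:
        raise UnitMismatchError("gold and silver must share a unit")
    shared = gold.doc_ids() & silver.doc_ids()
    if not shared:
        raise ValueError("gold and silver cover disjoint document sets")
    g_labels = {k: v for k, v in gold.labels.items() if k[0] in shared}
    s_labels = {k: v for k, v in silver.labels.items() if k[0] in shared}
    keys = set(g_labels) | set(s_labels)
    counts = {"both_pos": 0, "both_neg": 0, "gold_only": 0, "silver_only": 0}
    for key in keys:
        g = g_labels.get(key, 0)
        s = s_labels.get(key, 0)
        if g and s:
            counts["both_pos"] += 1
        elif not g and not s:
            counts["both_neg"] += 1
        elif g:
            counts["gold_only"] += 1
        else:
            counts["silver_only"] += 1
    agree = counts["both_pos"] + counts["both_neg"]
    prf = prf_from_counts(
        ConfusionCounts(
            tp=counts["both_pos"],
            fp=counts["silver_only"],
            fn=counts["gold_only"],
            tn=counts["both_neg"],
        )
    )
    return GoldSilverReport(
        percent_agreement=agree / len(keys) if keys else 0.0,
        counts=counts,
        precision=prf.precision,
        recall=prf.recall,
        n_units=len(keys),
    )


# ---------------------------------------------------------------------------
# error taxonomy


@dataclass(frozen=True)
class ErrorRecord:
    """One analyzed misclassification, assigned to the four-class taxonomy."""

    error_type: str
    unit_ref: str
    note: str = ""
    task: str = ""
    focus_area: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        if self.error_type not in ERROR_TYPES:
            raise ValueError(
                f"error_type must be one of {ERROR_TYPES}, got {self.error_type!r}"
            )


def tally_errors(
    records: Sequence[ErrorRecord], by: str | None = None
) -> dict:
    """Count error records per taxonomy class (zero-filled), optionally
    broken down by a task-metadata field (``task``, ``focus_area`` or
    ``method``)."""
    if by is None:
        counts = {etype: 0 for etype in ERROR_TYPES}
        for rec in records:
            counts[rec.error_type] += 1
        return counts
    if by not in ("task", "focus_area", "method"):
        raise ValueError(f"cannot break down by {by!r}")
    nested: dict[str, dict[str, int]] = {}
    for rec in records:
        group = nested.setdefault(
            getattr(rec, by), {etype: 0 for etype in ERROR_TYPES}
        )
        group[rec.error_type] += 1
    return nested


# ---------------------------------------------------------------------------
# cross-site reporting


def round3(x: float) -> float:
    """Round half-up to 3 decimals, the presentation used in site tables
    (0.95779 renders as 0.958)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def cross_site_report(
    reports: Sequence[MetricReport], mode: str = "micro"
) -> pd.DataFrame:
    """One column per site, rows F1/Recall/Precision, rounded half-up to
    3 decimals; duplicate site ids are an error."""
    if not reports:
        raise ValueError("cross_site_report requires at least one report")
    site_ids = [r.site_id for r in reports]
    if len(set(site_ids)) != len(site_ids):
        raise ValueError(f"duplicate site ids in {site_ids}")
    if mode not in ("micro", "macro"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    data = {}
    for r in reports:
        prf = r.micro if mode == "micro" else r.macro
        data[r.site_id] = [round3(prf.f1), round3(prf.recall), round3(prf.precision)]
    return pd.DataFrame(data, index=["F1", "Recall", "Precision"])


def render_report(table: pd.DataFrame) -> str:
    """Plain-text rendering of a cross-site table with 3-decimal cells."""
    return table.to_string(float_format=lambda v: f"{v:.3f}")


def attribute_accuracy(
    pred_mentions: Iterable, gold_records: Iterable, attribute: str
) -> tuple[float, int]:
    """Agreement of one contextual attribute between extracted mentions and
    gold mentions aligned by exact (doc, start, end) span.

    Returns ``(accuracy over aligned pairs, number of aligned pairs)``;
    accuracy is 0.0 when nothing aligns.
    """
    attribute = attribute.lower()
    if attribute not in ("certainty", "experiencer", "temporality"):
        raise ValueError(f"unknown attribute {attribute!r}")
    pred_by_span = {
        (m.doc.note_id, m.start, m.end): getattr(m, attribute)
        for m in pred_mentions
    }
    total = 0
    agree = 0
    for g in gold_records:
        key = (g.doc_id, g.start, g.end)
        if key in pred_by_span:
            total += 1
            agree += int(pred_by_span[key] == getattr(g, attribute))
    return (agree / total if total else 0.0, total)
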