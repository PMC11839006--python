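# Methods

This note documents the procedures the package implements, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where convention
left the design open.

## Extraction

**Sentence segmentation** is rule-based: a sentence ends at a run of
`.!?` followed by whitespace (or end of text), or at a newline. Spans are
0-based half-open character offsets, disjoint, ordered, and cover all
non-whitespace text. The segmenter does not handle abbreviations
("Dr.", "b.i.d.") or enumerated lists; on real notes this truncates some
trigger scopes early, which is conservative (attributes fall back to
defaults) but imprecise. Sentence scope is the context unit throughout.

**Dictionary matching** tests every word-bounded occurrence of each
lexicon surface (case-insensitive unless the entry sets `cs`; regex
entries are matched verbatim and manage their own boundaries). A word
boundary means the adjacent character is not in `[A-Za-z0-9_]`, so
`nap` does not match inside `kidnapping` or `naps` — no stemming or
inflection handling is attempted. Overlaps resolve greedily: candidates
are ranked longest-first, ties by leftmost start then lexicon order, and
a candidate is kept only if it does not overlap an already-kept one.
Candidates with the *identical* span but different concepts are all kept
(one span, several codes); same-span same-concept duplicates are
suppressed. This policy is deterministic and is the same one the
brute-force test oracle implements independently.

**Contextual attributes.** Three attributes with closed vocabularies:
certainty {POSITIVE, NEGATED, POSSIBLE}, experiencer {PATIENT, OTHER},
temporality {PRESENT, HISTORICAL, HYPOTHETICAL}; defaults POSITIVE /
PATIENT / PRESENT. A forward trigger scopes from its end to the sentence
end, a backward trigger from its start back to the sentence start, both
clipped at termination phrases (`but`, `however`, ...); a trigger whose
span overlaps the mention is ignored; when several triggers of one
attribute are in scope the nearest wins. The shipped default list has 42
triggers and 7 terminations; rulesets may replace it entirely via a
trigger TSV. The single-word negation triggers (`no`, `not`, `without`)
favour recall of negation over precision — on real notes they will
occasionally negate the wrong mention inside long coordinated sentences.

## Encoding

Concept codes follow two fixed templates —
`NLP|<PROJECT_NUM>|<VOCAB>:<CODE>` and
`NLP|<PROJECT_NUM>|CUSTOM|<PROJECT>:<CONCEPT>` — and the `NLP|` prefix is
the single test that partitions NLP-derived from structured rows in a
mixed fact table. Tokens may not contain `|` or `:`; the project number
is zero-padded digits (width 3 by default, configurable). The
`concept_cd` length cap defaults to 50 characters (a common DDL limit);
an over-length code is an *error*, never a truncation, because silent
truncation corrupts codes.

Choices where the conventions are silent:

* the base row uses `modifier_cd="@"` (the i2b2 idiom for "no
  modifier") and `valtype_cd=""` — the attribute values live in the
  modifier rows, so nothing is put in `tval_char`;
* numeric attributes use modifier token `NLP|<NAME>:VALUE` with
  `valtype_cd="N"`, `nval_num` = value, `tval_char` = unit, keeping the
  printed `NLP|ATTRIBUTE:VALUE` shape while routing numbers to the
  numeric column;
* `instance_num` is a running counter starting at 1 within each
  (patient, encounter, concept_cd, start_date) group, so grouping by that
  tuple plus `instance_num` recovers exactly one group per source
  mention;
* `start_date` is the note timestamp; `provider_id` defaults to `NLP@`;
* the two extension columns (`cohort_query_id`, `note_type_cd`) can be
  switched off for vanilla schemas; both STD and CUS note-type schemes
  are supported and neither is mandated;
* `observation_blob` is OFF by default: sentence snippets may contain
  protected health information.

Fact CSV I/O is RFC 4180 via the stdlib `csv` module; floats are written
with `repr` so `write_facts`/`read_facts` round-trips bit-exactly.

## Ontologies

Paths are backslash-delimited, rooted at `\ENACT\NLP\` by default (the
published subtrees appear only as a screenshot, so exact paths are
self-defined here); `c_hlevel` equals the number of path segments minus
one. Project subtrees hold one folder per project and one leaf per
distinct concept, ordered by concept key so rebuilding is byte-identical;
leaf `c_basecode` equals the encoded `concept_cd` (join closure with the
fact table is asserted in tests). Display names are derived by
underscore→space title-casing, with numeric suffixes on collisions.
Query-plumbing columns use conventional fact-table wiring
(`concept_cd` / `concept_dimension` / `concept_path` / `LIKE`).
`validate_hierarchy` checks levels, duplicate paths, folder/leaf basecode
rules, and orphans; nodes at the table's minimum level count as subtree
roots whose parents live in the wider network ontology.

## Evaluation

**Wildcard patterns.** A pattern is a literal code or a prefix ending in
`*` (anywhere else is an error); comparison is case-insensitive and the
dot is literal. A family pattern whose stem ends with a dot also matches
the bare stem (`F11` matches `F11.*`), since ICD parents are conventionally
included in their family.

**Silver standards** are computed from structured diagnoses alone: a rule
maps patterns to concept labels, and every patient in the diagnosis table
receives an explicit 0/1 per label. Patient-level labels are emitted as a
document-unit annotation set with the patient number as the document id;
per-note silver standards can be built by joining on the corpus. The same
normalized pattern mapped to two different labels is rejected;
prefix-overlapping patterns with different labels are legitimate
multi-label rules.

**Matching and metrics.** Document-unit comparison treats keys absent
from one side as label 0; true negatives are counted over explicitly
labelled keys only. Mention-unit comparison requires concept agreement
plus any character overlap (strict span equality by flag) and matches
greedily one-to-one in span order. Precision, recall and F1 are 0
whenever their denominator is 0. Both micro (pool counts, then compute)
and macro (average per-concept metrics; F1 averaged, not recomputed)
aggregates are first-class outputs: published site tables demonstrably
mix the two conventions, and neither alone reproduces every report.
Report tables round half-up to 3 decimals (0.95779 → 0.958), matching
how such tables are printed.

**Gold/silver agreement** is percent agreement over the shared documents
plus silver-vs-gold precision/recall with gold as truth; chance-corrected
coefficients are out of scope. **Error analysis** uses the four-class
taxonomy LOGIC / LINGUISTIC / CONTEXTUAL / ANNOTATION; unknown classes
are rejected at ingest and tallies are zero-filled.

## Synthetic corpora

The generator emulates the statistical shape of a targeted-extraction
workload: notes containing planted lexicon terms under controlled cue
phrases, distractor sentences, a note-type mix, and structured diagnosis
records planted per patient. Sentences are filled from fixed templates so
the span of every planted term is known exactly; distractor vocabulary is
filtered so no word of any lexicon surface appears in it (no sequence of
distractor words can spell a surface). All randomness flows from the
single `GenSpec.seed`.

Defaults (the standard conditions used by the tests and the acceptance
script): 200 documents, one patient and one encounter per document,
per-concept mention rate 0.3, cue-class rates NEGATED 0.2 / POSSIBLE 0.1 /
OTHER 0.1 / HISTORICAL 0.1 / HYPOTHETICAL 0.1 (remainder trigger-free),
1–3 distractor sentences per document, note-type mix 60% `STD|LOINC:59258-4`
/ 40% `CUS|PROGRESS`, and diagnosis planting probabilities spanning
cohort-relevant codes (`F11.20` 0.15, `T43.611A` 0.05, `G90.50` 0.05) and
background noise (`E11.9` 0.4, `I10` 0.5). The default toy ruleset is a
sleep-phenotyping project with five custom concepts over seven surfaces.

The keystone self-consistency property — extraction with the generator's
own ruleset reproduces the gold set *exactly*, spans, concepts and all
three attributes — is what makes the perfect end-to-end scores meaningful:
they certify losslessness of the pipeline under unambiguous input, not
clinical accuracy. Real notes differ in every way that matters for NLP
difficulty: lexical variation, misspellings, ambiguous and coordinated
negation scopes, section structure, copy-forward text, abbreviations.
Passing tests therefore validate the *conventions and plumbing* (offsets,
encodings, joins, metric arithmetic), and the noise injector exists
precisely to break perfection in controlled ways: length-preserving typos
on planted surfaces (LINGUISTIC errors), held-out cue synonyms the
trigger list does not know (CONTEXTUAL — spans still align but certainty
degrades), and gold-label flips (ANNOTATION), each recorded in a
manifest.

## Numerical and degenerate-input conventions

* 0/0 → 0 for precision, recall, F1, and agreement rates.
* Report rounding: decimal half-up at 3 places (not banker's rounding).
* Empty corpus, empty lexicon, empty text, header-only CSVs: all legal,
  all yield empty outputs (a warning where silence would be surprising).
* Ties in matching are broken deterministically (length, start, lexicon
  order); repeated runs are byte-identical everywhere.
* Timestamps are ISO 8601 with a space separator; round-trips are exact.

## Known limitations

* The sentence segmenter and trigger list are English-only and
  deliberately small; they are not a clinical-grade ConText
  implementation.
* Trigger scope is all-or-nothing within a sentence; no pseudo-trigger
  handling ("no increase in") or scope-width limits.
* Ruleset serialization cannot represent a ruleset whose
  `case_sensitive_default` is true but which contains case-insensitive
  entries; the loader normalizes custom concept tokens to upper case.
* The ontology generator emits structurally valid subtrees, not a
  node-for-node reproduction of any deployed network ontology.
* Silver standards are patient-level; mention-level silver is not
  derivable from structured data and is not attempted.
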