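# notefact

Clinical text to queryable i2b2 facts: dictionary-based concept extraction
with contextual attributes, bit-exact encoding into the i2b2
`observation_fact` entity-attribute-value model, query-ontology
generation, and a federated gold/silver evaluation harness — plus a
synthetic clinical-note generator so everything runs and is testable
without protected health information.

## Who this is for

Informatics teams at sites of federated EHR research networks who need to
(1) run targeted NLP algorithms over local clinical notes, (2) load the
extracted facts into an i2b2 clinical data warehouse using shared, network-
wide conventions so cohort queries work identically everywhere, and (3)
validate an algorithm developed elsewhere against a locally computable
reference standard.

## The model

**Extraction.** A *ruleset* couples a project identity (zero-padded
project number, uppercase project name) with a lexicon mapping surface
forms to concepts from either a standard terminology (e.g.
`ICD-10-CM:S92.4`) or a custom project terminology (e.g. `SLEEP:SNORING`).
Matching is sentence-scoped, word-bounded, and case-insensitive by
default; overlaps resolve greedily longest-first. Each mention then
receives three contextual attributes via a ConText-style trigger
algorithm — certainty ∈ {POSITIVE, NEGATED, POSSIBLE}, experiencer ∈
{PATIENT, OTHER}, temporality ∈ {PRESENT, HISTORICAL, HYPOTHETICAL} — with
trigger scopes clipped at sentence boundaries and termination phrases.

**Encoding.** A mention becomes one base `observation_fact` row
(`modifier_cd = "@"`) plus one row per attribute:

```
concept_cd  = NLP|<PROJECT_NUM>|<VOCAB>:<CODE>              (standard)
            | NLP|<PROJECT_NUM>|CUSTOM|<PROJECT>:<CONCEPT>  (custom)
modifier_cd = NLP|<ATTRIBUTE>:<VALUE>        e.g. NLP|EXPERIENCER:PATIENT
```

All rows of one mention share `(patient_num, encounter_num, concept_cd,
start_date, instance_num)`. Numeric attributes (e.g. a 325 mg dose) route
to `nval_num` with `valtype_cd="N"`. Two optional columns extend the
vanilla schema: the cohort Query ID and the note-type code
(`STD|LOINC:59258-4` or `CUS|<local>`); text snippets go to
`observation_blob` only when explicitly enabled.

**Querying.** Two metadata-table ontologies are generated: *Clinical
Concepts by Project* (one leaf per concept, leaf `c_basecode` equal to the
encoded `concept_cd` — the join that makes facts queryable) and *Note
Types* (the five LOINC document-ontology axes).

**Evaluation.** Cohorts are selected by ICD wildcard patterns (`F11.*`,
`T43.6*`, ...); a *silver* standard is computed from structured diagnoses
alone, a *gold* standard is read from annotation files. Metrics are
per-concept precision/recall/F1 with both micro (pooled counts) and macro
(averaged metrics) aggregates, where F1 = 2PR/(P+R) and 0/0 = 0. Errors
are tallied by the four-class taxonomy LOGIC / LINGUISTIC / CONTEXTUAL /
ANNOTATION.

## Worked example

```bash
notefact synth --seed 7 --out-dir fx
notefact extract --ruleset fx/ruleset/config.yaml --notes fx/notes.csv --out mentions.jsonl
notefact encode  --mentions mentions.jsonl --project-num 001 --query-id Q99 --out facts.csv
notefact ontology build --ruleset fx/ruleset/config.yaml --out meta.csv
notefact evaluate --pred mentions.jsonl --ref fx/gold.csv --unit mention --out report.csv
```

prints

```
200 notes, 292 gold mentions, 240 diagnoses -> fx (ruleset: fx/ruleset/config.yaml)
292 mentions from 200 notes -> mentions.jsonl
1168 fact rows from 292 mentions -> facts.csv
6 ontology rows -> meta.csv
           site
F1        1.000
Recall    1.000
Precision 1.000
```

The generator planted 292 mentions with known spans and attributes in 200
notes; extraction with the matched ruleset recovers all of them (perfect
precision/recall by construction — the keystone self-consistency check).
Each mention became 4 fact rows (base + certainty + experiencer +
temporality), e.g.

```
1000,5000,NLP|001|CUSTOM|SLEEP:SLEEP_QUALITY_BAD,NLP@,2024-03-18 13:28:00,@,1,,,,,Q99,STD|LOINC:59258-4
1000,5000,NLP|001|CUSTOM|SLEEP:SLEEP_QUALITY_BAD,NLP@,2024-03-18 13:28:00,NLP|CERTAINTY:NEGATED,1,,,,,Q99,STD|LOINC:59258-4
```

and every distinct `concept_cd` in `facts.csv` joins exactly one leaf
`c_basecode` in `meta.csv`.

The same works in Python:

```python
from notefact import (GenSpec, generate_corpus, toy_sleep_ruleset,
                      extract_corpus, encode_mentions, EncodeOptions)

corpus = generate_corpus(GenSpec(seed=7, n_docs=200))
mentions = extract_corpus(corpus.documents, toy_sleep_ruleset())
facts = encode_mentions(mentions, EncodeOptions(project_num="001"))
```

## Layout

| module | role |
| --- | --- |
| `notefact.ruleset` | lexicon + config loading, validation, serialization |
| `notefact.context` | attribute vocabularies, default trigger list |
| `notefact.extract` | sentence segmentation, dictionary matching, context |
| `notefact.cdm` | observation_fact encoding/parsing, CSV and SQL output |
| `notefact.ontology` | metadata-table generation and validation |
| `notefact.evaluate` | cohorts, silver standards, metrics, error taxonomy |
| `notefact.synthnotes` | synthetic corpora with planted ground truth |
| `notefact.io` | corpus / mention / diagnosis file formats |
| `notefact.cli` | the `notefact` console entry point |

See `docs/methods.md` for the design rationale, parameter defaults, and
known limitations.
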