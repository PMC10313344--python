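# metacurate

Semi-supervised harmonization of messy sample-metadata tables against a
controlled vocabulary, with multi-dataset integration and a GLP-style,
replayable audit trail.

Public omics repositories are full of studies whose *data* follow strict
format standards while their *metadata* — the samples × features table
saying which dose, exposure time, tissue or donor ethnicity each sample
corresponds to — are free text typed by different labs in different
styles. Harmonizing that text against a shared vocabulary is what makes
datasets integrable and FAIR, but fully automatic cleaning is not
trustworthy and fully manual cleaning is neither reproducible nor
auditable. `metacurate` takes the middle road: the machine proposes,
the curator decides, and every decision is recorded with a mandatory
justification so the entire curation can be reconstructed step by step.

## The model

The vocabulary is two linked layers of `canonical term → synonyms`
maps: features (column concepts such as `ethnicity`, synonym `race`)
and, within each feature, instances (values such as `Black`, synonyms
`B`, `African-American`). A query term is resolved in three tiers —
verbatim equality, equality after normalization (casefold, trim,
punctuation `[_.,;:/()-]` → space), and optionally fuzzy matching by
token-set normalized-Levenshtein similarity (default threshold 0.85).
Fuzzy hits are only ever *proposed*; ties are reported as ambiguous,
never guessed.

Curation of one table runs in three stages: (i) renaming of columns to
canonical features, (ii) deletion or cell-wise coalescing of duplicate
columns, (iii) replacement of each unique instance value. Each candidate
change is a proposal the user accepts, rejects or edits; terms no
vocabulary resolves are staged into a temporary vocabulary pending
promotion. Integration stacks curated tables and classifies every
feature GREEN / AMBER / RED (reference-resolved everywhere / only
temporary-vocabulary or missing-from-a-dataset defects / unresolvable or
conflicting), aggregating conservatively by the worst check.

## Worked example

```python
from metacurate import (MetadataTable, ethnicity_vocabulary,
                        run_auto_curation, curated_table)

vocab = ethnicity_vocabulary()   # ethnicity/race; Black, White, Inuit
table = MetadataTable("geo1", ["race"],
                      [["African-American"], ["B"], ["Caucasian"],
                       ["C"], ["Inuit"]])
state = run_auto_curation(table, vocab)
out = curated_table(state)
print(out.column_headers)          # ['ethnicity']
print([r[0] for r in out.rows])    # ['Black', 'Black', 'White', 'White', 'Inuit']
print(len(state.trail.records))    # 5  (1 rename + 4 value replacements, all audited)
```

The header `race` is renamed to the canonical feature `ethnicity`, and
every synonym spelling is replaced by its canonical instance; the five
audit records are the complete, replayable explanation of every
difference between input and output.

The same scenario from the shell:

```bash
metacurate fixture --seed 5 --out-dir fx          # synthetic messy datasets
metacurate curate fx/ds1.messy.csv fx/ds2.messy.csv \
    --vocabulary fx/vocabulary.json --out-dir curated
metacurate integrate curated/ds1.messy.curated.csv curated/ds2.messy.curated.csv \
    --vocabulary fx/vocabulary.json --out-dir multi
metacurate replay --session curated/session.json   # exit 0 iff reconstructible
```

`metacurate curate --glp-mode` refuses any decision that lacks a
justification (exit code 4) before touching the data. Decision files
(`--decisions`) replace the interactive user for scripted runs; exit
codes are stable (0 ok, 2 input, 3 vocabulary, 4 GLP, 5 replay
divergence).

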