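# Methods

## Vocabulary model

A vocabulary is a set of canonical *features*, each carrying a synonym
set and a map from canonical *instances* to their synonym sets — two
linked layers of `canonical → synonyms` dictionaries. The published
description of this structure admits more than one reading; this
package fixes the reading "feature→synonyms map, linked to per-feature
instance→synonyms maps", which is the minimal structure that supports
both column renaming and value harmonization. Structural invariants
(enforced by `validate_vocabulary`, and re-checked after every merge):

- feature keys are unique after normalization;
- no normalized term (key or synonym) resolves to two different
  features; a canonical key is implicitly a synonym of itself;
- within one feature, no normalized instance term resolves to two
  different canonical instances.

Synonym sets may be empty. Canonical spellings are preserved for
display; every comparison happens in normalized space.

## Term normalization and matching

`normalize_term` casefolds, trims, maps the punctuation set
`[_.,;:/()-]` to spaces and collapses whitespace runs; it is pure and
idempotent. Resolution is tiered:

1. **exact** — verbatim string equality with a key or synonym;
2. **normalized** — equality after `normalize_term`;
3. **fuzzy** — token-set normalized-Levenshtein similarity
   `1 − d(a*, b*) / max(|a*|, |b*|)`, where `a*`, `b*` are the
   normalized strings with tokens sorted, so word order is never
   penalized. Edit distance is computed with `edlib`; the test suite
   cross-checks it against an independent dynamic-programming
   implementation.

The default fuzzy threshold of 0.85 accepts roughly one edit in a
seven-character token and avoids collapsing short codes (`B` vs `C`);
it is exposed as a parameter everywhere. Whether matching ought to be
exact or approximate is genuinely open; both are provided, and the
semi-supervised contract is kept by never auto-applying a fuzzy hit:
ties at the top score are flagged ambiguous with no canonical key, and
only the interactive or batch user can accept a fuzzy proposal.

## Curation pipeline

Stages are monotone: rename → dedup → values → done; operations called
out of stage raise. Every candidate change is a `Proposal` with a
deterministic identifier (stage, column position, normalized term), so
batch decision files remain valid across runs.

- **Duplicates** are defined by equal canonicalized headers, not by
  content — stage (ii) follows renaming, and content equality is used
  only to decide whether a coalesce is safe. Content-identical columns
  under different canonical names are treated as distinct concepts.
  Coalescing keeps the first column and fills its missing cells from
  the duplicates (first non-missing value wins); any row holding two
  distinct non-missing values blocks the merge with the row indices
  listed, and the group can instead be kept whole or reduced to one
  named column.
- **Missing values** are cells whose stripped, casefolded content is in
  `{"", "na", "n/a", "null", "-"}` (configurable). The set matters only
  for coalescing and for skipping value proposals.
- **Value harmonization** operates per unique non-missing value of a
  column, not per cell; accepting a proposal rewrites every equal cell.
  Columns whose headers are not canonical features are left untouched
  and surface later in the integration report.
- Terms no vocabulary resolves are staged into a **temporary
  vocabulary** (pending/approved/rejected — the same colour semantics
  as integration). A term resolvable in the reference vocabulary can
  never be staged, and promotion (`merge_temp`) is atomic: the merged
  vocabulary is re-validated and any collision aborts the whole merge.

## Integration semantics

The colour rules are this package's formalization (the colour system's
published description names the colours but not the rules): GREEN
requires reference-vocabulary resolution of the feature and all
observed instances plus presence in every dataset; temporary-vocabulary
resolution or absence from a dataset caps at AMBER; unresolvable terms
or one normalized header mapping to different canonical features force
RED. Statuses are computed per feature *and* per instance, and a
feature's overall status is the minimum over all its checks — the
report is deliberately conservative, and temporary-vocabulary entries
are never GREEN so that promotion stays an explicit, audited act.
Integration synthesizes `sample_id` as `dataset_id-ordinal` when no
identifier column exists, orders features by normalized name and rows
by input dataset order, and never alters a cell value.

## Audit, GLP mode and replay

Every applied or rejected action appends exactly one record (seq
consecutive from 1). GLP mode is fixed at session creation; in it, a
record without a non-blank justification is refused *before* any state
mutates, for **all** action kinds including rejections — presence, not
quality, of the justification is what is checked. Accepted no-op
proposals (suggestion equal to the current text) are recorded with
`before == after`; completeness accounting therefore counts records
whose `before` and `after` differ.

Replay re-executes the log against the original tables and the starting
vocabulary. Records carry column positions and verbatim before/after
strings, so replay verifies each step against the evolving table and
fails loudly (naming the `seq`) when log and inputs do not belong
together. Timestamps are recorded for the report but excluded from
replay semantics and structural equality: reproducibility must not
depend on wall-clock. Sessions serialize to a single versioned JSON
document; successive saves of one session are prefix-consistent in
their record lists.

## Synthetic data generator

The generator emulates uncurated repository exports: a vocabulary of
pronounceable consonant-vowel terms (so single-character typos stay
meaningful for fuzzy matching), fully canonical ground-truth tables,
and a corruption pass with per-token probabilities for synonym swaps,
case mangling, typos, missing tokens, duplicated columns and
out-of-vocabulary terms. Defaults (5 features, 2–5 instances each, 0–3
synonyms per term, 3 datasets × 25 rows, swap 0.5 / case 0.2) mirror a
small multi-study curation campaign: a handful of GEO-sized annotation
tables over a shared feature set. The whole fixture is a pure function
of its spec; one stream seeded once is consumed in the order
vocabulary → tables → corruption, so each part can be regenerated
independently. Duplicated columns are appended with cells copied from
the messy original or blanked, so a coalesce can never conflict by
construction. The generator returns the exact messy→truth mapping,
which is how recovery is scored without external data.

What the generator does **not** emulate: multi-token free-prose cells,
cross-feature semantic constraints (dose–unit consistency), structured
identifiers, or realistic synonym frequency distributions. Passing
tests therefore demonstrate the mechanics of harmonization, audit and
integration, not performance on real-world annotation prose.

## Problem sizes and numerical choices

The test suite and the acceptance script run at deliberately small
scale — hundreds of sessions of a few features × a handful of rows —
because every property checked (recovery, replay identity, GLP
soundness, idempotence, round-trips) is size-independent: the small
sizes exercise all code paths (duplicates, conflicts, staging,
unknown terms) while keeping the whole suite near-instant. Fuzzy
scores are compared exactly against the brute-force oracle (both sides
compute the same rational numbers); the only tolerance in the package
is the user-facing fuzzy threshold itself.

## Known limitations

- Cell-level (row-specific) edits are out of scope; harmonization is
  per unique value.
- Only the native JSON vocabulary format is read; OBO/OWL ontologies
  must be restructured externally.
- Instances can be staged only under reference-vocabulary features, so
  values observed under a still-unpromoted feature remain RED until the
  feature is promoted first — a deliberate two-step promotion.
- The audit log is plain JSON: replayable and diffable, but not
  tamper-evident; regulatory e-signature workflows are out of scope.
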