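"""Deterministic synthetic vocabularies and messy metadata tables.

The generator emulates the shape of uncurated sample-annotation tables:
a ground-truth vocabulary of features (think dose / time / tissue /
ethnicity), clean tables whose headers and cells are canonical terms, and
a corruption pass that degrades them the way real exports do — synonym
spellings, case mangling, typos, missing tokens, duplicated columns and
out-of-vocabulary terms.  The exact messy-cell -> truth mapping is
returned, so curation quality can be scored without any external data.

Everything is a pure function of :class:`FixtureSpec`: one pseudo-random
stream, seeded once, consumed in the fixed order vocabulary -> tables ->
corruption, so each piece can be regenerated independently and stably.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field, replace
from typing import Mapping

from .curation import MetadataTable
from .exceptions import MetacurateError
from .vocabulary import FeatureEntry, Vocabulary, normalize_term

__all__ = [
    "CorruptionProfile",
    "FixtureSpec",
    "corrupt",
    "ethnicity_vocabulary",
    "make_fixture",
    "make_ground_truth_tables",
    "make_vocabulary",
]

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"
_MISSING_TOKENS = ("NA", "N/A", "null", "-", "")


def ethnicity_vocabulary() -> Vocabulary:
    """The worked single-feature example vocabulary.

    'ethnicity' (synonym 'race') with instances Black ('B',
    'African-American'), White ('Caucasian', 'C') and Inuit (no
    synonyms).  Used throughout the docs and tests as the minimal
    end-to-end scenario.
    """
    return Vocabulary(
        name="ethnicity-example",
        version="1",
        features={
            "ethnicity": FeatureEntry(
                canonical_name="ethnicity",
                synonyms=frozenset({"race"}),
                instances={
                    "Black": frozenset({"B", "African-American"}),
                    "White": frozenset({"Caucasian", "C"}),
                    "Inuit": frozenset(),
                },
            )
        },
    )


@dataclass(frozen=True)
class CorruptionProfile:
    """Per-token corruption probabilities, each in [0, 1]."""

    p_synonym_swap: float = 0.5
    p_case_mangle: float = 0.2
    p_typo: float = 0.0
    p_missing: float = 0.0
    p_duplicate_column: float = 0.0
    p_unknown_term: float = 0.0

    def __post_init__(self):
        for name in ("p_synonym_swap", "p_case_mangle", "p_typo",
                     "p_missing", "p_duplicate_column", "p_unknown_term"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise MetacurateError(f"{name}={p} outside [0, 1]")

    @classmethod
    def recoverable(cls, p_synonym_swap: float = 0.5, p_case_mangle: float = 0.3,
                    p_duplicate_column: float = 0.3) -> "CorruptionProfile":
        """Corruption drawn only from known synonyms and casing.

        With no typos, no unknown terms and no missing-token injection,
        the accept-all-exact policy recovers the ground truth exactly.
        """
        return cls(p_synonym_swap=p_synonym_swap, p_case_mangle=p_case_mangle,
                   p_typo=0.0, p_missing=0.0,
                   p_duplicate_column=p_duplicate_column, p_unknown_term=0.0)


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_features: int = 5
    instances_per_feature: tuple[int, int] = (2, 5)
    synonyms_per_term: tuple[int, int] = (0, 3)
    n_datasets: int = 3
    rows_per_dataset: int = 25
    corruption: CorruptionProfile = field(default_factory=CorruptionProfile)

    def __post_init__(self):
        if self.n_features < 1 or self.n_datasets < 1 or self.rows_per_dataset < 1:
            raise MetacurateError("all fixture counts must be >= 1")
        if self.instances_per_feature[0] < 1:
            raise MetacurateError("instances_per_feature lower bound must be >= 1")
        if self.synonyms_per_term[0] < 0:
            raise MetacurateError("synonyms_per_term lower bound must be >= 0")


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one messy position (header row = row -1)."""

    dataset_id: str
    row: int          # -1 for a header
    col: int
    messy: str
    truth: str
    corruptions: tuple[str, ...]


# ---------------------------------------------------------------------------
# Generation internals (single shared stream)
# ---------------------------------------------------------------------------

def _word(rng: random.Random, syllables: int) -> str:
    return "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
                   for _ in range(syllables))


def _fresh_term(rng: random.Random, taken: set[str], syllables=(2, 4)) -> str:
    while True:
        term = _word(rng, rng.randint(*syllables))
        if normalize_term(term) not in taken:
            taken.add(normalize_term(term))
            return term


def _gen_vocabulary(rng: random.Random, spec: FixtureSpec) -> Vocabulary:
    taken: set[str] = set()
    feats: dict[str, FeatureEntry] = {}
    for _ in range(spec.n_features):
        fname = _fresh_term(rng, taken)
        fsyns = frozenset(
            _fresh_term(rng, taken)
            for _ in range(rng.randint(*spec.synonyms_per_term)))
        instances = {}
        for _ in range(rng.randint(*spec.instances_per_feature)):
            iname = _fresh_term(rng, taken)
            isyns = frozenset(
                _fresh_term(rng, taken)
                for _ in range(rng.randint(*spec.synonyms_per_term)))
            instances[iname] = isyns
        feats[fname] = FeatureEntry(canonical_name=fname, synonyms=fsyns,
                                    instances=instances)
    return Vocabulary(features=feats, name=f"fixture-{spec.seed}", version="1")


def _gen_tables(rng: random.Random, spec: FixtureSpec,
                v: Vocabulary) -> list[MetadataTable]:
    headers = list(v.features)
    tables = []
    for d in range(spec.n_datasets):
        rows = []
        for _ in range(spec.rows_per_dataset):
            rows.append([rng.choice(list(v.features[h].instances)) for h in headers])
        tables.append(MetadataTable(
            dataset_id=f"ds{d + 1}", column_headers=list(headers), rows=rows))
    return tables


def _mangle_case(rng: random.Random, term: str) -> str:
    out = "".join(c.upper() if rng.random() < 0.5 else c.lower() for c in term)
    return out if out != term else (term.upper() if term != term.upper()
                                    else term.lower())


def _typo(rng: random.Random, term: str) -> str:
    if not term:
        return rng.choice(string.ascii_lowercase)
    i = rng.randrange(len(term))
    op = rng.choice(("sub", "del", "ins"))
    c = rng.choice(string.ascii_lowercase)
    if op == "sub":
        return term[:i] + c + term[i + 1:]
    if op == "del" and len(term) > 1:
        return term[:i] + term[i + 1:]
    return term[:i] + c + term[i:]


def _corrupt_term(rng: random.Random, truth: str, synonyms: tuple[str, ...],
                  prof: CorruptionProfile, taken: set[str],
                  allow_missing: bool) -> tuple[str, list[str]]:
    messy, kinds = truth, []
    if prof.p_unknown_term and rng.random() < prof.p_unknown_term:
        return _fresh_term(rng, taken), ["unknown_term"]
    if allow_missing and prof.p_missing and rng.random() < prof.p_missing:
        return rng.choice(_MISSING_TOKENS), ["missing"]
    if synonyms and rng.random() < prof.p_synonym_swap:
        messy = rng.choice(sorted(synonyms))
        kinds.append("synonym_swap")
    if rng.random() < prof.p_case_mangle:
        messy = _mangle_case(rng, messy)
        kinds.append("case_mangle")
    if prof.p_typo and rng.random() < prof.p_typo:
        messy = _typo(rng, messy)
        kinds.append("typo")
    return messy, kinds


def _corrupt_tables(rng: random.Random, spec: FixtureSpec, v: Vocabulary,
                    truth_tables: list[MetadataTable],
                    ) -> tuple[list[MetadataTable], list[CellTruth]]:
    prof = spec.corruption
    taken = {normalize_term(term) for term, _ in v.feature_terms()}
    for f in v.features:
        taken |= {normalize_term(term) for term, _ in v.instance_terms(f)}

    messy_tables: list[MetadataTable] = []
    mapping: list[CellTruth] = []
    for truth in truth_tables:
        t = truth.copy()
        # headers: synonym/case/typo corruption (never missing)
        for j, header in enumerate(list(t.column_headers)):
            entry = v.features[header]
            messy, kinds = _corrupt_term(
                rng, header, tuple(sorted(entry.synonyms)), prof, taken,
                allow_missing=False)
            t.column_headers[j] = messy
            mapping.append(CellTruth(t.dataset_id, -1, j, messy, header, tuple(kinds)))
        # cells
        for i, row in enumerate(t.rows):
            for j, cell in enumerate(row):
                feature = truth.column_headers[j]
                syns = tuple(sorted(v.features[feature].instances[cell]))
                messy, kinds = _corrupt_term(rng, cell, syns, prof, taken,
                                             allow_missing=True)
                row[j] = messy
                mapping.append(CellTruth(t.dataset_id, i, j, messy, cell, tuple(kinds)))
        # duplicated columns: appended at the end, cells copied-or-blanked
        # from the messy original so a coalesce can never conflict
        n_orig = len(truth.column_headers)
        for j in range(n_orig):
            if rng.random() >= prof.p_duplicate_column:
                continue
            feature = truth.column_headers[j]
            entry = v.features[feature]
            dup_header, kinds = _corrupt_term(
                rng, feature, tuple(sorted(entry.synonyms)), prof, taken,
                allow_missing=False)
            new_j = len(t.column_headers)
            t.column_headers.append(dup_header)
            mapping.append(CellTruth(
                t.dataset_id, -1, new_j, dup_header, feature,
                tuple(kinds) + ("duplicate_column",)))
            for row in t.rows:
                row.append("" if rng.random() < 0.5 else row[j])
        messy_tables.append(t)
    return messy_tables, mapping


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def make_fixture(spec: FixtureSpec):
    """(vocabulary, ground-truth tables, messy tables, cell mapping)."""
    rng = random.Random(spec.seed)
    v = _gen_vocabulary(rng, spec)
    truth = _gen_tables(rng, spec, v)
    messy, mapping = _corrupt_tables(rng, spec, v, truth)
    return v, truth, messy, mapping


def make_vocabulary(spec: FixtureSpec) -> Vocabulary:
    rng = random.Random(spec.seed)
    return _gen_vocabulary(rng, spec)


def make_ground_truth_tables(spec: FixtureSpec, v: Vocabulary) -> list[MetadataTable]:
    rng = random.Random(spec.seed)
    _gen_vocabulary(rng, spec)  # advance the shared stream past stage 1
    return _gen_tables(rng, spec, v)


def corrupt(tables: list[MetadataTable], v: Vocabulary, spec: FixtureSpec,
            ) -> tuple[list[MetadataTable], list[CellTruth]]:
    rng = random.Random(spec.seed)
    _gen_vocabulary(rng, spec)
    _gen_tables(rng, spec, v)  # advance past stage 2
    return _corrupt_tables(rng, spec, v, tables)
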