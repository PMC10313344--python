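"""Controlled vocabulary: types, normalization, term matching, staging.

A vocabulary is two linked layers of ``canonical term -> synonyms``
dictionaries: the outer layer maps each canonical *feature* (a metadata
column concept such as ``ethnicity``) to its synonyms, and each feature
carries an inner map from every canonical *instance* (a value the feature
may take, such as ``Black``) to that instance's synonyms.  All resolution
happens in a normalized text space; canonical spellings are preserved for
display.

Terms are resolved in three tiers:

1. *exact*   -- the query string equals a canonical term or synonym verbatim;
2. *normalized* -- equality after :func:`normalize_term`;
3. *fuzzy*   -- token-set normalized-Levenshtein similarity above a
   threshold (default 0.85).  Fuzzy hits are only ever *proposed* to the
   user, never applied automatically, and ties at the top score are
   reported as ambiguous rather than guessed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Literal, Mapping

import edlib

from .exceptions import MetacurateError, ParseError, VocabularyValidationError

__all__ = [
    "DEFAULT_FUZZY_THRESHOLD",
    "FeatureEntry",
    "MatchResult",
    "TempEntry",
    "TempVocabulary",
    "Vocabulary",
    "levenshtein",
    "load_vocabulary",
    "lookup_feature",
    "lookup_instance",
    "merge_temp",
    "normalize_term",
    "save_vocabulary",
    "similarity",
    "stage_term",
    "validate_vocabulary",
]

DEFAULT_FUZZY_THRESHOLD = 0.85

_PUNCT_RE = re.compile(r"[_.,;:/()\-]")
_WS_RE = re.compile(r"\s+")


def normalize_term(raw: str) -> str:
    """Canonicalize a term for comparison.

    Lower-cases, strips, maps the punctuation set ``[_.,;:/()-]`` to
    spaces and collapses whitespace runs.  Pure and idempotent; an empty
    input yields an empty string.
    """
    s = _PUNCT_RE.sub(" ", raw.casefold())
    return _WS_RE.sub(" ", s).strip()


def _token_set(normalized: str) -> str:
    return " ".join(sorted(normalized.split()))


def levenshtein(a: str, b: str) -> int:
    """Edit distance between two strings (via edlib; empty-safe)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def similarity(query: str, term: str) -> float:
    """Token-set normalized-Levenshtein similarity in [0, 1].

    Both strings are normalized, their tokens sorted (so word order never
    penalizes a match), then 1 - distance/max-length.
    """
    a = _token_set(normalize_term(query))
    b = _token_set(normalize_term(term))
    if not a and not b:
        return 1.0
    denom = max(len(a), len(b))
    return 1.0 - levenshtein(a, b) / denom


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchResult:
    """Outcome of resolving one query term against a term map."""

    query: str
    canonical_key: str | None
    match_kind: Literal["exact", "normalized", "fuzzy", "none"]
    score: float
    ambiguous: bool = False
    candidates: tuple[tuple[str, float], ...] = ()

    def to_dict(self) -> dict:
        return {
            "query": self.query,
            "canonical_key": self.canonical_key,
            "match_kind": self.match_kind,
            "score": self.score,
            "ambiguous": self.ambiguous,
            "candidates": [list(c) for c in self.candidates],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MatchResult":
        return cls(
            query=d["query"],
            canonical_key=d["canonical_key"],
            match_kind=d["match_kind"],
            score=d["score"],
            ambiguous=d["ambiguous"],
            candidates=tuple((c[0], c[1]) for c in d["candidates"]),
        )


@dataclass(frozen=True)
class FeatureEntry:
    """One canonical feature: its synonyms and its instance->synonyms map."""

    canonical_name: str
    synonyms: frozenset[str] = frozenset()
    instances: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "synonyms", frozenset(self.synonyms))
        object.__setattr__(
            self, "instances", {k: frozenset(v) for k, v in dict(self.instances).items()}
        )


@dataclass(frozen=True)
class Vocabulary:
    """The reference vocabulary: canonical features with linked instances."""

    features: Mapping[str, FeatureEntry] = field(default_factory=dict)
    name: str = "vocabulary"
    version: str = "1"
    provenance_note: str = ""

    def __post_init__(self):
        object.__setattr__(self, "features", dict(self.features))

    # -- resolution helpers -------------------------------------------------

    def feature_terms(self) -> list[tuple[str, str]]:
        """All (term, canonical_feature) pairs: keys and synonyms."""
        out = []
        for key, entry in self.features.items():
            out.append((key, key))
            for syn in sorted(entry.synonyms):
                out.append((syn, key))
        return out

    def instance_terms(self, feature_key: str) -> list[tuple[str, str]]:
        entry = self.features[feature_key]
        out = []
        for inst, syns in entry.instances.items():
            out.append((inst, inst))
            for syn in sorted(syns):
                out.append((syn, inst))
        return out

    def resolves_feature(self, term: str) -> str | None:
        """Canonical feature for ``term`` by exact/normalized match, else None."""
        m = lookup_feature(self, term, fuzzy_threshold=None)
        return m.canonical_key

    def resolves_instance(self, feature_key: str, term: str) -> str | None:
        m = lookup_instance(self, feature_key, term, fuzzy_threshold=None)
        return m.canonical_key

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "version": self.version,
            "provenance_note": self.provenance_note,
            "features": {
                key: {
                    "synonyms": sorted(entry.synonyms),
                    "instances": {
                        inst: sorted(syns) for inst, syns in sorted(entry.instances.items())
                    },
                }
                for key, entry in sorted(self.features.items())
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping, *, source: str = "<dict>") -> "Vocabulary":
        if "features" not in d:
            raise ParseError(f"{source}: missing required key 'features'")
        feats = {}
        for key, body in d["features"].items():
            if not isinstance(body, Mapping):
                raise ParseError(f"{source}: feature {key!r}: body must be an object")
            insts = body.get("instances", {})
            if not isinstance(insts, Mapping):
                raise ParseError(f"{source}: feature {key!r}: 'instances' must be an object")
            feats[key] = FeatureEntry(
                canonical_name=key,
                synonyms=frozenset(body.get("synonyms", [])),
                instances={inst: frozenset(syns) for inst, syns in insts.items()},
            )
        return cls(
            features=feats,
            name=d.get("name", "vocabulary"),
            version=str(d.get("version", "1")),
            provenance_note=d.get("provenance_note", ""),
        )


@dataclass(frozen=True)
class TempEntry:
    """A term staged during curation, awaiting vocabulary promotion."""

    entry_id: str
    kind: Literal["feature", "instance"]
    feature_key: str  # for kind=feature this is the new feature name itself
    term: str
    status: Literal["pending", "approved", "rejected"] = "pending"
    origin_dataset: str = ""
    created_at: str = ""

    def to_dict(self) -> dict:
        return {
            "entry_id": self.entry_id,
            "kind": self.kind,
            "feature_key": self.feature_key,
            "term": self.term,
            "status": self.status,
            "origin_dataset": self.origin_dataset,
            "created_at": self.created_at,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TempEntry":
        return cls(**{k: d[k] for k in (
            "entry_id", "kind", "feature_key", "term", "status",
            "origin_dataset", "created_at")})


@dataclass(frozen=True)
class TempVocabulary:
    """Staging area for terms not present in the reference vocabulary.

    Statuses realize the same colour-coded evaluation used at integration
    time: pending=AMBER, approved=GREEN, rejected=RED.
    """

    entries: tuple[TempEntry, ...] = ()
    name: str = "temporary vocabulary"

    def pending(self) -> list[TempEntry]:
        return [e for e in self.entries if e.status == "pending"]

    def find(self, entry_id: str) -> TempEntry | None:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e
        return None

    def resolves_feature(self, term: str) -> str | None:
        n = normalize_term(term)
        for e in self.entries:
            if e.kind == "feature" and e.status != "rejected" and normalize_term(e.term) == n:
                return e.term
        return None

    def resolves_instance(self, feature_key: str, term: str) -> str | None:
        n = normalize_term(term)
        nf = normalize_term(feature_key)
        for e in self.entries:
            if (
                e.kind == "instance"
                and e.status != "rejected"
                and normalize_term(e.feature_key) == nf
                and normalize_term(e.term) == n
            ):
                return e.term
        return None

    def to_dict(self) -> dict:
        return {"name": self.name, "entries": [e.to_dict() for e in self.entries]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "TempVocabulary":
        return cls(
            entries=tuple(TempEntry.from_dict(e) for e in d.get("entries", [])),
            name=d.get("name", "temporary vocabulary"),
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_vocabulary(v: Vocabulary) -> list[str]:
    """Return every invariant violation (empty list means valid).

    Checks, all in normalized space:
    - feature keys unique;
    - no synonym (or key) resolves to two different features;
    - within a feature, no instance synonym (or instance) resolves to two
      different canonical instances.
    """
    violations: list[str] = []

    seen_keys: dict[str, str] = {}
    for key in v.features:
        n = normalize_term(key)
        if n in seen_keys and seen_keys[n] != key:
            violations.append(
                f"feature keys {seen_keys[n]!r} and {key!r} collide after normalization"
            )
        seen_keys.setdefault(n, key)

    # feature-level term map: normalized term -> canonical feature
    fmap: dict[str, str] = {}
    for term, key in sorted(Vocabulary.feature_terms(v)):
        n = normalize_term(term)
        if n in fmap and fmap[n] != key:
            violations.append(
                f"term {term!r} resolves to both features {fmap[n]!r} and {key!r}"
            )
        fmap.setdefault(n, key)

    for key, entry in v.features.items():
        imap: dict[str, str] = {}
        for term, inst in sorted(Vocabulary.instance_terms(v, key)):
            n = normalize_term(term)
            if n in imap and imap[n] != inst:
                violations.append(
                    f"feature {key!r}: instance term {term!r} resolves to both "
                    f"{imap[n]!r} and {inst!r}"
                )
            imap.setdefault(n, inst)

    return violations


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def load_vocabulary(path) -> Vocabulary:
    """Load and validate a vocabulary from its JSON file format.

    An empty ``features`` object yields a vocabulary with zero features.
    Malformed JSON raises :class:`ParseError`; invariant violations raise
    :class:`VocabularyValidationError` listing all of them.
    """
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from e
    if not isinstance(doc, Mapping):
        raise ParseError(f"{path}: top level must be a JSON object")
    v = Vocabulary.from_dict(doc, source=str(path))
    violations = validate_vocabulary(v)
    if violations:
        raise VocabularyValidationError(violations)
    return v


def save_vocabulary(v: Vocabulary, path) -> None:
    """Write ``v`` so that :func:`load_vocabulary` round-trips identically."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(v.to_dict(), fh, indent=2, ensure_ascii=False)
        fh.write("\n")


def load_temp_vocabulary(path) -> TempVocabulary:
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from e
    return TempVocabulary.from_dict(doc)


def save_temp_vocabulary(t: TempVocabulary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(t.to_dict(), fh, indent=2, ensure_ascii=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Lookup
# ---------------------------------------------------------------------------

def _match(term_pairs: list[tuple[str, str]], query: str,
           fuzzy_threshold: float | None) -> MatchResult:
    """Resolve ``query`` against (term, canonical) pairs with the 3-tier rule."""
    # tier 1: verbatim equality
    for term, key in term_pairs:
        if term == query:
            return MatchResult(query, key, "exact", 1.0)
    # tier 2: normalized equality
    nq = normalize_term(query)
    for term, key in term_pairs:
        if normalize_term(term) == nq:
            return MatchResult(query, key, "normalized", 1.0)
    # tier 3: fuzzy (optional)
    if fuzzy_threshold is None or not nq:
        return MatchResult(query, None, "none", 0.0)
    best: dict[str, float] = {}
    for term, key in term_pairs:
        s = similarity(query, term)
        if s >= fuzzy_threshold and s > best.get(key, -1.0):
            best[key] = s
    if not best:
        return MatchResult(query, None, "none", 0.0)
    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ranked[0][1]
    tied = [k for k, s in ranked if s == top]
    if len(tied) > 1:
        return MatchResult(query, None, "fuzzy", top, ambiguous=True,
                           candidates=tuple(ranked))
    return MatchResult(query, ranked[0][0], "fuzzy", top, candidates=tuple(ranked))


def lookup_feature(v: Vocabulary, term: str,
                   fuzzy_threshold: float | None = DEFAULT_FUZZY_THRESHOLD) -> MatchResult:
    """Resolve a term against canonical feature keys and their synonyms.

    ``fuzzy_threshold=None`` disables the fuzzy tier entirely.
    """
    return _match(v.feature_terms(), term, fuzzy_threshold)


def lookup_instance(v: Vocabulary, feature_key: str, term: str,
                    fuzzy_threshold: float | None = DEFAULT_FUZZY_THRESHOLD) -> MatchResult:
    """Resolve a value against one feature's instance map (key + synonyms)."""
    if feature_key not in v.features:
        raise MetacurateError(f"unknown feature key {feature_key!r}")
    return _match(v.instance_terms(feature_key), term, fuzzy_threshold)


# ---------------------------------------------------------------------------
# Staging and merging
# ---------------------------------------------------------------------------

def _now_iso() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def temp_entry_id(kind: str, feature_key: str, term: str) -> str:
    return f"{kind}:{normalize_term(feature_key)}:{normalize_term(term)}"


def stage_term(t: TempVocabulary, v: Vocabulary, feature_key: str, term: str,
               as_kind: Literal["feature", "instance"],
               origin_dataset: str = "", created_at: str | None = None) -> TempVocabulary:
    """Stage an unresolved term as a pending temp-vocabulary entry.

    A term that already resolves in the reference vocabulary cannot be
    staged; a duplicate pending entry errors.  Returns a new value; the
    input is unchanged.
    """
    if as_kind == "feature":
        if v.resolves_feature(term) is not None:
            raise MetacurateError(
                f"term {term!r} already in reference vocabulary "
                f"(feature {v.resolves_feature(term)!r})"
            )
        feature_key = term
    elif as_kind == "instance":
        if feature_key not in v.features:
            raise MetacurateError(f"unknown feature key {feature_key!r}")
        hit = v.resolves_instance(feature_key, term)
        if hit is not None:
            raise MetacurateError(
                f"term {term!r} already in reference vocabulary "
                f"(resolves to {hit!r} under {feature_key!r})"
            )
    else:
        raise MetacurateError(f"as_kind must be 'feature' or 'instance', got {as_kind!r}")

    eid = temp_entry_id(as_kind, feature_key, term)
    if t.find(eid) is not None:
        raise MetacurateError(f"term {term!r} already staged (entry {eid!r})")
    entry = TempEntry(
        entry_id=eid, kind=as_kind, feature_key=feature_key, term=term,
        status="pending", origin_dataset=origin_dataset,
        created_at=created_at if created_at is not None else _now_iso(),
    )
    return replace(t, entries=t.entries + (entry,))


def apply_temp_entry(v: Vocabulary, entry: TempEntry) -> Vocabulary:
    """Insert one approved temp entry into a new vocabulary value."""
    feats = dict(v.features)
    if entry.kind == "feature":
        feats[entry.term] = FeatureEntry(canonical_name=entry.term)
    else:
        if entry.feature_key not in feats:
            raise MetacurateError(
                f"cannot add instance {entry.term!r}: feature {entry.feature_key!r} absent"
            )
        old = feats[entry.feature_key]
        insts = dict(old.instances)
        insts[entry.term] = frozenset()
        feats[entry.feature_key] = replace(old, instances=insts)
    return replace(v, features=feats)


def merge_temp(v: Vocabulary, t: TempVocabulary,
               decisions: Mapping[str, str]) -> tuple[Vocabulary, TempVocabulary]:
    """Promote approved pending entries into the reference vocabulary.

    Every pending entry must carry a decision (``approve``/``reject``).
    The merge is atomic: if the merged vocabulary would not validate, an
    error names the collision and nothing is changed.  Rejected entries
    stay in the temp vocabulary with status ``rejected``.
    """
    pending = t.pending()
    missing = [e.entry_id for e in pending if e.entry_id not in decisions]
    if missing:
        raise MetacurateError("missing decision for entries: " + ", ".join(missing))
    bad = {eid: d for eid, d in decisions.items()
           if d not in ("approve", "reject")}
    if bad:
        raise MetacurateError(f"decisions must be 'approve' or 'reject', got {bad}")

    new_v = v
    for e in pending:
        if decisions[e.entry_id] == "approve":
            new_v = apply_temp_entry(new_v, e)
    violations = validate_vocabulary(new_v)
    if violations:
        raise VocabularyValidationError(violations)

    new_entries = []
    for e in t.entries:
        if e.status == "pending":
            new_status = "approved" if decisions[e.entry_id] == "approve" else "rejected"
            new_entries.append(replace(e, status=new_status))
        else:
            new_entries.append(e)
    # approved entries now live in the reference vocabulary; keep them for
    # provenance but they no longer resolve terms (reference wins).
    return new_v, replace(t, entries=tuple(new_entries))
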