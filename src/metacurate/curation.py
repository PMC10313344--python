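"""Single-dataset curation: the three-stage harmonization pipeline.

Curation proceeds through three stages on one metadata table:

(i)   *rename*  -- consistent renaming of table columns against the
      vocabulary's canonical features;
(ii)  *dedup*   -- deletion (or cell-wise coalescing) of duplicate columns,
      where duplicates are columns whose canonicalized headers are equal;
(iii) *values*  -- editing of remaining content, per unique instance value
      rather than per cell.

Every candidate modification is a :class:`Proposal`; nothing touches the
working table until a proposal is accepted (or edited) by a decision,
which also appends exactly one audit record.  The original table is never
modified.  Terms the vocabulary cannot resolve are collected for staging
into the temporary vocabulary.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

from .audit import AuditTrail
from .exceptions import DecisionError, MetacurateError, ParseError, StageError
from .vocabulary import (
    DEFAULT_FUZZY_THRESHOLD,
    MatchResult,
    TempVocabulary,
    Vocabulary,
    lookup_feature,
    lookup_instance,
    normalize_term,
    stage_term,
)

__all__ = [
    "CurationState",
    "DuplicateGroup",
    "MetadataTable",
    "Proposal",
    "advance_stage",
    "apply_decision",
    "curated_table",
    "detect_duplicate_columns",
    "is_missing",
    "load_table",
    "propose_column_renames",
    "propose_value_harmonization",
    "resolve_duplicates",
    "run_auto_curation",
    "unmatched_terms",
    "write_table",
]

#: cell contents treated as missing (compared after strip+casefold)
DEFAULT_MISSING_TOKENS = frozenset({"", "na", "n/a", "null", "-"})

STAGES = ("rename", "dedup", "values", "done")


def is_missing(cell: str, tokens: frozenset[str] = DEFAULT_MISSING_TOKENS) -> bool:
    return cell.strip().casefold() in tokens


# ---------------------------------------------------------------------------
# MetadataTable
# ---------------------------------------------------------------------------

@dataclass
class MetadataTable:
    """A samples x features table of verbatim free-text metadata."""

    dataset_id: str
    column_headers: list[str]
    rows: list[list[str]]
    source_path: str | None = None

    def __post_init__(self):
        if not self.dataset_id:
            raise ParseError("dataset_id must be non-empty")
        for i, row in enumerate(self.rows, start=1):
            if len(row) != len(self.column_headers):
                raise ParseError(
                    f"{self.dataset_id}: row {i} has {len(row)} cells, "
                    f"expected {len(self.column_headers)}")
        for j, h in enumerate(self.column_headers):
            if not h.strip():
                raise ParseError(f"{self.dataset_id}: blank header at column {j}")

    def copy(self) -> "MetadataTable":
        return MetadataTable(
            dataset_id=self.dataset_id,
            column_headers=list(self.column_headers),
            rows=[list(r) for r in self.rows],
            source_path=self.source_path,
        )

    def column(self, header: str) -> list[str]:
        idx = self.column_headers.index(header)
        return [row[idx] for row in self.rows]

    def content_equals(self, other: "MetadataTable") -> bool:
        """Structural equality ignoring provenance (source path)."""
        return (
            self.dataset_id == other.dataset_id
            and self.column_headers == other.column_headers
            and self.rows == other.rows
        )

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "column_headers": list(self.column_headers),
            "rows": [list(r) for r in self.rows],
            "source_path": self.source_path,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetadataTable":
        return cls(
            dataset_id=d["dataset_id"],
            column_headers=list(d["column_headers"]),
            rows=[list(r) for r in d["rows"]],
            source_path=d.get("source_path"),
        )


_DELIMS = {"comma": ",", "tab": "\t"}


def load_table(path, delimiter: Literal["comma", "tab"] = "comma",
               dataset_id: str | None = None) -> MetadataTable:
    """Load a UTF-8 CSV/TSV table; cells are kept verbatim (no trimming).

    The dataset identifier defaults to the file stem.  Ragged rows raise
    :class:`ParseError` naming the first offending row (1-based, counting
    data rows).  Duplicate identical header texts load fine — stage (ii)
    flags them as a duplicate group.
    """
    path = Path(path)
    sep = _DELIMS[delimiter]
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            headers = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (header row required)") from None
        rows = []
        for i, row in enumerate(reader, start=1):
            if len(row) != len(headers):
                raise ParseError(
                    f"{path}: row {i} has {len(row)} cells, expected {len(headers)}")
            rows.append(row)
    return MetadataTable(
        dataset_id=dataset_id or path.stem,
        column_headers=headers,
        rows=rows,
        source_path=str(path),
    )


def write_table(t: MetadataTable, path, delimiter: Literal["comma", "tab"] = "comma") -> None:
    """Write with minimal quoting; atomic (temp name + rename)."""
    path = str(path)
    tmp = path + ".tmp"
    with open(tmp, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=_DELIMS[delimiter], quoting=csv.QUOTE_MINIMAL)
        writer.writerow(t.column_headers)
        writer.writerows(t.rows)
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# Proposals and state
# ---------------------------------------------------------------------------

@dataclass
class Proposal:
    """One suggested modification awaiting a user decision."""

    proposal_id: str
    kind: Literal["rename_column", "delete_duplicate", "replace_value"]
    target: str  # column header (rename) or "<column>=<value>" (replace)
    current: str
    suggested: str | None
    match: MatchResult
    status: Literal["pending", "accepted", "rejected", "edited"] = "pending"
    edited_value: str | None = None
    column_index: int | None = None  # for rename proposals
    column: str | None = None        # for replace proposals

    @property
    def stage(self) -> str:
        return {"rename_column": "rename", "delete_duplicate": "dedup",
                "replace_value": "values"}[self.kind]

    def to_dict(self) -> dict:
        return {
            "proposal_id": self.proposal_id,
            "kind": self.kind,
            "target": self.target,
            "current": self.current,
            "suggested": self.suggested,
            "match": self.match.to_dict(),
            "status": self.status,
            "edited_value": self.edited_value,
            "column_index": self.column_index,
            "column": self.column,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Proposal":
        d = dict(d)
        d["match"] = MatchResult.from_dict(d["match"])
        return cls(**d)


@dataclass(frozen=True)
class DuplicateGroup:
    """Columns sharing a canonicalized header, with per-row agreement."""

    normalized_header: str
    column_indices: tuple[int, ...]
    headers: tuple[str, ...]
    row_agreement: tuple[bool, ...]  # per row: do non-missing cells agree?

    @property
    def conflict_rows(self) -> list[int]:
        return [i for i, ok in enumerate(self.row_agreement) if not ok]


@dataclass
class CurationState:
    """Mutable state machine for curating one dataset.

    ``original`` is never modified; ``working`` differs from it only by
    applied, audited proposals.  Stage transitions are monotone
    rename -> dedup -> values -> done.
    """

    original: MetadataTable
    working: MetadataTable
    trail: AuditTrail
    stage: str = "rename"
    proposals: list[Proposal] = field(default_factory=list)
    temp_vocab: TempVocabulary = field(default_factory=TempVocabulary)
    glp_mode: bool = False

    @property
    def dataset_id(self) -> str:
        return self.original.dataset_id

    def pending_proposals(self, stage: str | None = None) -> list[Proposal]:
        return [p for p in self.proposals
                if p.status == "pending" and (stage is None or p.stage == stage)]

    def find_proposal(self, proposal_id: str) -> Proposal:
        for p in self.proposals:
            if p.proposal_id == proposal_id:
                return p
        raise DecisionError(f"unknown proposal_id {proposal_id!r}")

    def to_dict(self) -> dict:
        return {
            "original": self.original.to_dict(),
            "working": self.working.to_dict(),
            "stage": self.stage,
            "proposals": [p.to_dict() for p in self.proposals],
            "temp_vocab": self.temp_vocab.to_dict(),
            "glp_mode": self.glp_mode,
        }

    @classmethod
    def from_dict(cls, d: Mapping, trail: AuditTrail) -> "CurationState":
        return cls(
            original=MetadataTable.from_dict(d["original"]),
            working=MetadataTable.from_dict(d["working"]),
            trail=trail,
            stage=d["stage"],
            proposals=[Proposal.from_dict(p) for p in d["proposals"]],
            temp_vocab=TempVocabulary.from_dict(d["temp_vocab"]),
            glp_mode=d["glp_mode"],
        )


def start_curation(table: MetadataTable, *, trail: AuditTrail | None = None,
                   glp_mode: bool = False) -> CurationState:
    """Open a curation state on a deep copy of ``table``."""
    if trail is None:
        trail = AuditTrail.new(session_id=table.dataset_id, glp_mode=glp_mode)
    return CurationState(
        original=table.copy(),
        working=table.copy(),
        trail=trail,
        glp_mode=glp_mode,
    )


def _require_stage(s: CurationState, stage: str, op: str) -> None:
    if s.stage != stage:
        raise StageError(
            f"{op} requires stage {stage!r}; state is in stage {s.stage!r}")


def advance_stage(s: CurationState) -> str:
    """Move to the next stage; pending proposals of the current stage block."""
    pend = s.pending_proposals(s.stage)
    if pend:
        raise StageError(
            f"cannot leave stage {s.stage!r}: pending proposals "
            + ", ".join(p.proposal_id for p in pend))
    i = STAGES.index(s.stage)
    if i == len(STAGES) - 1:
        raise StageError("already in final stage 'done'")
    s.stage = STAGES[i + 1]
    return s.stage


# -- stage (i): column renaming ---------------------------------------------

def propose_column_renames(s: CurationState, v: Vocabulary,
                           fuzzy_threshold: float | None = DEFAULT_FUZZY_THRESHOLD,
                           ) -> list[Proposal]:
    """One proposal per column header, in column order.

    Exact/normalized hits suggest the canonical feature; fuzzy hits
    suggest the top candidate (never auto-applied); headers the
    vocabulary cannot resolve get no suggestion and become staging
    candidates.
    """
    _require_stage(s, "rename", "propose_column_renames")
    proposals = []
    for idx, header in enumerate(s.working.column_headers):
        m = lookup_feature(v, header, fuzzy_threshold)
        suggested = m.canonical_key
        pid = f"rename:{idx:03d}:{normalize_term(header)}"
        proposals.append(Proposal(
            proposal_id=pid, kind="rename_column", target=header,
            current=header, suggested=suggested, match=m,
            column_index=idx,
        ))
    s.proposals = [p for p in s.proposals if p.stage != "rename"] + proposals
    return proposals


# -- stage (ii): duplicate columns ------------------------------------------

def detect_duplicate_columns(t: MetadataTable) -> list[DuplicateGroup]:
    """Group columns whose normalized headers are equal.

    For each group the per-row agreement summary says whether the
    non-missing cells of that row agree (zero or one distinct non-missing
    value).  Groups are ordered by first column occurrence.
    """
    by_norm: dict[str, list[int]] = {}
    for idx, header in enumerate(t.column_headers):
        by_norm.setdefault(normalize_term(header), []).append(idx)
    groups = []
    for norm, indices in by_norm.items():
        if len(indices) < 2:
            continue
        agreement = []
        for row in t.rows:
            values = {row[i] for i in indices if not is_missing(row[i])}
            agreement.append(len(values) <= 1)
        groups.append(DuplicateGroup(
            normalized_header=norm,
            column_indices=tuple(indices),
            headers=tuple(t.column_headers[i] for i in indices),
            row_agreement=tuple(agreement),
        ))
    groups.sort(key=lambda g: g.column_indices[0])
    return groups


def resolve_duplicates(s: CurationState, group: DuplicateGroup,
                       decision, justification: str | None = None) -> CurationState:
    """Apply a duplicate-group decision to the working table.

    ``decision`` is ``"keep_first_fill_missing"`` (cell-wise coalesce into
    the first column, first non-missing value wins), ``("keep_named_column",
    <header or index>)`` (drop the rest unmerged), or ``"keep_all"``.
    Conflicting non-missing cells block a coalesce with the offending row
    indices; each dropped column is audited individually.
    """
    _require_stage(s, "dedup", "resolve_duplicates")
    current = {g.normalized_header: g for g in detect_duplicate_columns(s.working)}
    live = current.get(group.normalized_header)
    if live is None or live.column_indices != group.column_indices:
        raise DecisionError(
            f"duplicate group {group.normalized_header!r} is stale; re-detect first")

    t = s.working
    if decision == "keep_all":
        s.trail.record(
            action_kind="reject", dataset_id=s.dataset_id,
            target=f"duplicates:{group.normalized_header}",
            before=",".join(group.headers), after=None,
            justification=justification)
        return s

    if decision == "keep_first_fill_missing":
        conflicts = group.conflict_rows
        if conflicts:
            raise DecisionError(
                f"cannot merge duplicate columns {group.headers}: conflicting "
                f"non-missing values in rows {conflicts}; edit those cells first")
        kept = group.column_indices[0]
        for di in sorted(group.column_indices[1:], reverse=True):
            s.trail.record(
                action_kind="merge", dataset_id=s.dataset_id,
                target=f"column:{di}<-column:{kept}",
                before=t.column_headers[di], after=t.column_headers[kept],
                justification=justification)
            for row in t.rows:
                if is_missing(row[kept]) and not is_missing(row[di]):
                    row[kept] = row[di]
                del row[di]
            del t.column_headers[di]
        return s

    if isinstance(decision, tuple) and decision[0] == "keep_named_column":
        which = decision[1]
        if isinstance(which, int):
            kept = which
        else:
            matches = [i for i in group.column_indices
                       if t.column_headers[i] == which]
            if not matches:
                raise DecisionError(f"no column named {which!r} in group")
            kept = matches[0]
        if kept not in group.column_indices:
            raise DecisionError(f"column {which!r} not part of the group")
        for di in sorted(group.column_indices, reverse=True):
            if di == kept:
                continue
            s.trail.record(
                action_kind="delete", dataset_id=s.dataset_id,
                target=f"column:{di}", before=t.column_headers[di], after=None,
                justification=justification)
            del t.column_headers[di]
            for row in t.rows:
                del row[di]
        return s

    raise DecisionError(f"unknown duplicate decision {decision!r}")


# -- stage (iii): value harmonization ---------------------------------------

def propose_value_harmonization(s: CurationState, column: str, v: Vocabulary,
                                fuzzy_threshold: float | None = DEFAULT_FUZZY_THRESHOLD,
                                ) -> list[Proposal]:
    """One proposal per unique non-missing value of ``column`` (not per cell).

    The column header must already be a canonical feature; otherwise
    return to stage (i) and rename it first.
    """
    _require_stage(s, "values", "propose_value_harmonization")
    if column not in s.working.column_headers:
        raise DecisionError(f"no column named {column!r}")
    if column not in v.features:
        raise StageError(
            f"column {column!r} is not a canonical vocabulary feature; "
            f"rename it in stage (i) before harmonizing values")
    seen: list[str] = []
    for cell in s.working.column(column):
        if not is_missing(cell) and cell not in seen:
            seen.append(cell)
    taken = {p.proposal_id for p in s.proposals}
    proposals = []
    for value in seen:
        m = lookup_instance(v, column, value, fuzzy_threshold)
        pid = base = f"value:{normalize_term(column)}:{normalize_term(value)}"
        k = 2
        while pid in taken:
            pid = f"{base}#{k}"
            k += 1
        taken.add(pid)
        proposals.append(Proposal(
            proposal_id=pid, kind="replace_value",
            target=f"{column}={value}", current=value,
            suggested=m.canonical_key, match=m, column=column,
        ))
    s.proposals.extend(proposals)
    return proposals


# -- decisions ---------------------------------------------------------------

def apply_decision(s: CurationState, proposal_id: str,
                   decision: Literal["accept", "reject", "edit"],
                   justification: str | None = None,
                   edited_value: str | None = None) -> CurationState:
    """Resolve one pending proposal; the audit record precedes the mutation.

    ``accept`` applies the suggestion; ``edit`` applies ``edited_value``;
    ``reject`` changes nothing but is still audited.  A replace decision
    rewrites every cell equal to the unique value in that column.  In GLP
    mode a blank justification aborts with no state change.
    """
    p = s.find_proposal(proposal_id)
    if p.status != "pending":
        raise DecisionError(f"proposal {proposal_id!r} already {p.status}")
    if p.stage != s.stage:
        raise StageError(
            f"proposal {proposal_id!r} belongs to stage {p.stage!r}; "
            f"state is in stage {s.stage!r}")

    if decision == "reject":
        s.trail.record(
            action_kind="reject", dataset_id=s.dataset_id,
            target=p.target, before=p.current, after=None,
            justification=justification)
        p.status = "rejected"
        return s

    if decision == "accept":
        if p.suggested is None:
            raise DecisionError(
                f"proposal {proposal_id!r} has no suggestion; use edit or reject")
        new_value = p.suggested
    elif decision == "edit":
        if edited_value is None:
            raise DecisionError("edit decision requires edited_value")
        new_value = edited_value
    else:
        raise DecisionError(f"unknown decision {decision!r}")

    if p.kind == "rename_column":
        idx = p.column_index
        if idx is None or idx >= len(s.working.column_headers) \
                or s.working.column_headers[idx] != p.current:
            raise DecisionError(
                f"proposal {proposal_id!r} no longer matches the working table")
        s.trail.record(
            action_kind="rename", dataset_id=s.dataset_id,
            target=f"column:{idx}", before=p.current, after=new_value,
            justification=justification)
        s.working.column_headers[idx] = new_value
    elif p.kind == "replace_value":
        if p.column not in s.working.column_headers:
            raise DecisionError(f"column {p.column!r} gone from working table")
        s.trail.record(
            action_kind="replace", dataset_id=s.dataset_id,
            target=f"column:{p.column}", before=p.current, after=new_value,
            justification=justification)
        col = s.working.column_headers.index(p.column)
        for row in s.working.rows:
            if row[col] == p.current:
                row[col] = new_value
    else:
        raise DecisionError(f"proposal kind {p.kind!r} not decidable here")

    p.status = "accepted" if decision == "accept" else "edited"
    if decision == "edit":
        p.edited_value = edited_value
    return s


def unmatched_terms(s: CurationState) -> list[tuple[str, str]]:
    """Terms the vocabulary could not resolve, ready for staging.

    Pending or edited proposals with no match: for renames the term is
    the header itself; for values it is the unique instance value.
    """
    out = []
    for p in s.proposals:
        if p.match.match_kind == "none" and p.status in ("pending", "edited"):
            if p.kind == "rename_column":
                out.append((p.current, p.current))
            else:
                out.append((p.column, p.current))
    return out


def curated_table(s: CurationState) -> MetadataTable:
    """The curated output; only available once every proposal is resolved."""
    if s.stage != "done":
        raise StageError(f"curation not finished (stage {s.stage!r})")
    pend = s.pending_proposals()
    if pend:
        raise StageError(
            "pending proposals remain: " + ", ".join(p.proposal_id for p in pend))
    return s.working


# ---------------------------------------------------------------------------
# Scripted pipeline
# ---------------------------------------------------------------------------

AUTO_JUSTIFICATION = "automatic policy: exact/normalized vocabulary match"
AUTO_REJECT_JUSTIFICATION = "automatic policy: no exact vocabulary match"


def run_auto_curation(table: MetadataTable, v: Vocabulary, *,
                      fuzzy_threshold: float | None = DEFAULT_FUZZY_THRESHOLD,
                      glp_mode: bool = False,
                      trail: AuditTrail | None = None,
                      temp_vocab: TempVocabulary | None = None,
                      decisions: Mapping[str, Mapping] | None = None,
                      ) -> CurationState:
    """Run the full three-stage pipeline under the accept-all-exact policy.

    Exact and normalized matches are accepted automatically; fuzzy and
    unresolved proposals take their decision from ``decisions`` (a map
    proposal_id -> {"decision", "edited_value"?, "justification"?}) and
    are rejected otherwise.  Duplicate groups are coalesced when safe
    (``keep_all`` when cells conflict).  Unresolved terms are staged into
    the temporary vocabulary.
    """
    decisions = dict(decisions or {})
    s = start_curation(table, trail=trail, glp_mode=glp_mode)
    if temp_vocab is not None:
        s.temp_vocab = temp_vocab

    to_stage: list[tuple[str, str]] = []

    def settle(proposals: Iterable[Proposal]) -> None:
        for p in proposals:
            if p.match.match_kind == "none":
                # remember unresolved terms before the auto-reject settles them
                if p.kind == "rename_column":
                    to_stage.append((p.current, p.current))
                else:
                    to_stage.append((p.column, p.current))
            if p.proposal_id in decisions:
                d = decisions[p.proposal_id]
                apply_decision(s, p.proposal_id, d["decision"],
                               justification=d.get("justification"),
                               edited_value=d.get("edited_value"))
            elif p.match.match_kind in ("exact", "normalized"):
                apply_decision(s, p.proposal_id, "accept",
                               justification=AUTO_JUSTIFICATION)
            else:
                apply_decision(s, p.proposal_id, "reject",
                               justification=AUTO_REJECT_JUSTIFICATION)

    settle(propose_column_renames(s, v, fuzzy_threshold))
    advance_stage(s)

    while True:
        groups = detect_duplicate_columns(s.working)
        actionable = [g for g in groups if not g.conflict_rows]
        if not actionable:
            for g in groups:  # conflicted groups: keep everything, audited
                resolve_duplicates(s, g, "keep_all",
                                   justification=AUTO_REJECT_JUSTIFICATION)
            break
        resolve_duplicates(s, actionable[0], "keep_first_fill_missing",
                           justification=AUTO_JUSTIFICATION)
    advance_stage(s)

    for header in list(s.working.column_headers):
        if header in v.features:
            settle(propose_value_harmonization(s, header, v, fuzzy_threshold))
    advance_stage(s)

    for feature_or_col, term in to_stage + unmatched_terms(s):
        as_kind = "feature" if feature_or_col == term else "instance"
        try:
            new_temp = stage_term(
                s.temp_vocab, v, feature_or_col, term, as_kind,
                origin_dataset=s.dataset_id)
        except MetacurateError:
            continue  # already staged (e.g. seen in an earlier dataset)
        entry = new_temp.entries[-1]
        s.trail.record(
            action_kind="stage_term", dataset_id=s.dataset_id,
            target=entry.entry_id, before=entry.feature_key, after=entry.term,
            justification="unresolved term stored in temporary vocabulary")
        s.temp_vocab = new_temp
    return s
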