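"""Audit trail, session persistence, deterministic replay, reporting.

Every applied (or rejected) curation action appends exactly one record to
an append-only log.  In GLP mode a record without a non-blank
justification is refused *before* any state changes, so the log can never
under-document a GLP session.  Replay re-executes a log against the
original inputs and must reproduce the curated outputs exactly; record
timestamps are recorded for the report but excluded from replay semantics
and structural equality, so reproducibility never depends on wall-clock.
"""

from __future__ import annotations

import getpass
import json
import os
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Literal, Mapping

from .exceptions import (
    GLPViolationError,
    MetacurateError,
    ParseError,
    ReplayError,
    SessionFormatError,
)
from .vocabulary import (
    TempVocabulary,
    Vocabulary,
    apply_temp_entry,
    stage_term,
)

SESSION_FORMAT_VERSION = "1"

ActionKind = Literal[
    "rename", "merge", "replace", "delete", "reject",
    "stage_term", "vocab_merge", "issue", "issue_resolve", "session",
]

#: record kinds that modify a metadata table during replay
TABLE_KINDS = ("rename", "merge", "replace", "delete")


def utc_now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def default_actor() -> str:
    try:
        return getpass.getuser()
    except Exception:  # pragma: no cover - environment-dependent
        return os.environ.get("USER", "unknown")


@dataclass(frozen=True)
class AuditRecord:
    seq: int
    timestamp: str
    actor: str
    action_kind: ActionKind
    target: str
    dataset_id: str | None = None
    before: str | None = None
    after: str | None = None
    justification: str | None = None
    glp_mode: bool = False

    def to_dict(self) -> dict:
        return {
            "seq": self.seq,
            "timestamp": self.timestamp,
            "actor": self.actor,
            "action_kind": self.action_kind,
            "target": self.target,
            "dataset_id": self.dataset_id,
            "before": self.before,
            "after": self.after,
            "justification": self.justification,
            "glp_mode": self.glp_mode,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AuditRecord":
        return cls(**{k: d[k] for k in (
            "seq", "timestamp", "actor", "action_kind", "target", "dataset_id",
            "before", "after", "justification", "glp_mode")})


@dataclass(frozen=True)
class AuditLog:
    session_id: str
    records: tuple[AuditRecord, ...] = ()
    created_at: str = field(default_factory=utc_now)

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "created_at": self.created_at,
            "records": [r.to_dict() for r in self.records],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AuditLog":
        return cls(
            session_id=d["session_id"],
            created_at=d.get("created_at", ""),
            records=tuple(AuditRecord.from_dict(r) for r in d.get("records", [])),
        )


def record(log: AuditLog, *, actor: str, action_kind: ActionKind, target: str,
           dataset_id: str | None = None, before: str | None = None,
           after: str | None = None, justification: str | None = None,
           glp_mode: bool = False, timestamp: str | None = None) -> AuditLog:
    """Append one record; in GLP mode the justification is mandatory.

    Callers record *before* mutating state, so a GLP violation here
    guarantees the action never happened.
    """
    if glp_mode and (justification is None or not justification.strip()):
        raise GLPViolationError(
            f"GLP mode requires a non-blank justification for action "
            f"{action_kind!r} on {target!r}"
        )
    seq = (log.records[-1].seq + 1) if log.records else 1
    rec = AuditRecord(
        seq=seq,
        timestamp=timestamp if timestamp is not None else utc_now(),
        actor=actor,
        action_kind=action_kind,
        target=target,
        dataset_id=dataset_id,
        before=before,
        after=after,
        justification=justification,
        glp_mode=glp_mode,
    )
    return replace(log, records=log.records + (rec,))


class AuditTrail:
    """Mutable holder around the append-only :class:`AuditLog`.

    One trail is shared by every curation state of a session, so all
    actions land in a single consecutive sequence.  GLP mode and the
    actor are fixed at creation: a report that is only partially GLP is
    not GLP.
    """

    def __init__(self, log: AuditLog, *, glp_mode: bool = False,
                 actor: str | None = None):
        self.log = log
        self.glp_mode = glp_mode
        self.actor = actor if actor is not None else default_actor()

    @classmethod
    def new(cls, session_id: str, *, glp_mode: bool = False,
            actor: str | None = None) -> "AuditTrail":
        return cls(AuditLog(session_id=session_id), glp_mode=glp_mode, actor=actor)

    def record(self, *, action_kind: ActionKind, target: str,
               dataset_id: str | None = None, before: str | None = None,
               after: str | None = None, justification: str | None = None,
               actor: str | None = None) -> AuditRecord:
        self.log = record(
            self.log, actor=actor if actor is not None else self.actor,
            action_kind=action_kind, target=target, dataset_id=dataset_id,
            before=before, after=after, justification=justification,
            glp_mode=self.glp_mode)
        return self.log.records[-1]

    @property
    def records(self) -> tuple[AuditRecord, ...]:
        return self.log.records


# ---------------------------------------------------------------------------
# Replay
# ---------------------------------------------------------------------------

def _is_missing(cell: str) -> bool:
    # local import avoids a cycle; curation owns the configurable list
    from .curation import is_missing
    return is_missing(cell)


def _parse_column_target(target: str, seq: int) -> int:
    if not target.startswith("column:"):
        raise ReplayError(seq, f"unexpected target format {target!r}")
    try:
        return int(target.split(":", 1)[1])
    except ValueError:
        raise ReplayError(seq, f"unexpected target format {target!r}") from None


def replay(originals: list, v: Vocabulary, log: AuditLog):
    """Re-execute an audit log against the original tables.

    Returns ``(tables_by_dataset_id, vocabulary, temp_vocabulary)`` with
    the same structure the live session produced.  A record that does not
    apply cleanly (column missing, header mismatch) raises
    :class:`ReplayError` naming the failing ``seq`` — the log does not
    belong to these inputs.
    """
    from .curation import MetadataTable  # cycle guard

    tables: dict[str, MetadataTable] = {}
    for t in originals:
        if t.dataset_id in tables:
            raise MetacurateError(f"duplicate dataset_id {t.dataset_id!r} in originals")
        tables[t.dataset_id] = t.copy()

    vocab = v
    temp = TempVocabulary()

    for rec in log.records:
        kind = rec.action_kind
        if kind in ("reject", "issue", "issue_resolve", "session"):
            continue
        if kind == "stage_term":
            # target encodes "<kind>:<feature>:<term>" via temp_entry_id,
            # but before/after carry the verbatim strings
            as_kind, feature_key = rec.target.split(":", 2)[0], rec.before or ""
            term = rec.after or ""
            try:
                temp = stage_term(temp, vocab, feature_key, term, as_kind,
                                  origin_dataset=rec.dataset_id or "",
                                  created_at=rec.timestamp)
            except MetacurateError as e:
                raise ReplayError(rec.seq, str(e)) from e
            continue
        if kind == "vocab_merge":
            entry = temp.find(rec.target)
            if entry is None:
                raise ReplayError(rec.seq, f"no staged entry {rec.target!r}")
            decision = rec.after or ""
            new_status = "approved" if decision == "approve" else "rejected"
            if decision == "approve":
                try:
                    vocab = apply_temp_entry(vocab, entry)
                except MetacurateError as e:
                    raise ReplayError(rec.seq, str(e)) from e
            temp = replace(temp, entries=tuple(
                replace(e, status=new_status) if e.entry_id == rec.target else e
                for e in temp.entries))
            continue

        # table-modifying kinds need a dataset
        if rec.dataset_id is None or rec.dataset_id not in tables:
            raise ReplayError(rec.seq, f"unknown dataset {rec.dataset_id!r}")
        table = tables[rec.dataset_id]

        if kind == "rename":
            idx = _parse_column_target(rec.target, rec.seq)
            if idx >= len(table.column_headers):
                raise ReplayError(rec.seq, f"no column at index {idx}")
            if table.column_headers[idx] != rec.before:
                raise ReplayError(
                    rec.seq,
                    f"column {idx} is {table.column_headers[idx]!r}, "
                    f"expected {rec.before!r}")
            table.column_headers[idx] = rec.after or ""
        elif kind == "merge":
            # target "column:<dropped><-column:<kept>"
            try:
                dropped_s, kept_s = rec.target.split("<-")
            except ValueError:
                raise ReplayError(rec.seq, f"unexpected target {rec.target!r}") from None
            di = _parse_column_target(dropped_s, rec.seq)
            ki = _parse_column_target(kept_s, rec.seq)
            if max(di, ki) >= len(table.column_headers):
                raise ReplayError(rec.seq, "merge column index out of range")
            if table.column_headers[di] != rec.before:
                raise ReplayError(rec.seq, f"dropped column header mismatch at {di}")
            for row in table.rows:
                if _is_missing(row[ki]) and not _is_missing(row[di]):
                    row[ki] = row[di]
                del row[di]
            del table.column_headers[di]
        elif kind == "delete":
            idx = _parse_column_target(rec.target, rec.seq)
            if idx >= len(table.column_headers):
                raise ReplayError(rec.seq, f"no column at index {idx}")
            if table.column_headers[idx] != rec.before:
                raise ReplayError(rec.seq, f"column header mismatch at {idx}")
            del table.column_headers[idx]
            for row in table.rows:
                del row[idx]
        elif kind == "replace":
            header = rec.target.removeprefix("column:")
            if header not in table.column_headers:
                raise ReplayError(rec.seq, f"no column named {header!r}")
            idx = table.column_headers.index(header)
            for row in table.rows:
                if row[idx] == rec.before:
                    row[idx] = rec.after if rec.after is not None else ""
        else:  # pragma: no cover - exhaustive over ActionKind
            raise ReplayError(rec.seq, f"unknown action kind {kind!r}")

    return tables, vocab, temp


# ---------------------------------------------------------------------------
# Session
# ---------------------------------------------------------------------------

@dataclass
class Session:
    """Everything needed to restore or replay a curation campaign."""

    session_id: str
    glp_mode: bool
    vocabulary: Vocabulary
    temp_vocab: TempVocabulary = field(default_factory=TempVocabulary)
    curation_states: dict = field(default_factory=dict)  # dataset_id -> CurationState
    integration_report: object | None = None
    trail: AuditTrail | None = None
    actor: str | None = None

    def __post_init__(self):
        if self.trail is None:
            self.trail = AuditTrail.new(
                session_id=self.session_id, glp_mode=self.glp_mode,
                actor=self.actor)

    @property
    def audit(self) -> AuditLog:
        return self.trail.log

    def to_dict(self) -> dict:
        from .integration import IntegrationReport  # noqa: F401  (type only)
        return {
            "format_version": SESSION_FORMAT_VERSION,
            "session_id": self.session_id,
            "glp_mode": self.glp_mode,
            "vocabulary": self.vocabulary.to_dict(),
            "temp_vocab": self.temp_vocab.to_dict(),
            "curation_states": {
                ds: st.to_dict() for ds, st in self.curation_states.items()
            },
            "integration_report": (
                self.integration_report.to_dict()
                if self.integration_report is not None else None
            ),
            "audit": self.audit.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Session":
        from .curation import CurationState
        from .integration import IntegrationReport
        got = str(d.get("format_version"))
        if got != SESSION_FORMAT_VERSION:
            raise SessionFormatError(
                f"session format version {got!r} unsupported "
                f"(this build reads {SESSION_FORMAT_VERSION!r})")
        s = cls(
            session_id=d["session_id"],
            glp_mode=d["glp_mode"],
            vocabulary=Vocabulary.from_dict(d["vocabulary"]),
            temp_vocab=TempVocabulary.from_dict(d["temp_vocab"]),
            trail=AuditTrail(AuditLog.from_dict(d["audit"]),
                             glp_mode=d["glp_mode"]),
        )
        s.curation_states = {
            ds: CurationState.from_dict(body, trail=s.trail)
            for ds, body in d.get("curation_states", {}).items()
        }
        rep = d.get("integration_report")
        s.integration_report = IntegrationReport.from_dict(rep) if rep else None
        return s


def save_session(s: Session, path) -> None:
    tmp = f"{path}.tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(s.to_dict(), fh, indent=1, ensure_ascii=False)
        fh.write("\n")
    os.replace(tmp, path)


def load_session(path) -> Session:
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from e
    return Session.from_dict(doc)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def generate_report(s: Session, format: Literal["machine", "human"] = "human"):
    """Render the full session audit report.

    ``machine`` returns a JSON-serializable dict that round-trips; ``human``
    returns Markdown with a session header, one line per action (seq,
    timestamp, actor, action, before -> after, justification) and the
    integration summary when present.
    """
    if format == "machine":
        return s.to_dict()

    lines = [
        f"# Curation report — session {s.session_id}",
        "",
        f"- vocabulary: {s.vocabulary.name} (version {s.vocabulary.version})",
        f"- datasets: {', '.join(sorted(s.curation_states)) or '(none)'}",
        f"- GLP mode: {'yes' if s.glp_mode else 'no'}",
        f"- actions recorded: {len(s.audit.records)}",
        "",
        "## Actions",
        "",
    ]
    for r in s.audit.records:
        arrow = ""
        if r.before is not None or r.after is not None:
            arrow = f" {r.before!r} -> {r.after!r}"
        just = f" — justification: {r.justification}" if r.justification else ""
        ds = f" [{r.dataset_id}]" if r.dataset_id else ""
        lines.append(
            f"{r.seq}. {r.timestamp} {r.actor}: {r.action_kind}{ds} "
            f"{r.target}{arrow}{just}")
    if not s.audit.records:
        lines.append("(no actions)")
    if s.integration_report is not None:
        from .integration import render_report_markdown
        lines += ["", "## Integration summary", "",
                  render_report_markdown(s.integration_report)]
    return "\n".join(lines) + "\n"
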