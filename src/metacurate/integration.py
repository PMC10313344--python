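"""Multi-dataset integration with traffic-light consistency reporting.

After each dataset has been curated on its own, integration stacks the
tables into one, aligns columns on canonical features, and classifies
every feature with a conservative traffic light:

* **GREEN** — the feature is a reference-vocabulary canonical, present in
  every dataset, and every observed instance resolves in the reference
  vocabulary;
* **AMBER** — the only defects are terms resolvable solely through the
  temporary (not yet promoted) vocabulary, or absence of the feature from
  one or more datasets;
* **RED**   — the feature or an observed instance resolves in neither
  vocabulary, or two datasets map the same normalized header to different
  canonical features.

A feature's overall status is the minimum over all its checks
(RED < AMBER < GREEN).  Discrepancies can be marked as *Issues*, which
feed the task list for the next curation round.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

from .audit import AuditTrail, utc_now
from .curation import MetadataTable, is_missing
from .exceptions import IntegrationError, MetacurateError
from .vocabulary import TempVocabulary, Vocabulary, normalize_term

__all__ = [
    "IntegratedTable",
    "IntegrationReport",
    "IssueFlag",
    "export_report",
    "integrate",
    "issues_for_next_round",
    "load_report",
    "mark_issue",
    "render_report_markdown",
    "status_of_feature",
]

STATUS_ORDER = {"RED": 0, "AMBER": 1, "GREEN": 2}
Status = Literal["GREEN", "AMBER", "RED"]


def min_status(statuses: Sequence[str]) -> str:
    """Conservative aggregation: the worst status wins."""
    if not statuses:
        return "GREEN"
    return min(statuses, key=STATUS_ORDER.__getitem__)


@dataclass(frozen=True)
class IssueFlag:
    """A user-flagged discrepancy deferred to the next curation round."""

    target: str  # "feature" or "feature=instance"
    note: str
    raised_by: str
    raised_at: str
    resolved: bool = False

    def to_dict(self) -> dict:
        return {"target": self.target, "note": self.note,
                "raised_by": self.raised_by, "raised_at": self.raised_at,
                "resolved": self.resolved}

    @classmethod
    def from_dict(cls, d: Mapping) -> "IssueFlag":
        return cls(**{k: d[k] for k in
                      ("target", "note", "raised_by", "raised_at", "resolved")})


@dataclass(frozen=True)
class FeatureRow:
    """Per-feature consistency summary across all integrated datasets."""

    feature: str
    presence: Mapping[str, bool]            # dataset_id -> present?
    instance_statuses: Mapping[str, str]    # observed instance -> status
    overall: str
    reasons: tuple[str, ...]
    issues: tuple[IssueFlag, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "presence", dict(self.presence))
        object.__setattr__(self, "instance_statuses", dict(self.instance_statuses))

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "presence": dict(self.presence),
            "instance_statuses": dict(self.instance_statuses),
            "overall": self.overall,
            "reasons": list(self.reasons),
            "issues": [i.to_dict() for i in self.issues],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureRow":
        return cls(
            feature=d["feature"], presence=d["presence"],
            instance_statuses=d["instance_statuses"], overall=d["overall"],
            reasons=tuple(d["reasons"]),
            issues=tuple(IssueFlag.from_dict(i) for i in d["issues"]),
        )


@dataclass(frozen=True)
class IntegrationReport:
    datasets: tuple[str, ...]
    feature_rows: tuple[FeatureRow, ...]
    generated_at: str = field(default_factory=utc_now)

    def row(self, feature: str) -> FeatureRow:
        for r in self.feature_rows:
            if r.feature == feature:
                return r
        raise MetacurateError(f"no feature {feature!r} in report")

    def to_dict(self) -> dict:
        return {
            "datasets": list(self.datasets),
            "generated_at": self.generated_at,
            "feature_rows": [r.to_dict() for r in self.feature_rows],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "IntegrationReport":
        return cls(
            datasets=tuple(d["datasets"]),
            generated_at=d["generated_at"],
            feature_rows=tuple(FeatureRow.from_dict(r) for r in d["feature_rows"]),
        )


@dataclass
class IntegratedTable:
    """All samples of all datasets, columns aligned on canonical features."""

    column_headers: list[str]  # dataset_id, sample_id, then features
    rows: list[list[str]]

    def to_table(self, dataset_id: str = "integrated") -> MetadataTable:
        return MetadataTable(dataset_id=dataset_id,
                             column_headers=list(self.column_headers),
                             rows=[list(r) for r in self.rows])


# ---------------------------------------------------------------------------
# Feature resolution across vocabularies
# ---------------------------------------------------------------------------

def _resolve_header(header: str, v: Vocabulary, t: TempVocabulary):
    """(canonical-or-header, tier) with tier in {reference, temp, unresolved}."""
    hit = v.resolves_feature(header)
    if hit is not None:
        return hit, "reference"
    hit = t.resolves_feature(header)
    if hit is not None:
        return hit, "temp"
    return header, "unresolved"


def _observed_instances(feature: str, tables: Sequence[MetadataTable],
                        v: Vocabulary, t: TempVocabulary) -> dict[str, list[str]]:
    """Unique non-missing values observed under ``feature``, per dataset."""
    out: dict[str, list[str]] = {}
    for table in tables:
        for idx, header in enumerate(table.column_headers):
            canon, _ = _resolve_header(header, v, t)
            if canon != feature:
                continue
            vals = out.setdefault(table.dataset_id, [])
            for row in table.rows:
                cell = row[idx]
                if not is_missing(cell) and cell not in vals:
                    vals.append(cell)
    return out


def status_of_feature(feature: str, tables: Sequence[MetadataTable],
                      v: Vocabulary, t: TempVocabulary,
                      ) -> tuple[str, list[str]]:
    """Classify one feature across curated tables; returns (status, reasons).

    ``reasons`` enumerates every triggering check, not just the decisive
    one, so the user sees the full picture before marking Issues.
    """
    checks: list[str] = ["GREEN"]
    reasons: list[str] = []

    feature_tier = (
        "reference" if v.resolves_feature(feature) is not None
        else "temp" if t.resolves_feature(feature) is not None
        else "unresolved")
    if feature_tier == "temp":
        checks.append("AMBER")
        reasons.append(f"feature {feature!r} only in temporary vocabulary")
    elif feature_tier == "unresolved":
        checks.append("RED")
        reasons.append(f"feature {feature!r} resolves in no vocabulary")

    # header-mapping conflicts: same normalized header, different canonical
    norm_to_canon: dict[str, set[str]] = {}
    for table in tables:
        for header in table.column_headers:
            canon, _ = _resolve_header(header, v, t)
            norm_to_canon.setdefault(normalize_term(header), set()).add(canon)
    for norm, canons in sorted(norm_to_canon.items()):
        if feature in canons and len(canons) > 1:
            checks.append("RED")
            reasons.append(
                f"header {norm!r} maps to multiple canonical features: "
                + ", ".join(sorted(canons)))

    # presence per dataset
    present_in = set(_observed_instances(feature, tables, v, t))
    for table in tables:
        canons = {_resolve_header(h, v, t)[0] for h in table.column_headers}
        if feature in canons:
            present_in.add(table.dataset_id)
    for table in tables:
        if table.dataset_id not in present_in:
            checks.append("AMBER")
            reasons.append(f"absent from dataset {table.dataset_id!r}")

    # instance-level checks
    feature_in_ref = v.resolves_feature(feature) is not None
    per_ds = _observed_instances(feature, tables, v, t)
    for ds in sorted(per_ds):
        for value in per_ds[ds]:
            if feature_in_ref and v.resolves_instance(
                    v.resolves_feature(feature), value) is not None:
                continue
            if t.resolves_instance(feature, value) is not None:
                checks.append("AMBER")
                reasons.append(
                    f"instance {value!r} ({ds}) only in temporary vocabulary")
            else:
                checks.append("RED")
                reasons.append(
                    f"instance {value!r} ({ds}) resolves in no vocabulary")

    return min_status(checks), reasons


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

_SAMPLE_ID_NORMS = {"sample id", "id"}


def _sample_ids(table: MetadataTable) -> list[str]:
    for idx, header in enumerate(table.column_headers):
        if normalize_term(header) in _SAMPLE_ID_NORMS:
            return [row[idx] for row in table.rows]
    # no identifier column: synthesize dataset_id + row ordinal
    return [f"{table.dataset_id}-{i}" for i in range(1, len(table.rows) + 1)]


def integrate(tables: Sequence[MetadataTable], v: Vocabulary,
              t: TempVocabulary | None = None,
              ) -> tuple[IntegratedTable, IntegrationReport]:
    """Stack curated tables and classify every feature.

    Deterministic given the inputs: features are sorted by canonical
    name, rows grouped by dataset in input order.  Requires at least two
    tables with distinct dataset ids.
    """
    if t is None:
        t = TempVocabulary()
    if len(tables) < 2:
        raise IntegrationError(
            "integration requires at least two curated tables; "
            "use single-dataset mode for one table")
    ids = [x.dataset_id for x in tables]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise IntegrationError(f"duplicate dataset_ids: {', '.join(dupes)}")

    # union of canonical features over all tables
    features: set[str] = set()
    for table in tables:
        for header in table.column_headers:
            canon, _ = _resolve_header(header, v, t)
            features.add(canon)
    ordered = sorted(features, key=lambda f: (normalize_term(f), f))

    headers = ["dataset_id", "sample_id"] + ordered
    rows: list[list[str]] = []
    for table in tables:
        col_of: dict[str, int] = {}
        for idx, header in enumerate(table.column_headers):
            canon, _ = _resolve_header(header, v, t)
            col_of.setdefault(canon, idx)  # first occurrence wins
        sids = _sample_ids(table)
        for r, row in enumerate(table.rows):
            out = [table.dataset_id, sids[r]]
            for f in ordered:
                out.append(row[col_of[f]] if f in col_of else "")
            rows.append(out)

    feature_rows = []
    for f in ordered:
        status, reasons = status_of_feature(f, tables, v, t)
        presence = {}
        for table in tables:
            canons = {_resolve_header(h, v, t)[0] for h in table.column_headers}
            presence[table.dataset_id] = f in canons
        per_ds = _observed_instances(f, tables, v, t)
        inst_status: dict[str, str] = {}
        ref_key = v.resolves_feature(f)
        for ds in sorted(per_ds):
            for value in per_ds[ds]:
                if ref_key is not None and v.resolves_instance(ref_key, value) is not None:
                    st = "GREEN"
                elif t.resolves_instance(f, value) is not None:
                    st = "AMBER"
                else:
                    st = "RED"
                prev = inst_status.get(value)
                inst_status[value] = st if prev is None else min_status([prev, st])
        feature_rows.append(FeatureRow(
            feature=f, presence=presence, instance_statuses=inst_status,
            overall=status, reasons=tuple(reasons)))

    report = IntegrationReport(datasets=tuple(ids), feature_rows=tuple(feature_rows))
    return IntegratedTable(column_headers=headers, rows=rows), report


# ---------------------------------------------------------------------------
# Issues
# ---------------------------------------------------------------------------

def mark_issue(r: IntegrationReport, target: str, note: str, actor: str,
               trail: AuditTrail | None = None,
               justification: str | None = None) -> IntegrationReport:
    """Flag a discrepancy (``"feature"`` or ``"feature=instance"``).

    History is preserved: marking the same target twice keeps two flags.
    Returns a new report; the action is audited when a trail is given.
    """
    if not note.strip():
        raise MetacurateError("issue note must be non-empty")
    feature = target.split("=", 1)[0]
    row = r.row(feature)  # raises on unknown target
    if "=" in target:
        instance = target.split("=", 1)[1]
        if instance not in row.instance_statuses:
            raise MetacurateError(
                f"instance {instance!r} not observed under feature {feature!r}")
    if trail is not None:
        trail.record(action_kind="issue", target=target, after=note,
                     justification=justification or note, actor=actor)
    flag = IssueFlag(target=target, note=note, raised_by=actor,
                     raised_at=utc_now())
    new_rows = tuple(
        replace(fr, issues=fr.issues + (flag,)) if fr.feature == feature else fr
        for fr in r.feature_rows)
    return replace(r, feature_rows=new_rows)


def issues_for_next_round(r: IntegrationReport) -> list[tuple[str, str]]:
    """Unresolved Issues translated into per-dataset curation tasks.

    Returns (dataset_id, target) pairs for every dataset in which the
    flagged feature is present.
    """
    tasks = []
    for row in r.feature_rows:
        for flag in row.issues:
            if flag.resolved:
                continue
            for ds, present in row.presence.items():
                if present:
                    tasks.append((ds, flag.target))
    return tasks


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

def render_report_markdown(r: IntegrationReport) -> str:
    """Human-readable report: one table row per feature, literal colour words."""
    lines = [
        f"Datasets: {', '.join(r.datasets)}",
        "",
        "| feature | status | present in | reasons | issues |",
        "|---|---|---|---|---|",
    ]
    for row in r.feature_rows:
        present = ", ".join(ds for ds, p in row.presence.items() if p) or "—"
        reasons = "; ".join(row.reasons) or "all checks pass"
        issues = "; ".join(f.target + ": " + f.note for f in row.issues) or "—"
        lines.append(
            f"| {row.feature} | {row.overall} | {present} | {reasons} | {issues} |")
    return "\n".join(lines) + "\n"


def export_report(r: IntegrationReport, path,
                  format: Literal["machine", "human"] = "machine") -> None:
    """machine = lossless JSON round-trip; human = Markdown table."""
    payload = (json.dumps(r.to_dict(), indent=2, ensure_ascii=False) + "\n"
               if format == "machine" else render_report_markdown(r))
    tmp = str(path) + ".tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write(payload)
    os.replace(tmp, str(path))


def load_report(path) -> IntegrationReport:
    with open(path, encoding="utf-8") as fh:
        return IntegrationReport.from_dict(json.load(fh))
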