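"""Three-stage curation: proposals, decisions, dedup, audit coupling."""

import random

import pytest

from metacurate import (
    DecisionError,
    GLPViolationError,
    MetadataTable,
    ParseError,
    StageError,
    advance_stage,
    apply_decision,
    curated_table,
    detect_duplicate_columns,
    load_table,
    propose_column_renames,
    propose_value_harmonization,
    resolve_duplicates,
    run_auto_curation,
    start_curation,
    unmatched_terms,
    write_table,
)
from metacurate.curation import is_missing

from conftest import oracle_coalesce, oracle_duplicate_groups


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def test_load_table_basic(tmp_path):
    p = tmp_path / "toy.csv"
    p.write_text("a,b\n1,2\n3,4\n5,6\n")
    t = load_table(p)
    assert t.dataset_id == "toy"
    assert t.column_headers == ["a", "b"] and len(t.rows) == 3


def test_load_table_keeps_cells_verbatim(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text('a,b\n"  x ",Y Z\n')
    t = load_table(p)
    assert t.rows[0] == ["  x ", "Y Z"]


def test_ragged_row_errors_with_row_number(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("a,b\n1,2\n3\n")
    with pytest.raises(ParseError, match="row 2"):
        load_table(p)


def test_blank_header_is_a_load_error(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("a,\n1,2\n")
    with pytest.raises(ParseError, match="blank header"):
        load_table(p)


@pytest.mark.parametrize("seed", range(0, 100, 5))
def test_write_load_round_trip(tmp_path, seed):
    rng = random.Random(seed)
    headers = [f"h{i}" for i in range(rng.randint(1, 5))]
    rows = [[rng.choice(["x", "a,b", 'q"t', " s ", ""]) for _ in headers]
            for _ in range(rng.randint(1, 8))]
    t = MetadataTable("ds", headers, rows)
    p = tmp_path / "ds.csv"
    write_table(t, p)
    assert load_table(p).content_equals(t)


# ---------------------------------------------------------------------------
# stage (i): renames
# ---------------------------------------------------------------------------

def test_rename_proposals_one_per_header(messy_ethnicity_table, ethnicity_vocab):
    s = start_curation(messy_ethnicity_table)
    props = propose_column_renames(s, ethnicity_vocab)
    assert [p.current for p in props] == ["race", "dose"]
    assert props[0].suggested == "ethnicity" and props[0].match.score == 1.0
    assert props[1].suggested is None  # 'dose' not in the example vocabulary


def test_already_canonical_header_is_a_noop_proposal(ethnicity_vocab):
    t = MetadataTable("d", ["ethnicity"], [["Black"]])
    s = start_curation(t)
    (p,) = propose_column_renames(s, ethnicity_vocab)
    assert p.suggested == "ethnicity" and p.match.match_kind == "exact"
    apply_decision(s, p.proposal_id, "accept")
    assert s.working.column_headers == ["ethnicity"]


def test_fuzzy_header_is_proposed_not_applied(ethnicity_vocab):
    t = MetadataTable("d", ["Ethncity"], [["Black"]])
    s = start_curation(t)
    (p,) = propose_column_renames(s, ethnicity_vocab, fuzzy_threshold=0.8)
    assert p.match.match_kind == "fuzzy" and p.suggested == "ethnicity"
    assert s.working.column_headers == ["Ethncity"]  # nothing auto-applied


def test_accepting_rename_updates_header_and_audits(
        messy_ethnicity_table, ethnicity_vocab):
    s = start_curation(messy_ethnicity_table)
    props = propose_column_renames(s, ethnicity_vocab)
    apply_decision(s, props[0].proposal_id, "accept")
    assert s.working.column_headers[0] == "ethnicity"
    assert s.original.column_headers[0] == "race"  # original untouched
    assert len(s.trail.records) == 1
    assert s.trail.records[0].action_kind == "rename"


def test_reject_leaves_table_but_is_audited(messy_ethnicity_table, ethnicity_vocab):
    s = start_curation(messy_ethnicity_table)
    props = propose_column_renames(s, ethnicity_vocab)
    apply_decision(s, props[0].proposal_id, "reject")
    assert s.working.column_headers == ["race", "dose"]
    assert s.trail.records[0].action_kind == "reject"


def test_glp_blank_justification_blocks_with_no_state_change(
        messy_ethnicity_table, ethnicity_vocab):
    s = start_curation(messy_ethnicity_table, glp_mode=True)
    s.trail.glp_mode = True
    props = propose_column_renames(s, ethnicity_vocab)
    for bad in (None, "", "   "):
        with pytest.raises(GLPViolationError):
            apply_decision(s, props[0].proposal_id, "accept", justification=bad)
    assert s.working.column_headers == ["race", "dose"]
    assert len(s.trail.records) == 0
    assert props[0].status == "pending"


def test_decisions_on_unknown_or_settled_proposals_error(
        messy_ethnicity_table, ethnicity_vocab):
    s = start_curation(messy_ethnicity_table)
    props = propose_column_renames(s, ethnicity_vocab)
    with pytest.raises(DecisionError, match="unknown proposal_id"):
        apply_decision(s, "nope", "accept")
    apply_decision(s, props[0].proposal_id, "accept")
    with pytest.raises(DecisionError, match="already accepted"):
        apply_decision(s, props[0].proposal_id, "reject")


# ---------------------------------------------------------------------------
# stage (ii): duplicates
# ---------------------------------------------------------------------------

def test_identical_duplicate_columns_form_one_full_agreement_group():
    t = MetadataTable("d", ["ethnicity", "ethnicity"],
                      [["Black", "Black"], ["White", "White"]])
    (g,) = detect_duplicate_columns(t)
    assert g.column_indices == (0, 1)
    assert all(g.row_agreement)


def test_distinct_headers_give_no_groups():
    t = MetadataTable("d", ["a", "b"], [["1", "2"]])
    assert detect_duplicate_columns(t) == []


@pytest.mark.parametrize("seed", range(0, 200, 3))
def test_duplicate_groups_match_all_pairs_oracle(seed):
    rng = random.Random(seed)
    n_cols = rng.randint(2, 10)
    headers = [rng.choice(["dose", "Dose", "time", "tissue", f"h{i}"])
               for i in range(n_cols)]
    rows = [[rng.choice(["x", "y", "NA", ""]) for _ in range(n_cols)]
            for _ in range(rng.randint(1, 50))]
    t = MetadataTable("d", headers, rows)
    got = {g.normalized_header: list(g.column_indices)
           for g in detect_duplicate_columns(t)}
    assert got == oracle_duplicate_groups(t)
    # agreement summary vs direct scan
    for g in detect_duplicate_columns(t):
        for r, ok in enumerate(g.row_agreement):
            vals = {t.rows[r][i] for i in g.column_indices
                    if not is_missing(t.rows[r][i])}
            assert ok == (len(vals) <= 1)


def _dedup_state(headers, rows):
    s = start_curation(MetadataTable("d", headers, rows))
    propose_column_renames(s, __import__("metacurate").Vocabulary())
    for p in list(s.pending_proposals()):
        apply_decision(s, p.proposal_id, "reject")
    advance_stage(s)
    return s


def test_coalesce_with_all_missing_duplicate_equals_other_column():
    s = _dedup_state(["a", "a"], [["x", ""], ["y", "NA"]])
    (g,) = detect_duplicate_columns(s.working)
    resolve_duplicates(s, g, "keep_first_fill_missing")
    assert s.working.column_headers == ["a"]
    assert [r[0] for r in s.working.rows] == ["x", "y"]


def test_conflicting_cells_block_merge_listing_rows():
    s = _dedup_state(["a", "a"], [["x", "y"], ["z", "z"]])
    (g,) = detect_duplicate_columns(s.working)
    with pytest.raises(DecisionError, match=r"rows \[0\]"):
        resolve_duplicates(s, g, "keep_first_fill_missing")
    assert s.working.column_headers == ["a", "a"]  # unchanged


def test_keep_all_changes_nothing_but_audits():
    s = _dedup_state(["a", "a"], [["x", "x"]])
    (g,) = detect_duplicate_columns(s.working)
    n_before = len(s.trail.records)
    resolve_duplicates(s, g, "keep_all")
    assert s.working.column_headers == ["a", "a"]
    assert len(s.trail.records) == n_before + 1


def test_keep_named_column_drops_the_rest():
    s = _dedup_state(["a", "a"], [["x", "y"]])
    (g,) = detect_duplicate_columns(s.working)
    resolve_duplicates(s, g, ("keep_named_column", 1))
    assert s.working.column_headers == ["a"]
    assert s.working.rows == [["y"]]


@pytest.mark.parametrize("seed", range(0, 100, 2))
def test_coalesce_equals_brute_force_cell_wise_oracle(seed):
    rng = random.Random(seed)
    n = rng.randint(2, 4)
    rows_n = rng.randint(1, 20)
    # conflict-free by construction: per row one value, others missing/equal
    rows = []
    for _ in range(rows_n):
        value = rng.choice(["x", "y", "z"])
        row = [value if rng.random() < 0.5 else rng.choice(["", "NA", "-"])
               for _ in range(n)]
        rows.append(row)
    s = _dedup_state(["c"] * n, [list(r) for r in rows])
    (g,) = detect_duplicate_columns(s.working)
    resolve_duplicates(s, g, "keep_first_fill_missing")
    expected = oracle_coalesce([[r[i] for r in rows] for i in range(n)], is_missing)
    assert [r[0] for r in s.working.rows] == expected


# ---------------------------------------------------------------------------
# stage (iii): values
# ---------------------------------------------------------------------------

def _values_state(table, vocab, threshold=0.85):
    s = start_curation(table)
    for p in propose_column_renames(s, vocab, threshold):
        if p.match.match_kind in ("exact", "normalized"):
            apply_decision(s, p.proposal_id, "accept")
        else:
            apply_decision(s, p.proposal_id, "reject")
    advance_stage(s)
    advance_stage(s)
    return s


def test_value_proposals_per_unique_value_not_per_cell(ethnicity_vocab):
    rows = [["Caucasian"], ["Caucasian"], ["B"], ["NA"]] * 50
    t = MetadataTable("d", ["race"], rows)
    s = _values_state(t, ethnicity_vocab)
    props = propose_value_harmonization(s, "ethnicity", ethnicity_vocab)
    assert len(props) == 2  # Caucasian, B; NA is missing
    by = {p.current: p.suggested for p in props}
    assert by == {"Caucasian": "White", "B": "Black"}


def test_accepting_replacement_rewrites_all_matching_cells(ethnicity_vocab):
    t = MetadataTable("d", ["race"], [["Caucasian"], ["Caucasian"], ["B"]])
    s = _values_state(t, ethnicity_vocab)
    props = propose_value_harmonization(s, "ethnicity", ethnicity_vocab)
    pid = next(p.proposal_id for p in props if p.current == "Caucasian")
    apply_decision(s, pid, "accept")
    assert [r[0] for r in s.working.rows] == ["White", "White", "B"]


def test_non_canonical_column_errors_back_to_stage_one(ethnicity_vocab):
    t = MetadataTable("d", ["race", "dose"], [["B", "10"]])
    s = _values_state(t, ethnicity_vocab)
    with pytest.raises(StageError, match="stage"):
        propose_value_harmonization(s, "dose", ethnicity_vocab)


def test_stage_monotonicity_later_ops_error_early():
    t = MetadataTable("d", ["a"], [["x"]])
    s = start_curation(t)
    with pytest.raises(StageError):
        resolve_duplicates(s, None, "keep_all")
    with pytest.raises(StageError):
        propose_value_harmonization(s, "a", __import__("metacurate").Vocabulary())


def test_cannot_advance_with_pending_proposals(messy_ethnicity_table,
                                               ethnicity_vocab):
    s = start_curation(messy_ethnicity_table)
    propose_column_renames(s, ethnicity_vocab)
    with pytest.raises(StageError, match="pending"):
        advance_stage(s)


# ---------------------------------------------------------------------------
# unmatched terms, curated output, whole pipeline
# ---------------------------------------------------------------------------

def test_unmatched_terms_lists_unknown_instances(ethnicity_vocab):
    t = MetadataTable("d", ["race"], [["Maori"], ["B"]])
    s = _values_state(t, ethnicity_vocab)
    props = propose_value_harmonization(s, "ethnicity", ethnicity_vocab)
    assert ("ethnicity", "Maori") in unmatched_terms(s)
    for p in props:
        apply_decision(s, p.proposal_id,
                       "accept" if p.suggested else "reject")
    assert unmatched_terms(s) == []  # rejected => no longer listed


def test_curated_table_requires_done_stage(messy_ethnicity_table,
                                           ethnicity_vocab):
    s = start_curation(messy_ethnicity_table)
    with pytest.raises(StageError, match="not finished"):
        curated_table(s)


def test_auto_pipeline_harmonizes_worked_example(messy_ethnicity_table,
                                                ethnicity_vocab):
    s = run_auto_curation(messy_ethnicity_table, ethnicity_vocab)
    out = curated_table(s)
    assert out.column_headers[0] == "ethnicity"
    assert [r[0] for r in out.rows] == ["Black", "White", "Black", "White", "Inuit"]
    assert set(r[0] for r in out.rows) <= {"Black", "White", "Inuit"}
    # 'dose' is not in the vocabulary: untouched, staged as feature
    assert [r[1] for r in out.rows] == [r[1] for r in messy_ethnicity_table.rows]
    assert any(e.term == "dose" for e in s.temp_vocab.entries)


def test_pipeline_is_idempotent_on_its_own_output(messy_ethnicity_table,
                                                  ethnicity_vocab):
    first = curated_table(run_auto_curation(messy_ethnicity_table,
                                            ethnicity_vocab))
    s2 = run_auto_curation(first, ethnicity_vocab)
    second = curated_table(s2)
    assert second.content_equals(first)
    actionable = [p for p in s2.proposals
                  if p.status in ("accepted", "edited")
                  and p.current != (p.edited_value or p.suggested)]
    assert actionable == []


def test_audit_completeness_every_diff_has_a_record(messy_ethnicity_table,
                                                    ethnicity_vocab):
    s = run_auto_curation(messy_ethnicity_table, ethnicity_vocab)
    changing = [r for r in s.trail.records
                if r.action_kind in ("rename", "merge", "replace", "delete")
                and r.before != r.after]
    # header change: race->ethnicity; value changes: 4 unique synonyms
    assert len(changing) == 5
    assert s.original.content_equals(messy_ethnicity_table)
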