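"""Shared fixtures and independent brute-force oracles.

The oracles re-derive expected results with the plainest possible code
(dynamic-programming edit distance, all-pairs scans, direct rule tables)
so they share no code path with the implementation they check.
"""

from __future__ import annotations

import pytest

from metacurate import MetadataTable, ethnicity_vocabulary
from metacurate.vocabulary import Vocabulary, normalize_term


@pytest.fixture
def ethnicity_vocab() -> Vocabulary:
    return ethnicity_vocabulary()


@pytest.fixture
def messy_ethnicity_table() -> MetadataTable:
    """Free-text table using only documented synonyms of the example."""
    return MetadataTable(
        dataset_id="geo1",
        column_headers=["race", "dose"],
        rows=[
            ["African-American", "10"],
            ["Caucasian", "20"],
            ["B", "10"],
            ["C", "20"],
            ["Inuit", "30"],
        ],
    )


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def dp_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        curr = [i]
        for j, cb in enumerate(b, 1):
            curr.append(min(prev[j] + 1, curr[j - 1] + 1,
                            prev[j - 1] + (ca != cb)))
        prev = curr
    return prev[len(b)]


def oracle_similarity(query: str, term: str) -> float:
    a = " ".join(sorted(normalize_term(query).split()))
    b = " ".join(sorted(normalize_term(term).split()))
    if not a and not b:
        return 1.0
    return 1.0 - dp_levenshtein(a, b) / max(len(a), len(b))


def oracle_fuzzy_ranking(term_pairs, query, threshold):
    """Best similarity per canonical key, filtered and ranked."""
    best = {}
    for term, key in term_pairs:
        s = oracle_similarity(query, term)
        if s >= threshold and s > best.get(key, -1.0):
            best[key] = s
    return sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))


def oracle_validate(v: Vocabulary) -> int:
    """Count of collisions via an exhaustive pairwise scan."""
    n = 0
    fpairs = []
    for key, entry in v.features.items():
        fpairs.append((key, key))
        fpairs += [(s, key) for s in entry.synonyms]
    for i in range(len(fpairs)):
        for j in range(i + 1, len(fpairs)):
            (t1, k1), (t2, k2) = fpairs[i], fpairs[j]
            if normalize_term(t1) == normalize_term(t2) and k1 != k2:
                n += 1
    for key, entry in v.features.items():
        ipairs = []
        for inst, syns in entry.instances.items():
            ipairs.append((inst, inst))
            ipairs += [(s, inst) for s in syns]
        for i in range(len(ipairs)):
            for j in range(i + 1, len(ipairs)):
                (t1, k1), (t2, k2) = ipairs[i], ipairs[j]
                if normalize_term(t1) == normalize_term(t2) and k1 != k2:
                    n += 1
    return n


def oracle_duplicate_groups(table: MetadataTable):
    """All-pairs duplicate-column scan; returns {norm_header: [indices]}."""
    groups = {}
    for i, hi in enumerate(table.column_headers):
        for j, hj in enumerate(table.column_headers):
            if i < j and normalize_term(hi) == normalize_term(hj):
                groups.setdefault(normalize_term(hi), set()).update({i, j})
    return {k: sorted(v) for k, v in groups.items()}


def oracle_coalesce(columns: list[list[str]], missing) -> list[str]:
    """Cell-wise first-non-missing coalesce across columns."""
    out = []
    for cells in zip(*columns):
        value = cells[0]  # all-missing rows keep the kept cell verbatim
        for c in cells:
            if not missing(c):
                value = c
                break
        out.append(value)
    return out


def oracle_feature_status(feature, tables, v, t) -> str:
    """Direct re-statement of the traffic-light rule table."""
    def ref_feature(term):
        return v.resolves_feature(term)

    statuses = []
    in_ref = ref_feature(feature) is not None
    in_temp = t.resolves_feature(feature) is not None
    if not in_ref:
        statuses.append("AMBER" if in_temp else "RED")

    # header conflicts
    seen = {}
    for table in tables:
        for h in table.column_headers:
            canon = ref_feature(h) or t.resolves_feature(h) or h
            seen.setdefault(normalize_term(h), set()).add(canon)
    for canons in seen.values():
        if feature in canons and len(canons) > 1:
            statuses.append("RED")

    for table in tables:
        canons = {ref_feature(h) or t.resolves_feature(h) or h
                  for h in table.column_headers}
        if feature not in canons:
            statuses.append("AMBER")
        else:
            for h_idx, h in enumerate(table.column_headers):
                if (ref_feature(h) or t.resolves_feature(h) or h) != feature:
                    continue
                from metacurate.curation import is_missing
                for row in table.rows:
                    cell = row[h_idx]
                    if is_missing(cell):
                        continue
                    rk = ref_feature(feature)
                    if rk is not None and v.resolves_instance(rk, cell) is not None:
                        continue
                    if t.resolves_instance(feature, cell) is not None:
                        statuses.append("AMBER")
                    else:
                        statuses.append("RED")
    order = {"RED": 0, "AMBER": 1, "GREEN": 2}
    return min(statuses, key=order.__getitem__) if statuses else "GREEN"
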