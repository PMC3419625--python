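"""Unified set construction, Venn regions, annotation transfer, catalog."""

import itertools

import pytest
from hypothesis import given, strategies as st

import genereconcile as gr
from genereconcile.integration import (
    assign_four_group,
    catalog_rollup,
    transfer_annotation,
    unify,
    venn_membership,
)
from genereconcile.models import (
    CardinalityCall,
    CategoryNode,
    CorrespondenceRecord,
    SourcePriority,
)

PRIORITY = SourcePriority(["v1", "v0", "8X", "dfci", "grapegen"])


# --------------------------------------------------------------------------
# unify


def test_unique_id_comes_from_highest_priority_source():
    records = unify(
        {"v1": ["V1_001"], "8X": ["GSVIVT_9"]},
        [("v1", "V1_001", "8X", "GSVIVT_9")],
        PRIORITY,
    )
    (r,) = records
    assert r.unique_id == "V1_001"
    assert r.source_rank == 1
    assert r.ids_by_source == {"v1": "V1_001", "8X": "GSVIVT_9"}


def test_gene_only_in_lowest_priority_source_keeps_its_id():
    records = unify({"v1": ["a"], "grapegen": ["EST_7"]}, [], PRIORITY)
    assert {r.unique_id for r in records} == {"a", "EST_7"}
    est = next(r for r in records if r.unique_id == "EST_7")
    assert est.source_rank == 5


def test_records_ordered_by_priority_then_input_order():
    records = unify(
        {"v1": ["a", "b"], "8X": ["x", "y"]},
        [("v1", "b", "8X", "x")],
        PRIORITY,
    )
    assert [r.unique_id for r in records] == ["a", "b", "y"]


def test_unknown_match_id_rejected():
    with pytest.raises(ValueError, match="unknown gene"):
        unify({"v1": ["a"]}, [("v1", "a", "8X", "ghost")], PRIORITY)


def test_group_count_matches_inclusion_exclusion(rng):
    """Randomized 3-source scenario: the number of unified records equals
    |A|+|B|+|C| − |A∩B| − |A∩C| − |B∩C| + |A∩B∩C| when overlaps are planted
    as star matches from A."""
    nA, nB, nC = 30, 25, 20
    ab = 7
    ac = 5
    abc = 3
    ids_a = [f"a{i}" for i in range(nA)]
    ids_b = [f"b{i}" for i in range(nB)]
    ids_c = [f"c{i}" for i in range(nC)]
    matches = []
    # first `ab` B genes match first `ab` A genes; of those the first `abc`
    # also match C; plus `ac` A-only/C matches further along
    for i in range(ab):
        matches.append(("v1", ids_a[i], "8X", ids_b[i]))
    for i in range(abc):
        matches.append(("v1", ids_a[i], "dfci", ids_c[i]))
    for i in range(ac):
        matches.append(("v1", ids_a[ab + i], "dfci", ids_c[abc + i]))
    records = unify({"v1": ids_a, "8X": ids_b, "dfci": ids_c}, matches, PRIORITY)
    expected = nA + nB + nC - ab - (abc + ac) + 0  # abc already inside the ab stars
    assert len(records) == expected
    # partition: every input gene appears exactly once across the records
    seen = list(
        itertools.chain.from_iterable(
            (f"{s}:{g}" for g in r.ids_by_source[s].split(","))
            for r in records for s in r.ids_by_source
        )
    )
    assert len(seen) == len(set(seen)) == nA + nB + nC


# --------------------------------------------------------------------------
# venn_membership


def test_venn_counts_simple_fixture():
    records = unify(
        {"v1": [f"a{i}" for i in range(15)], "8X": [f"b{i}" for i in range(13)]},
        [("v1", f"a{i}", "8X", f"b{i}") for i in range(10)],
        PRIORITY,
    )
    regions = venn_membership(records)
    assert regions[frozenset({"v1", "8X"})] == 10
    assert regions[frozenset({"v1"})] == 5
    assert regions[frozenset({"8X"})] == 3
    assert sum(regions.values()) == len(records)


@given(
    st.lists(
        st.sets(st.sampled_from(["v1", "v0", "8X", "dfci"]), min_size=1),
        min_size=1, max_size=40,
    )
)
def test_venn_regions_sum_to_total_and_match_recount(signatures):
    records = [
        CorrespondenceRecord(f"g{i}", 1, {s: f"g{i}" for s in sig})
        for i, sig in enumerate(signatures)
    ]
    regions = venn_membership(records)
    assert sum(regions.values()) == len(records)
    # brute-force recount per signature
    for sig, n in regions.items():
        assert n == sum(1 for r in records if frozenset(r.ids_by_source) == sig)


# --------------------------------------------------------------------------
# transfer_annotation


def _record(uid, ids):
    return CorrespondenceRecord(uid, 1, ids)


def test_clean_pair_inherits_annotation():
    records = [_record("b1", {"v1": "b1", "8X": "a1"})]
    calls = [CardinalityCall("b1", "v1", "OK", 1, ["a1"])]
    transfer_annotation(records, {"a1": "putative kinase"}, calls)
    assert records[0].annotation == "putative kinase"
    assert records[0].needs_review is False


def test_cardinality_issue_flags_review():
    records = [_record("b1", {"v1": "b1", "8X": "a1"})]
    calls = [CardinalityCall("b1", "v1", "to_split", 2, ["a1", "a2"])]
    transfer_annotation(records, {"a1": "kinase"}, calls)
    assert records[0].needs_review is True
    assert records[0].annotation == "kinase"  # provisional copy
    assert records[0].cardinality_comment == "To split"


def test_unmatched_gene_flagged_with_empty_annotation():
    records = [_record("b9", {"v1": "b9"})]
    calls = [CardinalityCall("b9", "v1", "unmatched", 0)]
    transfer_annotation(records, {}, calls)
    assert records[0].needs_review is True
    assert records[0].annotation == ""
    assert records[0].cardinality_comment == "XX"


def test_review_count_identity(small_sim, small_result):
    """Over one record per newer-version gene, count(needs_review) equals
    count(non-clean calls), unmatched included."""
    calls_b = [c for c in small_result.calls if c.version_label == "B"]
    records = [
        _record(c.gene_id,
                {"B": c.gene_id, **({"A": c.partners[0]} if c.partners else {})})
        for c in calls_b
    ]
    transfer_annotation(records, {}, calls_b)
    n_flagged = sum(r.needs_review for r in records)
    expect = sum(1 for c in calls_b if c.call not in ("OK", "OK_split"))
    assert n_flagged == expect


# --------------------------------------------------------------------------
# assign_four_group


@pytest.mark.parametrize(
    "desc,group",
    [
        (None, "no_hit"),
        ("retrotransposon gag protein", "viral_te"),
        ("uncharacterized protein At1g01010", "unknown_function"),
        ("cinnamoyl-CoA reductase", "known_function"),
    ],
)
def test_four_group_examples(desc, group):
    r = CorrespondenceRecord("g", 1, {"v1": "g"})
    assign_four_group([r], {"g": desc})
    assert r.four_group == group


def test_four_group_exhaustive_and_exclusive(rng):
    descs = [None, "virus coat", "unknown", "kinase", "pol protein", ""]
    records = [CorrespondenceRecord(f"g{i}", 1, {"v1": f"g{i}"})
               for i in range(len(descs))]
    assign_four_group(records, {f"g{i}": d for i, d in enumerate(descs)})
    assert all(r.four_group in
               ("known_function", "unknown_function", "viral_te", "no_hit")
               for r in records)


def test_saturated_informative_hits_all_known():
    records = [CorrespondenceRecord(f"g{i}", 1, {"v1": f"g{i}"}) for i in range(5)]
    assign_four_group(records, {f"g{i}": "cellulose synthase" for i in range(5)})
    assert {r.four_group for r in records} == {"known_function"}


# --------------------------------------------------------------------------
# catalog_rollup


CATALOG = {
    "1": CategoryNode("1", "metabolism", 1),
    "1.1": CategoryNode("1.1", "lipid", 2, parent_code="1"),
    "1.2": CategoryNode("1.2", "amino acid", 2, parent_code="1"),
    "2": CategoryNode("2", "transport", 1),
    "2.1": CategoryNode("2.1", "ion", 2, parent_code="2"),
}


def test_distinct_roots_counted_once_each():
    r = CorrespondenceRecord("g", 1, {"v1": "g"}, categories=["1.1", "2.1"])
    roll = catalog_rollup([r], CATALOG)
    assert roll["per_category"]["1"] == 1
    assert roll["per_category"]["2"] == 1
    assert roll["root_memberships"] == 2


def test_shared_root_deduplicated():
    r = CorrespondenceRecord("g", 1, {"v1": "g"}, categories=["1.1", "1.2"])
    roll = catalog_rollup([r], CATALOG)
    assert roll["per_category"]["1"] == 1
    assert roll["multi_membership"] == 1


def test_unknown_code_rejected():
    r = CorrespondenceRecord("g", 1, {"v1": "g"}, categories=["9.9"])
    with pytest.raises(ValueError, match="absent from catalog"):
        catalog_rollup([r], CATALOG)


def test_rollup_conserves_totals_against_recount(rng):
    """Random assignments versus a brute-force hierarchy walk."""
    codes = list(CATALOG)
    records = []
    for i in range(60):
        k = int(rng.integers(0, 4))
        cats = list(rng.choice(codes, size=k, replace=False)) if k else []
        records.append(CorrespondenceRecord(f"g{i}", 1, {"v1": f"g{i}"},
                                            categories=cats))
    roll = catalog_rollup(records, CATALOG)

    def ancestors(code):
        out = set()
        while code:
            out.add(code)
            code = CATALOG[code].parent_code
        return out

    for code in CATALOG:
        brute = sum(
            1 for r in records
            if any(code in ancestors(c) for c in set(r.categories))
        )
        assert roll["per_category"].get(code, 0) == brute
    brute_roots = sum(
        len({a for c in set(r.categories) for a in ancestors(c)
             if CATALOG[a].level == 1})
        for r in records
    )
    assert roll["root_memberships"] == brute_roots
    assert sum(
        n for code, n in roll["per_category"].items() if CATALOG[code].level == 1
    ) == brute_roots
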