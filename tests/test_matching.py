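"""Stringency filtering and the gene-order consistency rule."""

import pytest
from hypothesis import given, strategies as st

import genereconcile as gr
from genereconcile.matching import (
    CONSISTENT,
    INCONSISTENT,
    UNTESTABLE,
    neighbor_consistency,
)
from genereconcile.models import GeneModel, MatchHit


def make_hit(q="q", s="s", identity=99.0, e=1e-50, bits=500.0, length=500,
             q_iv=(1, 500), s_iv=(1, 500)):
    return MatchHit(q, s, identity, length, 0, 0, q_iv[0], q_iv[1],
                    s_iv[0], s_iv[1], e, bits)


# --------------------------------------------------------------------------
# filter_hits


def test_retains_above_both_thresholds():
    kept = gr.filter_hits([make_hit(identity=96.0, e=1e-25)])
    assert len(kept) == 1


@pytest.mark.parametrize(
    "identity,e",
    [
        (95.0, 1e-25),   # identity exactly at the bound
        (94.9, 1e-25),
        (96.0, 1e-20),   # e-value exactly at the bound
        (96.0, 1e-19),
    ],
)
def test_boundary_hits_rejected_strict_inequalities(identity, e):
    assert gr.filter_hits([make_hit(identity=identity, e=e)]) == []


def test_est_mode_length_floor():
    policy = gr.FilterPolicy(mode="est")
    short = make_hit(length=99)
    long = make_hit(length=100)
    assert gr.filter_hits([short], policy) == []
    assert gr.filter_hits([long], policy) == [long]
    # genomic mode has no length floor
    assert gr.filter_hits([short]) == [short]


def test_top_k_matches_sort_truncate_oracle(rng):
    """Per query, exactly the top-4 hits by bit score survive; brute-force
    sort-and-truncate oracle."""
    hits = [
        make_hit(q="g1", s=f"s{i}", bits=float(b))
        for i, b in enumerate(rng.choice(10_000, size=6, replace=False))
    ]
    kept = gr.filter_hits(hits)
    oracle = sorted(hits, key=lambda h: -h.bit_score)[:4]
    assert kept == oracle


def test_top_k_tiebreak_by_identity_length_subject():
    hits = [
        make_hit(q="g", s="b", bits=100.0, identity=96.0, length=400),
        make_hit(q="g", s="a", bits=100.0, identity=96.0, length=400),
        make_hit(q="g", s="c", bits=100.0, identity=97.0, length=300),
        make_hit(q="g", s="d", bits=100.0, identity=96.0, length=500),
        make_hit(q="g", s="e", bits=101.0, identity=95.5, length=200),
    ]
    kept = gr.filter_hits(hits)
    assert [h.subject_id for h in kept] == ["e", "c", "d", "a"]


_hits_strategy = st.lists(
    st.builds(
        make_hit,
        q=st.sampled_from(["q1", "q2", "q3"]),
        s=st.sampled_from(["s1", "s2", "s3", "s4", "s5", "s6"]),
        identity=st.floats(90.0, 100.0),
        e=st.sampled_from([1e-30, 1e-21, 1e-19, 1e-10]),
        bits=st.floats(10.0, 1000.0),
        length=st.integers(50, 2000),
    ),
    max_size=30,
)


@given(_hits_strategy)
def test_filter_is_idempotent_subset_and_nonmutating(hits):
    policy = gr.FilterPolicy()
    once = gr.filter_hits(hits, policy)
    assert gr.filter_hits(once, policy) == once
    assert all(h in hits for h in once)  # subset, fields untouched


# --------------------------------------------------------------------------
# neighbor consistency


def _genes(version, layout):
    """layout: {chrom: [gene ids in order]} -> GeneModel list."""
    out = []
    for chrom, ids in layout.items():
        pos = 1
        for gid in ids:
            out.append(GeneModel.with_naming(gid, version, chrom, pos, pos + 99))
            pos += 200
    return out


def test_adjacent_pairs_are_consistent():
    ga = _genes("A", {"c1": ["a1", "a2"]})
    gb = _genes("B", {"c1": ["b1", "b2"]})
    res = neighbor_consistency([("a1", "b1"), ("a2", "b2")], ga, gb)
    assert set(res.values()) == {CONSISTENT}


def test_single_gene_scaffold_is_untestable():
    ga = _genes("A", {"c1": ["a1"], "c2": ["a2", "a3"]})
    gb = _genes("B", {"c1": ["b1"], "c2": ["b2", "b3"]})
    res = neighbor_consistency([("a1", "b1"), ("a2", "b2"), ("a3", "b3")], ga, gb)
    assert res[("a1", "b1")] == UNTESTABLE
    assert res[("a2", "b2")] == CONSISTENT


def test_shuffled_mapping_all_inconsistent():
    ids = [f"a{i}" for i in range(8)]
    ga = _genes("A", {"c1": ids})
    gb = _genes("B", {"c1": [f"b{i}" for i in range(8)]})
    # pair a_i with b_{perm(i)} such that no adjacency survives
    perm = [4, 0, 5, 1, 6, 2, 7, 3]
    pairs = [(f"a{perm[i]}", f"b{i}") for i in range(8)]
    res = neighbor_consistency(pairs, ga, gb)
    assert set(res.values()) == {INCONSISTENT}


def test_skip_tolerates_one_unmatched_gene():
    ga = _genes("A", {"c1": ["a1", "ax", "a2"]})  # ax unmatched
    gb = _genes("B", {"c1": ["b1", "by", "b2"]})  # by unmatched
    res = neighbor_consistency([("a1", "b1"), ("a2", "b2")], ga, gb)
    assert set(res.values()) == {CONSISTENT}
    # with no skip allowed, the intervening unmatched gene makes the
    # neighborhood unreachable: the pair cannot be tested at all
    strict = gr.NeighborRule(max_skip=0)
    res0 = neighbor_consistency([("a1", "b1"), ("a2", "b2")], ga, gb, strict)
    assert set(res0.values()) == {UNTESTABLE}


def brute_force_consistency(pairs, ga, gb, max_skip=1):
    """Exhaustive oracle: a pair is consistent iff some *other* pair is
    adjacent to it on both sides, adjacency meaning all intervening genes on
    that chromosome are partnerless and number at most max_skip."""
    def order(genes):
        by = {}
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            by.setdefault(g.chromosome, []).append(g.gene_id)
        return by

    oa, ob = order(ga), order(gb)
    paired_a = {a for a, _ in pairs}
    paired_b = {b for _, b in pairs}

    def adjacent(omap, paired, x, y):
        for ids in omap.values():
            if x in ids and y in ids:
                i, j = sorted((ids.index(x), ids.index(y)))
                between = ids[i + 1:j]
                return (i != j and len(between) <= max_skip
                        and all(g not in paired for g in between))
        return False

    out = {}
    for a, b in pairs:
        chrom_a = next(c for c, ids in oa.items() if a in ids)
        chrom_b = next(c for c, ids in ob.items() if b in ids)
        if len(oa[chrom_a]) == 1 or len(ob[chrom_b]) == 1:
            out[(a, b)] = UNTESTABLE
            continue
        testable = any(
            adjacent(ob, paired_b, b, b2) for _, b2 in pairs if b2 != b
        )
        ok = any(
            adjacent(ob, paired_b, b, b2) and adjacent(oa, paired_a, a, a2)
            for a2, b2 in pairs
            if (a2, b2) != (a, b)
        )
        out[(a, b)] = CONSISTENT if ok else (INCONSISTENT if testable else UNTESTABLE)
    return out


@pytest.mark.parametrize("seed", range(6))
def test_matches_brute_force_oracle_on_random_instances(seed, rng):
    import numpy as np

    r = np.random.default_rng(seed)
    n = int(r.integers(5, 50))
    ids_a = [f"a{i}" for i in range(n)]
    ids_b = [f"b{i}" for i in range(n)]
    # random gene order in both versions over two chromosomes
    split = int(r.integers(1, n))
    ga = _genes("A", {"c1": ids_a[:split], "c2": ids_a[split:]})
    order_b = list(r.permutation(ids_b))
    gb = _genes("B", {"c1": order_b[:split], "c2": order_b[split:]})
    # pair a subset
    k = int(r.integers(2, n))
    chosen = sorted(r.choice(n, size=k, replace=False))
    pairs = [(f"a{i}", f"b{i}") for i in chosen]
    got = neighbor_consistency(pairs, ga, gb)
    want = brute_force_consistency(pairs, ga, gb)
    assert got == want
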