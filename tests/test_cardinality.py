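"""Match-graph construction, cardinality classification, split proposals."""

import itertools

import pytest

import genereconcile as gr
from genereconcile.cardinality import (
    DIFFERENT,
    MIXED,
    SAME,
    ProteinEvidence,
    build_graph,
    classify,
    enumerate_resolutions,
    propose_splits,
    same_portion,
)
from genereconcile.models import (
    EVID_MULTIPLE,
    CardinalityCall,
    GeneModel,
    MatchHit,
    TO_SPLIT,
    UNRESOLVED,
)


def make_hit(q, s, q_iv, s_iv, identity=99.0, bits=500.0, e=1e-80):
    return MatchHit(q, s, identity, q_iv[1] - q_iv[0] + 1, 0, 0,
                    q_iv[0], q_iv[1], s_iv[0], s_iv[1], e, bits)


def one_gene_per_chrom(version, ids, length=2000):
    """Each gene alone on its chromosome: neighbor context untestable, so
    classification depends only on the graph topology and evidence."""
    return [
        GeneModel.with_naming(g, version, f"{version}_c{i}", 1, length)
        for i, g in enumerate(ids)
    ]


# --------------------------------------------------------------------------
# build_graph


def test_reciprocal_hits_merge_to_one_edge():
    ga = one_gene_per_chrom("A", ["a1"])
    gb = one_gene_per_chrom("B", ["b1"])
    g = build_graph([make_hit("a1", "b1", (1, 500), (1, 500))],
                    [make_hit("b1", "a1", (1, 480), (21, 500))], ga, gb)
    e = g.edge("a1", "b1")
    assert e.directions == {"A->B", "B->A"}
    assert e.interval_a == (1, 500)   # hull of both directions
    assert e.interval_b == (1, 500)


def test_one_direction_hit_keeps_flag():
    ga = one_gene_per_chrom("A", ["a1"])
    gb = one_gene_per_chrom("B", ["b1"])
    g = build_graph([make_hit("a1", "b1", (1, 500), (1, 500))], [], ga, gb)
    assert g.edge("a1", "b1").directions == {"A->B"}


def test_hub_degree_counted(rng):
    ga = one_gene_per_chrom("A", ["a1"])
    gb = one_gene_per_chrom("B", ["b1", "b2", "b3"])
    hits = [make_hit("a1", b, (1, 500), (1, 500)) for b in ("b1", "b2", "b3")]
    g = build_graph(hits, [], ga, gb)
    assert g.degree(g.node_a("a1")) == 3
    # brute-force recount over the edge list
    assert sum(1 for e in g.edges_of(g.node_a("a1"))) == 3


def test_unknown_gene_id_rejected():
    ga = one_gene_per_chrom("A", ["a1"])
    gb = one_gene_per_chrom("B", ["b1"])
    with pytest.raises(ValueError, match="absent"):
        build_graph([make_hit("ghost", "b1", (1, 9), (1, 9))], [], ga, gb)


def test_repeat_track_excluded_by_default():
    ga = one_gene_per_chrom("A", ["a1"])
    gb = [GeneModel.with_naming("b1", "B", "c1", 1, 2000, track="repeat")]
    hits = [make_hit("a1", "b1", (1, 500), (1, 500))]
    g = build_graph(hits, [], ga, gb)
    assert g.graph.number_of_edges() == 0
    assert g.node_b("b1") not in g.graph  # not even a node
    g2 = build_graph(hits, [], ga, gb, include_repeat=True)
    assert g2.graph.number_of_edges() == 1


# --------------------------------------------------------------------------
# same_portion


@pytest.mark.parametrize(
    "intervals,expected",
    [
        ([(1, 500), (10, 490)], SAME),
        ([(1, 400), (600, 1000)], DIFFERENT),
        ([(1, 500), (10, 490), (600, 1000)], MIXED),
    ],
)
def test_same_portion_examples(intervals, expected):
    assert same_portion(intervals) == expected


def test_same_portion_matches_pairwise_overlap_oracle(rng):
    """Randomized intervals versus an exhaustive pairwise-overlap recount."""
    for _ in range(200):
        n = int(rng.integers(2, 5))
        ivs = []
        for _ in range(n):
            lo = int(rng.integers(1, 1000))
            ivs.append((lo, lo + int(rng.integers(50, 800))))
        got = same_portion(ivs)
        flags = []
        for x, y in itertools.combinations(ivs, 2):
            ov = max(0, min(x[1], y[1]) - max(x[0], y[0]) + 1)
            shorter = min(x[1] - x[0] + 1, y[1] - y[0] + 1)
            flags.append(ov >= 0.5 * shorter)
        want = SAME if all(flags) else (DIFFERENT if not any(flags) else MIXED)
        assert got == want


# --------------------------------------------------------------------------
# classification of hand-built components


def _evidence(per_gene):
    return ProteinEvidence(per_gene)


def run_classify(ga, gb, hits_ab, evidence=None):
    g = build_graph(hits_ab, [], ga, gb)
    calls = classify(g, ga, gb, evidence=evidence)
    return {(c.version_label, c.gene_id): c for c in calls}


def test_tandem_copies_called_redundant():
    """Two newer genes on the same portion of one older gene."""
    ga = one_gene_per_chrom("A", ["a1"])
    gb = one_gene_per_chrom("B", ["b1", "b2"])
    hits = [make_hit("a1", b, (1, 900), (1, 900)) for b in ("b1", "b2")]
    calls = run_classify(ga, gb, hits)
    assert calls[("B", "b1")].call == "redundant"
    assert calls[("B", "b2")].call == "redundant"


def test_incorrectly_split_newer_genes_called_overlap():
    """Different portions + one spanning protein: reassemble in B."""
    ga = one_gene_per_chrom("A", ["a1"])
    gb = one_gene_per_chrom("B", ["b1", "b2"])
    hits = [make_hit("a1", "b1", (1, 900), (1, 900)),
            make_hit("a1", "b2", (1000, 1800), (1, 800))]
    ev = _evidence({"a1": [("p1", (1, 1800), 1.0)]})
    calls = run_classify(ga, gb, hits, ev)
    assert calls[("B", "b1")].call == "overlap"
    assert calls[("B", "b1")].evidence == "protein-single"


def test_older_chimera_called_split():
    """Each newer part matches its own protein: B correctly split."""
    ga = one_gene_per_chrom("A", ["a1"])
    gb = one_gene_per_chrom("B", ["b1", "b2"])
    hits = [make_hit("a1", "b1", (1, 900), (1, 900)),
            make_hit("a1", "b2", (1000, 1800), (1, 800))]
    ev = _evidence({"b1": [("p1", (1, 900), 1.0)],
                    "b2": [("p2", (1, 800), 1.0)]})
    calls = run_classify(ga, gb, hits, ev)
    assert calls[("B", "b1")].call == "split"
    assert calls[("B", "b1")].evidence == "protein-multiple"


def test_correct_merge_called_merged():
    ga = one_gene_per_chrom("A", ["a1", "a2"])
    gb = one_gene_per_chrom("B", ["b1"])
    hits = [make_hit("a1", "b1", (1, 900), (1, 900)),
            make_hit("a2", "b1", (1, 800), (1000, 1800))]
    ev = _evidence({"b1": [("p1", (1, 1800), 1.0)]})
    calls = run_classify(ga, gb, hits, ev)
    assert calls[("B", "b1")].call == "merged"


def test_newer_chimera_called_to_split_with_parts():
    ga = one_gene_per_chrom("A", ["a1", "a2"])
    gb = one_gene_per_chrom("B", ["b1"])
    hits = [make_hit("a1", "b1", (1, 900), (1, 900)),
            make_hit("a2", "b1", (1, 800), (1000, 1800))]
    ev = _evidence({"b1": [("p1", (1, 900), 1.0), ("p2", (1000, 1800), 1.0)]})
    calls = run_classify(ga, gb, hits, ev)
    c = calls[("B", "b1")]
    assert c.call == "to_split"
    assert len(c.parts) == 2


def test_missing_evidence_gives_unresolved_not_a_guess():
    ga = one_gene_per_chrom("A", ["a1", "a2"])
    gb = one_gene_per_chrom("B", ["b1"])
    hits = [make_hit("a1", "b1", (1, 900), (1, 900)),
            make_hit("a2", "b1", (1, 800), (1000, 1800))]
    calls = run_classify(ga, gb, hits, evidence=None)
    assert calls[("B", "b1")].call == UNRESOLVED
    assert calls[("B", "b1")].evidence == "none"


def test_mirror_same_portion_hub_not_called_redundant():
    """Several older genes on the same portion of one newer gene: the
    taxonomy deliberately leaves this uninterpreted."""
    ga = one_gene_per_chrom("A", ["a1", "a2"])
    gb = one_gene_per_chrom("B", ["b1"])
    hits = [make_hit("a1", "b1", (1, 900), (1, 900)),
            make_hit("a2", "b1", (1, 900), (1, 900))]
    calls = run_classify(ga, gb, hits)
    assert calls[("B", "b1")].call == UNRESOLVED
    assert all(c.call != "redundant" for c in calls.values())


def test_two_conditions_in_one_component_called_multiple():
    """An older-side hub with different portions plus a newer-side hub."""
    ga = one_gene_per_chrom("A", ["a1", "a2"])
    gb = one_gene_per_chrom("B", ["b1", "b2"])
    hits = [make_hit("a1", "b1", (1, 400), (1, 400)),
            make_hit("a1", "b2", (800, 1400), (1, 600)),
            make_hit("a2", "b2", (1, 500), (900, 1400))]
    calls = run_classify(ga, gb, hits)
    assert {calls[k].call for k in calls} == {"multiple"}


def test_unmatched_degree_zero():
    ga = one_gene_per_chrom("A", ["a1", "a2"])
    gb = one_gene_per_chrom("B", ["b1"])
    hits = [make_hit("a1", "b1", (1, 500), (1, 500))]
    calls = run_classify(ga, gb, hits)
    assert calls[("A", "a2")].call == "unmatched"
    assert calls[("A", "a2")].degree == 0


def test_every_gene_gets_exactly_one_call(small_sim, small_result):
    """Partition invariant over the simulated pair."""
    counts = {}
    for c in small_result.calls:
        key = (c.version_label, c.gene_id)
        counts[key] = counts.get(key, 0) + 1
    assert set(counts.values()) == {1}
    expect = {("A", g.gene_id) for g in small_sim.genes_a if g.track == "main"}
    expect |= {("B", g.gene_id) for g in small_sim.genes_b if g.track == "main"}
    assert set(counts) == expect


# --------------------------------------------------------------------------
# split proposals


def make_to_split_call(gid, k):
    parts = [((1 + 1000 * i, 900 + 1000 * i), f"p{gid}_{i}") for i in range(k)]
    return CardinalityCall(gene_id=gid, version_label="B", call=TO_SPLIT,
                           degree=k, evidence=EVID_MULTIPLE, parts=parts)


def test_split_accounting_sums_k_minus_one():
    """10 chimeras, 3 triple: 3*2 + 7*1 = 13 new records."""
    calls = [make_to_split_call(f"g{i}", 3 if i < 3 else 2) for i in range(10)]
    proposals, summary = propose_splits(calls)
    assert summary == {"n_genes_split": 10, "n_triple": 3, "n_new": 13}
    assert sum(p.n_new for p in proposals) == 13


def test_no_chimeras_no_new_records():
    assert propose_splits([]) == ([], {"n_genes_split": 0, "n_triple": 0, "n_new": 0})


def test_new_ids_use_suffix_convention():
    (p,), _ = propose_splits([make_to_split_call("GSVIVT01", 3)])
    assert p.new_ids == ["GSVIVT01_2", "GSVIVT01_3"]


def test_overlapping_parts_downgraded_to_unresolved():
    call = CardinalityCall(
        gene_id="g", version_label="B", call=TO_SPLIT, degree=2,
        evidence=EVID_MULTIPLE,
        parts=[((1, 900), "p1"), ((100, 1000), "p2")],
    )
    proposals, summary = propose_splits([call])
    assert proposals == []
    assert call.call == UNRESOLVED
    assert summary["n_new"] == 0


# --------------------------------------------------------------------------
# resolution enumeration


def _complex_component():
    ga = one_gene_per_chrom("A", ["C", "D"])
    gb = one_gene_per_chrom("B", ["N1", "N2"])
    hits = [make_hit("C", "N1", (1, 400), (1, 400)),
            make_hit("C", "N2", (800, 1400), (1, 600)),
            make_hit("D", "N2", (1, 500), (900, 1400))]
    g = build_graph(hits, [], ga, gb)
    comp = next(c for c in g.components() if len(c) == 4)
    return g, comp


def test_complex_topology_yields_three_resolutions():
    g, comp = _complex_component()
    rs = enumerate_resolutions(g, comp)
    assert [r.kind for r in rs] == ["no_change", "transfer_portion", "merge"]
    assert all(r.deciding_evidence for r in rs)


def test_degenerate_component_rejected():
    ga = one_gene_per_chrom("A", ["a1"])
    gb = one_gene_per_chrom("B", ["b1"])
    g = build_graph([make_hit("a1", "b1", (1, 500), (1, 500))], [], ga, gb)
    comp = next(c for c in g.components() if len(c) == 2)
    with pytest.raises(ValueError, match="topology"):
        enumerate_resolutions(g, comp)
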