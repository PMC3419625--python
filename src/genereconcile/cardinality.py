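"""Bipartite match-graph construction and cardinality classification.

The degree to which a gene is linked to several sister genes in the other
assembly version is its *cardinality*.  Per connected component of the
bipartite match graph the classifier distinguishes, for the newer version's
genes:

* ``OK`` / ``low_score`` — clean one-to-one pairs, validated by gene-order
  consistency and an alignment-score floor;
* ``redundant`` — several newer genes matching the *same portion* of one
  older gene (typically tandem repeats collapsed in the older assembly);
* ``overlap`` — several newer genes matching *different portions* of one
  older gene whose locus is spanned by a single evidence protein: the newer
  prediction split one real gene and the pieces should be reassembled;
* ``split`` — the same topology, but each newer gene matches a distinct
  protein: the newer prediction is right and the older gene was an
  artificial chimera;
* ``merged`` — one newer gene matching different portions of several older
  genes, with a single protein spanning the locus: the newer prediction
  correctly merged an over-split older locus;
* ``to_split`` — the same topology with two or more distinct proteins on
  disjoint regions: the newer gene is an artificial chimera and a split is
  proposed (new records suffixed ``_2``, ``_3``, ...);
* ``multiple`` — components satisfying at least two of the structural
  conditions above;
* ``unmatched`` — no hit at all.

The mirrored redundancy case (several *older* genes matching one newer gene
on the same portion) is deliberately not interpreted: an error in the older,
lower-coverage prediction is the more likely cause, so such components are
reported as unresolved rather than called redundant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .aligner import KPARAM as _KPARAM, LAMBDA as _LAMBDA, LN2 as _LN2

from .matching import CONSISTENT, INCONSISTENT, NeighborRule, neighbor_consistency
from .models import (
    EVID_MULTIPLE,
    EVID_NONE,
    EVID_SINGLE,
    LOW_SCORE,
    MERGED,
    MULTIPLE,
    OK,
    OVERLAP,
    REDUNDANT,
    REPEAT,
    SPLIT,
    TO_SPLIT,
    UNMATCHED,
    UNRESOLVED,
    CardinalityCall,
    GeneModel,
    MatchHit,
    Resolution,
    SplitProposal,
)

SAME = "same"
DIFFERENT = "different"
MIXED = "mixed"


@dataclass
class Edge:
    """Merged cross-version link between one gene of each version."""

    id_a: str
    id_b: str
    interval_a: tuple[int, int]  # hull of matched intervals on the A gene
    interval_b: tuple[int, int]
    bit_score: float
    identity: float
    aln_length: int
    directions: set = field(default_factory=set)  # {"A->B", "B->A"}

    @property
    def per_bp_score(self) -> float:
        """Raw-score density (score per aligned column) recovered from the
        bit score; length-independent for a perfect alignment, so the
        low-score floor does not punish long genes."""
        s = (self.bit_score * _LN2 + math.log(_KPARAM)) / _LAMBDA
        return s / max(self.aln_length, 1)


@dataclass
class MatchGraph:
    """Bipartite graph between the two versions' (non-repeat) genes.

    Nodes are ``(version_label, gene_id)`` tuples; every eligible gene is a
    node even when isolated, so degree-0 genes are classifiable."""

    graph: nx.Graph
    version_a: str
    version_b: str

    def node_a(self, gid: str):
        return (self.version_a, gid)

    def node_b(self, gid: str):
        return (self.version_b, gid)

    def components(self):
        return nx.connected_components(self.graph)

    def edge(self, ida: str, idb: str) -> Edge:
        return self.graph.edges[self.node_a(ida), self.node_b(idb)]["edge"]

    def edges_of(self, node) -> list[Edge]:
        return [self.graph.edges[node, nb]["edge"] for nb in self.graph.neighbors(node)]

    def degree(self, node) -> int:
        return self.graph.degree(node)


def build_graph(
    hits_ab: Sequence[MatchHit],
    hits_ba: Sequence[MatchHit],
    genes_a: Iterable[GeneModel],
    genes_b: Iterable[GeneModel],
    include_repeat: bool = False,
) -> MatchGraph:
    """Union the two directional (already filtered) hit sets into one graph.

    ``hits_ab`` carry version-A queries against version-B subjects and
    ``hits_ba`` the reverse.  Per gene pair the directional hits are merged:
    intervals become their hull on each gene, the best bit score and identity
    are kept, and a direction flag records which comparisons support the
    edge.  Repeat-track genes are excluded unless ``include_repeat``.  Hits
    naming unknown gene ids are rejected.
    """
    genes_a = list(genes_a)
    genes_b = list(genes_b)
    va = genes_a[0].version_label if genes_a else "A"
    vb = genes_b[0].version_label if genes_b else "B"
    elig_a = {g.gene_id for g in genes_a if include_repeat or g.track != REPEAT}
    elig_b = {g.gene_id for g in genes_b if include_repeat or g.track != REPEAT}
    all_a = {g.gene_id for g in genes_a}
    all_b = {g.gene_id for g in genes_b}

    merged: dict[tuple[str, str], Edge] = {}

    def _absorb(ida, idb, ia, ib, hit, direction):
        key = (ida, idb)
        e = merged.get(key)
        if e is None:
            merged[key] = Edge(
                id_a=ida, id_b=idb, interval_a=ia, interval_b=ib,
                bit_score=hit.bit_score, identity=hit.pct_identity,
                aln_length=hit.aln_length, directions={direction},
            )
        else:
            e.interval_a = (min(e.interval_a[0], ia[0]), max(e.interval_a[1], ia[1]))
            e.interval_b = (min(e.interval_b[0], ib[0]), max(e.interval_b[1], ib[1]))
            if hit.bit_score > e.bit_score:
                e.bit_score = hit.bit_score
                e.identity = hit.pct_identity
                e.aln_length = hit.aln_length
            e.directions.add(direction)

    for h in hits_ab:
        if h.query_id not in all_a or h.subject_id not in all_b:
            raise ValueError(
                f"hit {h.query_id}->{h.subject_id} references a gene id absent "
                "from the loaded gene sets"
            )
        if h.query_id in elig_a and h.subject_id in elig_b:
            _absorb(h.query_id, h.subject_id, h.q_interval, h.s_interval, h, "A->B")
    for h in hits_ba:
        if h.query_id not in all_b or h.subject_id not in all_a:
            raise ValueError(
                f"hit {h.query_id}->{h.subject_id} references a gene id absent "
                "from the loaded gene sets"
            )
        if h.query_id in elig_b and h.subject_id in elig_a:
            _absorb(h.subject_id, h.query_id, h.s_interval, h.q_interval, h, "B->A")

    g = nx.Graph()
    g.add_nodes_from(((va, gid) for gid in sorted(elig_a)), version=va)
    g.add_nodes_from(((vb, gid) for gid in sorted(elig_b)), version=vb)
    for (ida, idb), e in merged.items():
        g.add_edge((va, ida), (vb, idb), edge=e)
    return MatchGraph(graph=g, version_a=va, version_b=vb)


# --------------------------------------------------------------------------
# Same-portion test


def _overlap_len(x: tuple[int, int], y: tuple[int, int]) -> int:
    return max(0, min(x[1], y[1]) - max(x[0], y[0]) + 1)


def _ilen(x: tuple[int, int]) -> int:
    return x[1] - x[0] + 1


def same_portion(intervals: Sequence[tuple[int, int]], threshold: float = 0.5) -> str:
    """Classify how ≥2 hub-side intervals relate.

    ``same`` when every pairwise reciprocal overlap covers at least
    ``threshold`` of the shorter interval, ``different`` when every pairwise
    overlap stays below it, ``mixed`` otherwise.
    """
    if len(intervals) < 2:
        raise ValueError("same_portion needs at least two intervals")
    any_same = any_diff = False
    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            ov = _overlap_len(intervals[i], intervals[j])
            shorter = min(_ilen(intervals[i]), _ilen(intervals[j]))
            if ov >= threshold * shorter:
                any_same = True
            else:
                any_diff = True
    if any_same and any_diff:
        return MIXED
    return SAME if any_same else DIFFERENT


# --------------------------------------------------------------------------
# Protein evidence


class ProteinEvidence:
    """Protein (or cDNA-level evidence) hits indexed per gene.

    Per gene a list of ``(protein_id, (start, end), cover)`` where the
    interval lies on the gene and ``cover`` is the fraction of the protein's
    length covered by its alignment to that gene.  By default only proteins
    whose existence is demonstrated at the protein level are admitted.
    """

    def __init__(self, per_gene: Mapping[str, list]):
        self.per_gene = dict(per_gene)

    @classmethod
    def from_hits(
        cls,
        hits: Sequence[MatchHit],
        protein_lengths: Mapping[str, int],
        flags: Optional[Mapping[str, bool]] = None,
        protein_level_only: bool = True,
    ) -> "ProteinEvidence":
        """Build from protein-query-vs-gene-subject hits (already filtered)."""
        acc: dict[tuple[str, str], list[MatchHit]] = {}
        for h in hits:
            pid = h.query_id
            if protein_level_only and flags is not None and not flags.get(pid, False):
                continue
            acc.setdefault((h.subject_id, pid), []).append(h)
        per_gene: dict[str, list] = {}
        for (gene, pid), hs in acc.items():
            lo = min(h.s_interval[0] for h in hs)
            hi = max(h.s_interval[1] for h in hs)
            covered = sum(h.q_end - h.q_start + 1 for h in hs)
            plen = protein_lengths.get(pid, covered)
            cover = min(1.0, covered / max(plen, 1))
            per_gene.setdefault(gene, []).append((pid, (lo, hi), cover))
        for lst in per_gene.values():
            lst.sort(key=lambda t: (t[1], t[0]))
        return cls(per_gene)

    def hits_for(self, gene_id: str) -> list:
        return self.per_gene.get(gene_id, [])


# --------------------------------------------------------------------------
# Classification


@dataclass(frozen=True)
class ClassifyPolicy:
    """Tunable predicates of the cardinality classifier.

    ``same_portion_threshold`` — reciprocal overlap fraction of the shorter
    hub-side interval above which two matches hit the *same* portion.
    ``protein_cover_frac`` — a protein supports a part when its hit covers at
    least this fraction of the protein's length; a single protein *spans* a
    locus when its hit covers at least this fraction of the union interval.
    ``part_overlap_frac`` — two protein-supported parts must overlap less
    than this fraction of the shorter part to count as distinct.
    ``low_score_percentile`` — neighbor-inconsistent one-to-one pairs whose
    per-bp bit score falls below this percentile of the consistent pairs'
    scores are flagged ``low_score``.
    """

    same_portion_threshold: float = 0.5
    protein_cover_frac: float = 0.6
    part_overlap_frac: float = 0.2
    low_score_percentile: float = 5.0
    neighbor_rule: NeighborRule = field(default_factory=NeighborRule)


def _hub_portions(graph: MatchGraph, comp) -> tuple[list, list, dict]:
    """Hub nodes (degree >= 2) on each side with their portion class."""
    hubs_a, hubs_b, portion = [], [], {}
    for node in comp:
        deg = graph.degree(node)
        if deg < 2:
            continue
        edges = graph.edges_of(node)
        if node[0] == graph.version_a:
            ivs = [e.interval_a for e in edges]
            hubs_a.append(node)
        else:
            ivs = [e.interval_b for e in edges]
            hubs_b.append(node)
        portion[node] = same_portion(ivs)
    return hubs_a, hubs_b, portion


def _union_interval(intervals: Sequence[tuple[int, int]]) -> tuple[int, int]:
    return (min(i[0] for i in intervals), max(i[1] for i in intervals))


def _spanning_protein(evidence, gene_id, union_iv, cover_frac):
    """Protein whose hit on the gene covers >= cover_frac of the union
    interval, or None."""
    best = None
    ulen = _ilen(union_iv)
    for pid, iv, _cov in evidence.hits_for(gene_id):
        covered = _overlap_len(iv, union_iv)
        if covered >= cover_frac * ulen:
            if best is None or covered > best[1]:
                best = (pid, covered)
    return best[0] if best else None


def _best_protein(evidence, gene_id, cover_frac):
    """Best protein covering >= cover_frac of its own length on the gene."""
    best = None
    for pid, iv, cov in evidence.hits_for(gene_id):
        if cov >= cover_frac and (best is None or cov > best[2]):
            best = (pid, iv, cov)
    return best


def _distinct_parts(evidence, gene_id, cover_frac, overlap_frac):
    """Protein-supported parts on one gene: hits covering >= cover_frac of
    their protein, mutually overlapping < overlap_frac of the shorter part.
    Greedy by descending cover; returns the ordered parts."""
    cands = [t for t in evidence.hits_for(gene_id) if t[2] >= cover_frac]
    cands.sort(key=lambda t: (-t[2], t[1], t[0]))
    chosen: list = []
    for pid, iv, cov in cands:
        ok = True
        for _pid2, iv2, _ in chosen:
            shorter = min(_ilen(iv), _ilen(iv2))
            if _overlap_len(iv, iv2) >= overlap_frac * shorter:
                ok = False
                break
        if ok:
            chosen.append((pid, iv, cov))
    chosen.sort(key=lambda t: t[1])
    return chosen


def classify(
    graph: MatchGraph,
    genes_a: Iterable[GeneModel],
    genes_b: Iterable[GeneModel],
    evidence: Optional[ProteinEvidence] = None,
    policy: ClassifyPolicy = ClassifyPolicy(),
) -> list[CardinalityCall]:
    """Classify every gene of both versions into the cardinality taxonomy.

    Every non-repeat gene receives exactly one call.  Older-version genes in
    a structural component carry the component's class label under their own
    version tag; the headline taxonomy reads off the newer version's calls.
    Components needing protein evidence that is absent are reported
    ``unresolved_ambiguous`` rather than guessed.
    """
    genes_a = list(genes_a)
    genes_b = list(genes_b)
    if evidence is None:
        evidence = ProteinEvidence({})
    calls: list[CardinalityCall] = []

    components = [sorted(c) for c in graph.components()]
    components.sort()

    # -- pass 1: one-to-one pairs get neighbor-consistency + score floor
    pair_comps = []
    for comp in components:
        if len(comp) == 2:
            # a two-node component is necessarily a single cross-version edge
            a = next(n for n in comp if n[0] == graph.version_a)
            b = next(n for n in comp if n[0] == graph.version_b)
            pair_comps.append((a[1], b[1]))
    consistency = neighbor_consistency(pair_comps, genes_a, genes_b, policy.neighbor_rule)
    perbp = {p: graph.edge(*p).per_bp_score for p in pair_comps}
    cons_scores = [perbp[p] for p in pair_comps if consistency[p] == CONSISTENT]
    floor = (
        float(np.percentile(cons_scores, policy.low_score_percentile))
        if cons_scores else None
    )

    for comp in components:
        nodes_a = [n for n in comp if n[0] == graph.version_a]
        nodes_b = [n for n in comp if n[0] == graph.version_b]
        # degree 0
        if len(comp) == 1:
            (v, gid) = comp[0]
            calls.append(CardinalityCall(gene_id=gid, version_label=v,
                                         call=UNMATCHED, degree=0))
            continue
        # one-to-one
        if len(nodes_a) == 1 and len(nodes_b) == 1:
            pair = (nodes_a[0][1], nodes_b[0][1])
            status = consistency[pair]
            call = OK
            # the 1e-6 slack absorbs float noise from the bit-score round-trip
            if status == INCONSISTENT and floor is not None \
                    and perbp[pair] < floor - 1e-6:
                call = LOW_SCORE
            for v, gid in comp:
                partner = pair[1] if v == graph.version_a else pair[0]
                calls.append(CardinalityCall(
                    gene_id=gid, version_label=v, call=call, degree=1,
                    partners=[partner]))
            continue

        calls.extend(_classify_component(graph, comp, nodes_a, nodes_b,
                                         evidence, policy))
    return calls


def _component_calls(graph, comp, label, evidence_label, parts_by_gene=None):
    out = []
    for v, gid in comp:
        partners = [
            (e.id_b if v == graph.version_a else e.id_a)
            for e in graph.edges_of((v, gid))
        ]
        out.append(CardinalityCall(
            gene_id=gid, version_label=v, call=label,
            degree=graph.degree((v, gid)), partners=sorted(partners),
            evidence=evidence_label,
            parts=(parts_by_gene or {}).get(gid, []),
        ))
    return out


def _classify_component(graph, comp, nodes_a, nodes_b, evidence, policy):
    """Structural classification of one multi-gene component."""
    hubs_a, hubs_b, portion = _hub_portions(graph, comp)

    preds = set()
    if any(portion[h] == SAME for h in hubs_a):
        preds.add("redundant")                      # many-B on one A, same portion
    if any(portion[h] == DIFFERENT for h in hubs_a):
        preds.add("b_relative_split")               # many-B on one A, different portions
    if any(portion[h] == DIFFERENT for h in hubs_b):
        preds.add("a_relative_split")               # one B over many A, different portions
    mixed = any(portion[h] == MIXED for h in portion)

    if mixed or len(preds) >= 2:
        return _component_calls(graph, comp, MULTIPLE, EVID_NONE)

    if preds == {"redundant"}:
        return _component_calls(graph, comp, REDUNDANT, EVID_NONE)

    if preds == {"b_relative_split"}:
        # several newer genes on different portions of one older gene.  The
        # multiple-distinct-proteins test runs first: a chimera with one long
        # part could otherwise satisfy the weaker single-protein span.
        hub = hubs_a[0]
        part_proteins = []
        for v, gid in nodes_b:
            best = _best_protein(evidence, gid, policy.protein_cover_frac)
            if best is None:
                part_proteins = None
                break
            part_proteins.append(best[0])
        if part_proteins is not None and len(set(part_proteins)) == len(part_proteins):
            return _component_calls(graph, comp, SPLIT, EVID_MULTIPLE)
        edges = graph.edges_of(hub)
        union_iv = _union_interval([e.interval_a for e in edges])
        spanning = _spanning_protein(evidence, hub[1], union_iv,
                                     policy.protein_cover_frac)
        if spanning is not None:
            return _component_calls(graph, comp, OVERLAP, EVID_SINGLE)
        return _component_calls(graph, comp, UNRESOLVED, EVID_NONE)

    if preds == {"a_relative_split"}:
        # one newer gene over different portions of several older genes
        hub = hubs_b[0]
        parts = _distinct_parts(evidence, hub[1], policy.protein_cover_frac,
                                policy.part_overlap_frac)
        if len(parts) >= 2:
            parts_by_gene = {hub[1]: [(iv, pid) for pid, iv, _ in parts]}
            return _component_calls(graph, comp, TO_SPLIT, EVID_MULTIPLE,
                                    parts_by_gene)
        edges = graph.edges_of(hub)
        union_iv = _union_interval([e.interval_b for e in edges])
        spanning = _spanning_protein(evidence, hub[1], union_iv,
                                     policy.protein_cover_frac)
        if spanning is not None:
            return _component_calls(graph, comp, MERGED, EVID_SINGLE)
        return _component_calls(graph, comp, UNRESOLVED, EVID_NONE)

    # only non-interpreted signals remain (e.g. the mirrored same-portion
    # case on the newer side, which the taxonomy deliberately leaves alone)
    return _component_calls(graph, comp, UNRESOLVED, EVID_NONE)


# --------------------------------------------------------------------------
# Split proposals


def propose_splits(
    calls: Sequence[CardinalityCall],
    overlap_tolerance: float = 0.2,
) -> tuple[list[SplitProposal], dict]:
    """Turn ``to_split`` calls into concrete split proposals plus accounting.

    A k-part chimera yields k−1 new gene records suffixed ``_2``, ``_3``, ...
    after the source id.  Proposals whose part intervals overlap beyond the
    tolerance (fraction of the shorter part) are rejected and the call
    downgraded to unresolved-ambiguous in place.  The summary reports
    ``n_genes_split``, ``n_triple`` and ``n_new`` = Σ(k−1).
    """
    proposals: list[SplitProposal] = []
    n_genes = n_triple = n_new = 0
    for call in calls:
        if call.call != TO_SPLIT or not call.parts:
            continue
        parts = sorted(call.parts, key=lambda p: p[0])
        valid = len(parts) >= 2
        for i in range(len(parts) - 1):
            iv1, iv2 = parts[i][0], parts[i + 1][0]
            shorter = min(_ilen(iv1), _ilen(iv2))
            if _overlap_len(iv1, iv2) >= overlap_tolerance * shorter:
                valid = False
                break
        if not valid:
            call.call = UNRESOLVED
            call.evidence = EVID_NONE
            call.parts = []
            continue
        new_ids = [f"{call.gene_id}_{i}" for i in range(2, len(parts) + 1)]
        prop = SplitProposal(source_gene=call.gene_id, parts=parts, new_ids=new_ids)
        call.proposed_actions = [prop]
        proposals.append(prop)
        n_genes += 1
        n_new += len(new_ids)
        if len(parts) == 3:
            n_triple += 1
    summary = {"n_genes_split": n_genes, "n_triple": n_triple, "n_new": n_new}
    return proposals, summary


# --------------------------------------------------------------------------
# Resolution enumeration for the two-by-two 'multiple situations' topology


def enumerate_resolutions(graph: MatchGraph, component: Iterable) -> list[Resolution]:
    """Enumerate candidate corrections for the classic complex topology.

    Two newer-set genes align on different regions of one older-set gene,
    while a further portion of one of them also matches a second older-set
    gene.  Three corrections are possible: keep both newer genes as they are;
    transfer the doubly-matching gene's extra portion to its sibling; or
    merge the two newer genes.  Each candidate names the protein evidence
    that would decide it.  Any other topology is rejected.
    """
    comp = sorted(component)
    nodes_a = [n for n in comp if n[0] == graph.version_a]
    nodes_b = [n for n in comp if n[0] == graph.version_b]
    if len(nodes_a) != 2 or len(nodes_b) != 2:
        raise ValueError("not the two-by-two complex topology")
    deg = {n: graph.degree(n) for n in comp}
    hub_a = [n for n in nodes_a if deg[n] == 2]
    leaf_a = [n for n in nodes_a if deg[n] == 1]
    hub_b = [n for n in nodes_b if deg[n] == 2]
    leaf_b = [n for n in nodes_b if deg[n] == 1]
    if len(hub_a) != 1 or len(leaf_a) != 1 or len(hub_b) != 1 or len(leaf_b) != 1:
        raise ValueError("not the two-by-two complex topology")
    c = hub_a[0]      # older gene hit by both newer genes
    d = leaf_a[0]     # second older gene
    bb = hub_b[0]     # newer gene with the extra portion
    aa = leaf_b[0]
    if not graph.graph.has_edge(bb, c) or not graph.graph.has_edge(bb, d) \
            or not graph.graph.has_edge(aa, c):
        raise ValueError("not the two-by-two complex topology")
    # the two newer genes must sit on different regions of the shared older gene
    ivs = [graph.edge(c[1], aa[1]).interval_a, graph.edge(c[1], bb[1]).interval_a]
    if same_portion(ivs) == SAME:
        raise ValueError("newer genes hit the same portion; not the complex topology")
    na, nb_, oc, od = aa[1], bb[1], c[1], d[1]
    return [
        Resolution(
            kind="no_change",
            description=f"keep {na} and {nb_} separated as predicted",
            deciding_evidence=(
                f"distinct proteins each covering {na} and {nb_} in full"
            ),
        ),
        Resolution(
            kind="transfer_portion",
            description=(
                f"transfer the portion of {nb_} matching {oc} to {na}; "
                f"the remainder of {nb_} stays with {od}"
            ),
            deciding_evidence=(
                f"one protein spanning {na} plus the {oc}-matching portion of {nb_}, "
                f"and a second protein covering the {od}-matching remainder"
            ),
        ),
        Resolution(
            kind="merge",
            description=f"merge {na} and {nb_} into a single gene",
            deciding_evidence=f"a single protein spanning {na} and {nb_} together",
        ),
    ]
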