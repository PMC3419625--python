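"""End-to-end reconciliation of two gene prediction versions.

Glues the pieces together: bidirectional alignment (internal aligner unless
external tabular hits are supplied), stringency filtering, match-graph
construction, cardinality classification with protein evidence, split
proposals, and positional analysis of the one-to-one pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .aligner import KmerIndex, align_sets
from .cardinality import (
    ClassifyPolicy,
    MatchGraph,
    ProteinEvidence,
    build_graph,
    classify,
    propose_splits,
)
from .matching import FilterPolicy, filter_hits
from .models import LOW_SCORE, OK, REPEAT, ChromNaming, DEFAULT_NAMING
from .positions import (
    categorize_pairs,
    detect_inversion_runs,
    detect_modifications,
    normalize_positions,
)
from .synthetic import EvidenceSet


@dataclass
class ReconcileResult:
    graph: MatchGraph
    calls: list
    proposals: list
    split_summary: dict
    pairs: list
    positions: list
    category_counts: dict
    modifications: dict
    inversion_runs: list
    hits_ab: list
    hits_ba: list

    def calls_by_gene(self, version_label: str) -> dict:
        return {c.gene_id: c for c in self.calls if c.version_label == version_label}


def reconcile_pair(
    genes_a: Sequence,
    genes_b: Sequence,
    seqs_a: Optional[dict] = None,
    seqs_b: Optional[dict] = None,
    evidence: Optional[object] = None,
    hits_ab: Optional[list] = None,
    hits_ba: Optional[list] = None,
    protein_hits: Optional[list] = None,
    filter_policy: FilterPolicy = FilterPolicy(),
    classify_policy: ClassifyPolicy = ClassifyPolicy(),
    include_repeat: bool = False,
    min_run: int = 3,
    naming: ChromNaming = DEFAULT_NAMING,
) -> ReconcileResult:
    """Run the full reconciliation.

    ``evidence`` may be an :class:`EvidenceSet` (protein sequences, aligned
    internally against both versions' genes) or a prebuilt
    :class:`ProteinEvidence`.  When external ``hits_ab``/``hits_ba`` are
    given they win over the internal aligner.
    """
    genes_a, genes_b = list(genes_a), list(genes_b)

    def _eligible(genes, seqs):
        if seqs is None:
            return None
        keep = {g.sequence_key or g.gene_id for g in genes
                if include_repeat or g.track != REPEAT}
        return {k: v for k, v in seqs.items() if k in keep}

    index_a = index_b = None
    if hits_ab is None or hits_ba is None:
        if seqs_a is None or seqs_b is None:
            raise ValueError("either external hits or both sequence sets are required")
        index_a = KmerIndex(_eligible(genes_a, seqs_a))
        index_b = KmerIndex(_eligible(genes_b, seqs_b))
        if hits_ab is None:
            hits_ab = align_sets(_eligible(genes_a, seqs_a), index_b)
        if hits_ba is None:
            hits_ba = align_sets(_eligible(genes_b, seqs_b), index_a)

    hits_ab = filter_hits(hits_ab, filter_policy)
    hits_ba = filter_hits(hits_ba, filter_policy)
    graph = build_graph(hits_ab, hits_ba, genes_a, genes_b,
                        include_repeat=include_repeat)

    pe = None
    if isinstance(evidence, ProteinEvidence):
        pe = evidence
    elif isinstance(evidence, EvidenceSet) and evidence.sequences:
        if protein_hits is None:
            if index_a is None or index_b is None:
                if seqs_a is None or seqs_b is None:
                    raise ValueError(
                        "protein evidence needs gene sequences or precomputed "
                        "protein hits"
                    )
                index_a = KmerIndex(_eligible(genes_a, seqs_a))
                index_b = KmerIndex(_eligible(genes_b, seqs_b))
            protein_hits = align_sets(evidence.sequences, index_a)
            protein_hits += align_sets(evidence.sequences, index_b)
        protein_hits = filter_hits(protein_hits, filter_policy)
        pe = ProteinEvidence.from_hits(
            protein_hits, evidence.lengths, flags=evidence.protein_level,
        )

    calls = classify(graph, genes_a, genes_b, evidence=pe, policy=classify_policy)
    proposals, split_summary = propose_splits(calls)

    # one-to-one pairs (clean and low-score alike) feed the position analysis
    pairs = sorted(
        (c.partners[0], c.gene_id)
        for c in calls
        if c.version_label == graph.version_b and c.call in (OK, LOW_SCORE)
    )
    positions = normalize_positions(pairs, genes_a, genes_b)
    category_counts, positions = categorize_pairs(positions)
    modifications = detect_modifications(positions, naming=naming)
    runs = detect_inversion_runs(positions, min_run=min_run)

    return ReconcileResult(
        graph=graph,
        calls=calls,
        proposals=proposals,
        split_summary=split_summary,
        pairs=pairs,
        positions=positions,
        category_counts=dict(category_counts),
        modifications=modifications,
        inversion_runs=runs,
        hits_ab=hits_ab,
        hits_ba=hits_ba,
    )
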