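"""Stringency filtering of cross-version hits and neighbor-order validation.

The comparison between two gene prediction sets keeps only high-confidence
hits: identity strictly above 95%, e-value strictly below 1e-20, and at most
the four best matches per query.  In transcript (EST) mode an additional
100 bp minimum alignment length compensates for the absence of neighbor-gene
context.  Putative one-to-one identities are then validated by gene-order
consistency: at least two consecutively positioned genes in the newer
version must hit two consecutive genes in the older version, since absolute
chromosome coordinates cannot be trusted across assemblies.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .models import GeneModel, MatchHit

GENOMIC = "genomic"
EST = "est"

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
UNTESTABLE = "untestable"


@dataclass(frozen=True)
class FilterPolicy:
    """Hit-retention thresholds.  Both inequalities are strict: a hit at
    exactly 95.0% identity or exactly 1e-20 is rejected."""

    min_identity: float = 95.0
    max_evalue: float = 1e-20
    top_k: int = 4
    mode: str = GENOMIC
    min_aln_length_est: int = 100

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not (0.0 <= self.min_identity <= 100.0):
            raise ValueError("min_identity must be a percentage")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be >= 0")
        if self.mode not in (GENOMIC, EST):
            raise ValueError(f"mode must be {GENOMIC!r} or {EST!r}")


@dataclass(frozen=True)
class NeighborRule:
    """Parameters of the gene-order consistency check.

    ``min_consecutive_pairs`` includes the pair under test (2 means the pair
    plus one adjacent pair).  ``max_skip`` intervening genes without a
    one-to-one partner are tolerated when judging adjacency, so new or
    dropped genes do not break every neighborhood.
    """

    window: int = 1
    min_consecutive_pairs: int = 2
    max_skip: int = 1

    def __post_init__(self) -> None:
        if self.min_consecutive_pairs < 2:
            raise ValueError("min_consecutive_pairs must be >= 2")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.max_skip < 0:
            raise ValueError("max_skip must be >= 0")


def filter_hits(hits: Sequence[MatchHit], policy: FilterPolicy = FilterPolicy()) -> list[MatchHit]:
    """Apply the stringency filters and per-query top-k truncation.

    Retained hits satisfy ``pct_identity > min_identity`` and
    ``e_value < max_evalue`` (strict), plus the EST length floor when
    ``mode="est"``.  Per query only the ``top_k`` best hits by descending bit
    score survive; bit-score ties break by higher identity, longer alignment,
    then lexicographic subject id.  Hit records are never mutated; the
    operation is idempotent and its output is a subset of its input.
    """
    per_query: dict[str, list[MatchHit]] = defaultdict(list)
    query_order: list[str] = []
    for h in hits:
        if h.pct_identity <= policy.min_identity:
            continue
        if h.e_value >= policy.max_evalue:
            continue
        if policy.mode == EST and h.aln_length < policy.min_aln_length_est:
            continue
        if h.query_id not in per_query:
            query_order.append(h.query_id)
        per_query[h.query_id].append(h)
    out: list[MatchHit] = []
    for q in query_order:
        ranked = sorted(
            per_query[q],
            key=lambda h: (-h.bit_score, -h.pct_identity, -h.aln_length, h.subject_id),
        )
        out.extend(ranked[: policy.top_k])
    return out


# --------------------------------------------------------------------------
# Neighbor consistency


def _order_maps(genes: Iterable[GeneModel]):
    """Per-chromosome gene order: {chrom: [ids]} plus {id: (chrom, rank)}."""
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chromosome].append(g)
    order: dict[str, list[str]] = {}
    rank: dict[str, tuple[str, int]] = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.start, g.end, g.gene_id))
        ids = [g.gene_id for g in gs]
        order[chrom] = ids
        for i, gid in enumerate(ids):
            rank[gid] = (chrom, i)
    return order, rank


def _nearest_paired(ids: list[str], i: int, step: int, paired: set, max_skip: int):
    """Nearest gene with a partner in direction ``step``, skipping at most
    ``max_skip`` partnerless genes.  Returns its id or None."""
    skipped = 0
    j = i + step
    while 0 <= j < len(ids):
        if ids[j] in paired:
            return ids[j]
        skipped += 1
        if skipped > max_skip:
            return None
        j += step
    return None


def _adjacent(rank_map, order, x: str, y: str, paired: set, max_skip: int) -> bool:
    """True when x and y are consecutive on one chromosome, tolerating up to
    ``max_skip`` intervening partnerless genes."""
    cx, ix = rank_map[x]
    cy, iy = rank_map[y]
    if cx != cy or ix == iy:
        return False
    lo, hi = sorted((ix, iy))
    between = order[cx][lo + 1:hi]
    return all(g not in paired for g in between) and len(between) <= max_skip


def neighbor_consistency(
    pairs: Sequence[tuple[str, str]],
    genes_a: Iterable[GeneModel],
    genes_b: Iterable[GeneModel],
    rule: NeighborRule = NeighborRule(),
) -> dict[tuple[str, str], str]:
    """Annotate candidate one-to-one pairs by gene-order consistency.

    A pair ``(a, b)`` is *consistent* when it and at least one adjacent pair
    (the nearest paired predecessor or successor of ``b`` in the newer
    version's order) map to adjacent genes in the older version's order.
    Pairs whose gene sits alone on its scaffold in either version are
    *untestable*, not inconsistent; so are pairs with no reachable paired
    neighbor.  Everything else failing the adjacency check is *inconsistent*.
    """
    order_a, rank_a = _order_maps(genes_a)
    order_b, rank_b = _order_maps(genes_b)
    partner_a = {b: a for a, b in pairs}
    paired_a = {a for a, _ in pairs}
    paired_b = set(partner_a)
    out: dict[tuple[str, str], str] = {}
    for a, b in pairs:
        ca, ia = rank_a[a]
        cb, ib = rank_b[b]
        if len(order_a[ca]) == 1 or len(order_b[cb]) == 1:
            out[(a, b)] = UNTESTABLE
            continue
        found_neighbor = False
        consistent = False
        for step in (-1, 1):
            nb = _nearest_paired(order_b[cb], ib, step, paired_b, rule.max_skip)
            if nb is None:
                continue
            found_neighbor = True
            na = partner_a[nb]
            if _adjacent(rank_a, order_a, a, na, paired_a, rule.max_skip):
                consistent = True
                break
        if consistent:
            out[(a, b)] = CONSISTENT
        elif not found_neighbor:
            out[(a, b)] = UNTESTABLE
        else:
            out[(a, b)] = INCONSISTENT
    return out
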