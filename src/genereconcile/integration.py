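"""Unified gene set construction, annotation transfer and categorization.

The non-redundant total gene set is seeded with the highest-priority
prediction and complemented with genes from each successive source that were
not identified in a higher-priority one.  Unique IDs follow the priority
order of the sources.  Prior functional annotation is transferred across
clean one-to-one pairs; any gene with a cardinality issue is flagged for
independent re-review.  Genes are also classified into four broad groups by
their best cross-species hit, and counted within a hierarchical functional
category catalog.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Optional, Sequence

import networkx as nx

from .models import (
    MAIN,
    OK,
    OK_SPLIT,
    UNMATCHED,
    CALL_TO_COMMENT,
    CategoryNode,
    CardinalityCall,
    CorrespondenceRecord,
    GeneModel,
    SourcePriority,
)

#: best-hit descriptions matching any of these mark a transposon/viral gene
DEFAULT_TE_KEYWORDS = (
    "transposon", "retrotransposon", "transposase", "gag", "pol ",
    "polyprotein", "integrase", "reverse transcriptase", "viral", "virus",
)

#: best-hit descriptions matching these mark a gene of unknown function
UNKNOWN_KEYWORDS = ("unknown", "uncharacterized", "uncharacterised", "hypothetical")


def unify(
    gene_sets: Mapping[str, Sequence],
    cross_matches: Sequence[tuple[str, str, str, str]],
    priority: SourcePriority,
) -> list[CorrespondenceRecord]:
    """Build one correspondence record per equivalence group of genes.

    ``gene_sets`` maps each source label to its genes (GeneModel or bare
    ids); ``cross_matches`` lists ``(source1, id1, source2, id2)`` identities
    between sources.  Groups are connected components over the matches;
    every group's unique id comes from its highest-priority member.  Records
    are ordered by the priority of their top source, then by input order, so
    the top-priority prediction seeds the set and unmatched genes of each
    successive source are appended as new records.  The grouping must
    partition the input: a gene in two groups is impossible by construction,
    but matches naming unknown genes are rejected.
    """
    for src in gene_sets:
        priority.rank(src)  # unknown source -> ValueError
    ids: dict[str, list[str]] = {}
    gene_by_key: dict[tuple[str, str], object] = {}
    for src, genes in gene_sets.items():
        ids[src] = []
        for g in genes:
            gid = g.gene_id if isinstance(g, GeneModel) else str(g)
            if (src, gid) in gene_by_key:
                raise ValueError(f"duplicate gene {gid!r} in source {src!r}")
            gene_by_key[(src, gid)] = g
            ids[src].append(gid)

    g = nx.Graph()
    g.add_nodes_from(gene_by_key)
    for s1, i1, s2, i2 in cross_matches:
        for s, i in ((s1, i1), (s2, i2)):
            if (s, i) not in gene_by_key:
                raise ValueError(f"cross-match references unknown gene {i!r} in {s!r}")
        g.add_edge((s1, i1), (s2, i2))

    order_index = {}
    for src in priority.sources:
        for n, gid in enumerate(ids.get(src, [])):
            order_index[(src, gid)] = n

    records = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda n: (priority.rank(n[0]), order_index[n]))
        top_src, top_id = members[0]
        by_source: dict[str, str] = {}
        positions: dict[str, str] = {}
        track = MAIN
        for src, gid in members:
            by_source[src] = f"{by_source[src]},{gid}" if src in by_source else gid
            gene = gene_by_key[(src, gid)]
            if isinstance(gene, GeneModel):
                positions.setdefault(src, f"{gene.chromosome}_{gene.start}_{gene.end}")
                if src == top_src and gid == top_id:
                    track = gene.track
        records.append(
            CorrespondenceRecord(
                unique_id=top_id,
                source_rank=priority.rank(top_src),
                ids_by_source=by_source,
                positions_by_source=positions,
                track=track,
            )
        )
    records.sort(key=lambda r: (r.source_rank,
                                order_index[(priority.sources[r.source_rank - 1],
                                             r.unique_id.split(",")[0])]))
    return records


def venn_membership(records: Sequence[CorrespondenceRecord]) -> dict[frozenset, int]:
    """Count records per source-membership signature (the Venn regions)."""
    counts: Counter = Counter()
    for r in records:
        counts[frozenset(r.ids_by_source)] += 1
    return dict(counts)


def transfer_annotation(
    records: Sequence[CorrespondenceRecord],
    prior_annotations: Mapping[str, str],
    calls: Sequence[CardinalityCall],
    annotation_source: Optional[str] = None,
) -> list[CorrespondenceRecord]:
    """Transfer prior (older-version) annotation across the correspondence.

    Genes in a clean one-to-one relationship inherit the prior annotation
    outright.  Genes with any cardinality issue keep a provisional copy but
    are flagged for independent functional re-review, as are genes with no
    counterpart (and hence no annotation to inherit).
    """
    call_by_gene = {(c.version_label, c.gene_id): c for c in calls}
    for r in records:
        # the prior annotation is keyed by the annotation-source gene id
        prior = ""
        for src, gid in r.ids_by_source.items():
            if annotation_source is not None and src != annotation_source:
                continue
            for one in gid.split(","):
                if one in prior_annotations:
                    prior = prior_annotations[one]
                    break
            if prior:
                break
        call = None
        for src, gid in r.ids_by_source.items():
            for one in gid.split(","):
                c = call_by_gene.get((src, one))
                # a single issue call anywhere in the group taints the record
                if c is not None and (call is None or c.call not in (OK, OK_SPLIT)):
                    call = c
        r.annotation = prior  # provisional unless the pair is clean
        if call is not None and call.call in (OK, OK_SPLIT):
            r.needs_review = False
            r.cardinality_comment = CALL_TO_COMMENT[call.call]
        else:
            r.needs_review = True
            if call is not None:
                r.cardinality_comment = CALL_TO_COMMENT[call.call]
            elif not r.cardinality_comment:
                r.cardinality_comment = CALL_TO_COMMENT[UNMATCHED]
    return list(records)


def assign_four_group(
    records: Sequence[CorrespondenceRecord],
    best_hits: Mapping[str, Optional[str]],
    te_keywords: Sequence[str] = DEFAULT_TE_KEYWORDS,
) -> list[CorrespondenceRecord]:
    """Classify each record by its best cross-species hit description.

    No hit → ``no_hit``; hit matching a transposon/viral keyword →
    ``viral_te``; hit flagged unknown/uncharacterized → ``unknown_function``;
    anything else → ``known_function``.  Groups are mutually exclusive and
    exhaustive on any input.
    """
    te = tuple(k.lower() for k in te_keywords)
    for r in records:
        desc = best_hits.get(r.unique_id)
        if desc is None:
            r.four_group = "no_hit"
            continue
        low = desc.lower()
        if any(k in low for k in te):
            r.four_group = "viral_te"
        elif any(k in low for k in UNKNOWN_KEYWORDS):
            r.four_group = "unknown_function"
        else:
            r.four_group = "known_function"
    return list(records)


def catalog_rollup(
    records: Sequence[CorrespondenceRecord],
    catalog: Mapping[str, CategoryNode],
) -> dict:
    """Aggregate category membership up the hierarchy.

    Each gene counts once per distinct ancestor category at every level (a
    gene with two categories under one root counts once at that root).
    Unknown category codes are rejected.  Returns per-category counts, the
    per-level totals, and the number of genes present in two or more
    distinct categories.
    """
    per_category: Counter = Counter()
    multi = 0
    total_root_memberships = 0
    for r in records:
        distinct = set(r.categories)
        if len(distinct) >= 2:
            multi += 1
        ancestors: set[str] = set()
        for code in distinct:
            node = catalog.get(code)
            if node is None:
                raise ValueError(
                    f"{r.unique_id}: category code {code!r} absent from catalog"
                )
            while node is not None:
                ancestors.add(node.code)
                node = catalog.get(node.parent_code) if node.parent_code else None
        for code in ancestors:
            per_category[code] += 1
        total_root_memberships += sum(
            1 for code in ancestors if catalog[code].level == 1
        )
    per_level: Counter = Counter()
    for code, n in per_category.items():
        per_level[catalog[code].level] += n
    return {
        "per_category": dict(per_category),
        "per_level": dict(per_level),
        "multi_membership": multi,
        "root_memberships": total_root_memberships,
    }
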