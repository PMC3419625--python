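"""Cross-version comparison of matched gene pairs' chromosomal positions.

Because chromosome sequences are heavily revised between assemblies,
absolute coordinates are not comparable; positions are normalized to the
percentage of each chromosome's length (gene midpoint / chromosome length).
Matched pairs fall into three categories — same chromosome in both versions,
unknown chromosome involved, or different/random chromosomes — and the
per-pair *modification* labels capture the assembly improvements: genes
newly placed from the unknown chromosome or from a random chromosome,
chromosome reassignments, and members of inverted blocks detected as
gene-order runs.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import spearmanr

from .models import (
    DIFFERENT_OR_RANDOM,
    MOD_FROM_RANDOM,
    MOD_FROM_UNKNOWN,
    MOD_INVERTED,
    MOD_NONE,
    MOD_REASSIGNED,
    PLACED,
    RANDOM,
    SAME_CHROM,
    UNKNOWN,
    UNKNOWN_INVOLVED,
    ChromNaming,
    DEFAULT_NAMING,
    GeneModel,
    GenePairPosition,
    InversionRun,
)


def chromosome_lengths(genes: Iterable[GeneModel]) -> dict[str, int]:
    """Infer chromosome lengths as the maximum gene end per chromosome."""
    lengths: dict[str, int] = {}
    for g in genes:
        lengths[g.chromosome] = max(lengths.get(g.chromosome, 0), g.end)
    return lengths


def normalize_positions(
    pairs: Sequence[tuple[str, str]],
    genes_a: Iterable[GeneModel],
    genes_b: Iterable[GeneModel],
    lengths_a: Optional[Mapping[str, int]] = None,
    lengths_b: Optional[Mapping[str, int]] = None,
) -> list[GenePairPosition]:
    """Midpoint-based percent positions for matched (id_a, id_b) pairs."""
    by_a = {g.gene_id: g for g in genes_a}
    by_b = {g.gene_id: g for g in genes_b}
    lengths_a = dict(lengths_a) if lengths_a else chromosome_lengths(by_a.values())
    lengths_b = dict(lengths_b) if lengths_b else chromosome_lengths(by_b.values())
    for name, lens in (("A", lengths_a), ("B", lengths_b)):
        for chrom, ln in lens.items():
            if ln <= 0:
                raise ValueError(f"version {name}: zero-length chromosome {chrom!r}")
    out = []
    for ida, idb in pairs:
        ga, gb = by_a[ida], by_b[idb]
        out.append(
            GenePairPosition(
                id_a=ida,
                id_b=idb,
                chrom_a=ga.chromosome,
                chrom_b=gb.chromosome,
                pos_a_pct=100.0 * ga.midpoint / lengths_a[ga.chromosome],
                pos_b_pct=100.0 * gb.midpoint / lengths_b[gb.chromosome],
                placement_a=ga.placement,
                placement_b=gb.placement,
            )
        )
    return out


def categorize_pairs(
    positions: Sequence[GenePairPosition],
) -> tuple[Counter, list[GenePairPosition]]:
    """Assign each pair exactly one category; unknown takes precedence.

    ``same_chrom`` requires both genes placed on the same chromosome;
    ``unknown_involved`` fires when either side sits on the unknown
    chromosome; everything else (different chromosomes, or a random
    pseudo-chromosome on either side) is ``different_or_random``.
    """
    counts: Counter = Counter()
    for p in positions:
        if UNKNOWN in (p.placement_a, p.placement_b):
            p.pair_category = UNKNOWN_INVOLVED
        elif (p.placement_a == PLACED and p.placement_b == PLACED
              and p.chrom_a == p.chrom_b):
            p.pair_category = SAME_CHROM
        else:
            p.pair_category = DIFFERENT_OR_RANDOM
        counts[p.pair_category] += 1
    return counts, list(positions)


def detect_modifications(
    positions: Sequence[GenePairPosition],
    naming: ChromNaming = DEFAULT_NAMING,
) -> dict:
    """Label assembly-improvement modification types per pair.

    With version A as the older assembly: unknown→placed pairs are newly
    placed from the unknown chromosome; random→placed pairs on the same base
    chromosome are newly positioned within their chromosome; pairs placed on
    different chromosomes (including random→other-chromosome flows) changed
    chromosomal assignment.  Returns per-type counts and the reassignment
    flows (chrom_A → chrom_B).
    """
    counts: Counter = Counter()
    flows: Counter = Counter()
    for p in positions:
        mod = MOD_NONE
        if p.placement_a == UNKNOWN and p.placement_b == PLACED:
            mod = MOD_FROM_UNKNOWN
        elif p.placement_a == RANDOM and p.placement_b == PLACED:
            if naming.base_chromosome(p.chrom_a) == p.chrom_b:
                mod = MOD_FROM_RANDOM
            else:
                mod = MOD_REASSIGNED
        elif (p.placement_a == PLACED and p.placement_b == PLACED
              and p.chrom_a != p.chrom_b):
            mod = MOD_REASSIGNED
        if p.modification != MOD_INVERTED:  # inversion labels are kept
            p.modification = mod
        if mod != MOD_NONE:
            counts[mod] += 1
        if mod == MOD_REASSIGNED:
            flows[(p.chrom_a, p.chrom_b)] += 1
    return {"counts": dict(counts), "flows": dict(flows)}


def detect_inversion_runs(
    positions: Sequence[GenePairPosition],
    min_run: int = 3,
) -> list[InversionRun]:
    """Detect inverted assembly blocks from gene-order runs.

    Same-chromosome pairs are sorted by position in the newer version; a
    maximal contiguous run of at least ``min_run`` pairs whose older-version
    order is strictly decreasing is an inversion.  Pairs without a match do
    not exist in the list, so unmatched genes never break contiguity.
    Globally reversing both versions' orders leaves the output empty — a
    reversed coordinate system is not an inversion.
    """
    by_chrom: dict[str, list[GenePairPosition]] = defaultdict(list)
    for p in positions:
        if p.pair_category == SAME_CHROM:
            by_chrom[p.chrom_b].append(p)
    runs: list[InversionRun] = []
    for chrom in sorted(by_chrom):
        ps = sorted(by_chrom[chrom], key=lambda p: (p.pos_b_pct, p.id_b))
        i = 0
        while i < len(ps) - 1:
            if ps[i + 1].pos_a_pct < ps[i].pos_a_pct:
                j = i + 1
                while j < len(ps) - 1 and ps[j + 1].pos_a_pct < ps[j].pos_a_pct:
                    j += 1
                if j - i + 1 >= min_run:
                    members = ps[i:j + 1]
                    xs = [p.pos_b_pct for p in members]
                    ys = [p.pos_a_pct for p in members]
                    rho = spearmanr(xs, ys).statistic
                    run = InversionRun(
                        chromosome=chrom,
                        member_pairs=[(p.id_a, p.id_b) for p in members],
                        orientation_score=float(rho),
                    )
                    runs.append(run)
                    for p in members:
                        p.modification = MOD_INVERTED
                i = j
            else:
                i += 1
    return runs


# --------------------------------------------------------------------------
# Optional plot (display conventions only; never used in computation)


def plot_positions(positions: Sequence[GenePairPosition], path,
                   naming: ChromNaming = DEFAULT_NAMING) -> None:
    """Scatter the matched pairs' percent positions, one panel per category.

    Random chromosomes are drawn at one tenth of a regular chromosome's
    visual scale and the unknown chromosome magnified 20-fold, mirroring the
    conventional display; the stored percentages are untouched.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4.2), sharex=True, sharey=True)
    panels = {SAME_CHROM: axes[0], UNKNOWN_INVOLVED: axes[1],
              DIFFERENT_OR_RANDOM: axes[2]}
    titles = {SAME_CHROM: "same chromosome",
              UNKNOWN_INVOLVED: "unknown chromosome involved",
              DIFFERENT_OR_RANDOM: "different / random chromosome"}

    def _scale(p, chrom, placement, pct):
        if placement == RANDOM:
            return pct / 10.0
        if placement == UNKNOWN:
            return min(100.0, pct * 20.0)
        return pct

    chroms = sorted({p.chrom_b for p in positions})
    cmap = plt.get_cmap("tab20")
    color = {c: cmap(i % 20) for i, c in enumerate(chroms)}
    for p in positions:
        ax = panels.get(p.pair_category)
        if ax is None:
            continue
        x = _scale(p, p.chrom_b, p.placement_b, p.pos_b_pct)
        y = _scale(p, p.chrom_a, p.placement_a, p.pos_a_pct)
        marker = "*" if p.modification == MOD_INVERTED else "o"
        ax.plot(x, y, marker, ms=3, color=color.get(p.chrom_b, "grey"), alpha=0.6)
    for cat, ax in panels.items():
        ax.set_title(titles[cat])
        ax.set_xlabel("newer version position (% chromosome)")
    axes[0].set_ylabel("older version position (% chromosome)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
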