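"""Core domain types shared across the reconciliation pipeline.

Two gene prediction sets ("versions", conventionally the older version *A*
and the newer version *B*) are compared by nucleotide homology.  Everything
downstream — match filtering, the bipartite match graph, cardinality calls,
positional analysis and the unified correspondence table — is expressed in
terms of the types defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

# --- placement and track vocabularies -------------------------------------

PLACED = "placed"
RANDOM = "random"
UNKNOWN = "unknown"
PLACEMENTS = frozenset({PLACED, RANDOM, UNKNOWN})

MAIN = "main"
REPEAT = "repeat"
TRACKS = frozenset({MAIN, REPEAT})

# --- cardinality call vocabulary -------------------------------------------

OK = "OK"
OK_SPLIT = "OK_split"
REDUNDANT = "redundant"
OVERLAP = "overlap"
SPLIT = "split"
MERGED = "merged"
TO_SPLIT = "to_split"
MULTIPLE = "multiple"
LOW_SCORE = "low_score"
UNMATCHED = "unmatched"
UNRESOLVED = "unresolved_ambiguous"

CALLS = frozenset(
    {OK, OK_SPLIT, REDUNDANT, OVERLAP, SPLIT, MERGED, TO_SPLIT, MULTIPLE,
     LOW_SCORE, UNMATCHED, UNRESOLVED}
)

#: Human-readable comment strings used in the correspondence table.  "OK"
#: marks a clean one-to-one pair, "XX" no match at all, "Ls" a correct-looking
#: pair whose alignment score is suspiciously low, "OK (Split)" a newer-set
#: gene whose older-set partner was an incorrect merging.
CALL_TO_COMMENT = {
    OK: "OK",
    OK_SPLIT: "OK (Split)",
    REDUNDANT: "redundant",
    OVERLAP: "Overlap",
    SPLIT: "Split",
    MERGED: "merge",
    TO_SPLIT: "To split",
    MULTIPLE: "multiple",
    LOW_SCORE: "Ls",
    UNMATCHED: "XX",
    UNRESOLVED: "unresolved",
}
COMMENT_TO_CALL = {v: k for k, v in CALL_TO_COMMENT.items()}

# --- evidence vocabulary ----------------------------------------------------

EVID_SINGLE = "protein-single"
EVID_MULTIPLE = "protein-multiple"
EVID_NONE = "none"


@dataclass(frozen=True)
class ChromNaming:
    """Conventions for recognising special chromosome labels.

    ``unknown_label`` is the artificial concatenation of unassignable
    scaffolds; chromosomes whose name ends with ``random_suffix`` hold
    scaffolds assigned to a chromosome but not positioned within it.
    """

    unknown_label: str = "chrUn"
    random_suffix: str = "_random"

    def placement_of(self, chromosome: str) -> str:
        if chromosome == self.unknown_label:
            return UNKNOWN
        if chromosome.endswith(self.random_suffix):
            return RANDOM
        return PLACED

    def base_chromosome(self, chromosome: str) -> str:
        """Chromosome name with any random suffix stripped."""
        if chromosome.endswith(self.random_suffix):
            return chromosome[: -len(self.random_suffix)]
        return chromosome


DEFAULT_NAMING = ChromNaming()


@dataclass
class GeneModel:
    """One predicted gene in one assembly version.

    Coordinates are 1-based inclusive.  ``placement`` mirrors the chromosome
    label under a :class:`ChromNaming` convention; ``track`` distinguishes the
    main annotation track from the speculative repeat track.
    """

    gene_id: str
    version_label: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    placement: str = PLACED
    track: str = MAIN
    sequence_key: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"{self.gene_id}: bad placement {self.placement!r}")
        if self.track not in TRACKS:
            raise ValueError(f"{self.gene_id}: bad track {self.track!r}")

    @classmethod
    def with_naming(
        cls,
        gene_id: str,
        version_label: str,
        chromosome: str,
        start: int,
        end: int,
        strand: str = "+",
        track: str = MAIN,
        sequence_key: Optional[str] = None,
        naming: ChromNaming = DEFAULT_NAMING,
    ) -> "GeneModel":
        """Build a gene model with placement derived from the chromosome name."""
        return cls(
            gene_id=gene_id,
            version_label=version_label,
            chromosome=chromosome,
            start=start,
            end=end,
            strand=strand,
            placement=naming.placement_of(chromosome),
            track=track,
            sequence_key=sequence_key if sequence_key is not None else gene_id,
        )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MatchHit:
    """One pairwise alignment record (12-column BLAST tabular dialect).

    ``s_start > s_end`` is permitted and encodes a minus-strand alignment;
    query coordinates are always ascending.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1, got {self.aln_length}")
        if self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")
        if self.q_start > self.q_end:
            raise ValueError("q_start > q_end is not a valid query interval")

    @property
    def is_minus(self) -> bool:
        return self.s_start > self.s_end

    @property
    def q_interval(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def s_interval(self) -> tuple[int, int]:
        """Subject interval with ascending coordinates regardless of strand."""
        return (min(self.s_start, self.s_end), max(self.s_start, self.s_end))


@dataclass(frozen=True)
class CategoryNode:
    """One node of the hierarchical functional-category catalog.

    Codes are dotted numeric strings ("1", "1.2", "1.2.3", ...); a node's
    level is 1 + its parent's level, roots sit at level 1.  GO and MIPS funcat
    cross-references are optional.
    """

    code: str
    name: str
    level: int
    go_id: Optional[str] = None
    mips_code: Optional[str] = None
    parent_code: Optional[str] = None

    def __post_init__(self) -> None:
        if self.level < 1 or self.level > 8:
            raise ValueError(f"category {self.code}: level must be 1..8, got {self.level}")
        if self.level == 1 and self.parent_code is not None:
            raise ValueError(f"category {self.code}: root nodes have no parent")
        if self.level > 1 and self.parent_code is None:
            raise ValueError(f"category {self.code}: non-root node needs a parent")


@dataclass
class SplitProposal:
    """Proposed decomposition of a chimeric gene into its evidenced parts."""

    source_gene: str
    parts: list  # ordered list of ((start, end), protein_id)
    new_ids: list

    @property
    def k(self) -> int:
        return len(self.parts)

    @property
    def n_new(self) -> int:
        return len(self.new_ids)


@dataclass
class CardinalityCall:
    """A gene's classification in the cross-version cardinality taxonomy."""

    gene_id: str
    version_label: str
    call: str
    degree: int = 0
    partners: list = field(default_factory=list)
    evidence: str = EVID_NONE
    proposed_actions: list = field(default_factory=list)
    #: protein-supported part intervals on this gene, for to_split calls:
    #: list of ((start, end), protein_id)
    parts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call label {self.call!r}")
        if self.call == OK and self.degree != 1:
            raise ValueError("OK calls require degree 1")
        if self.call == UNMATCHED and self.degree != 0:
            raise ValueError("unmatched calls require degree 0")


@dataclass(frozen=True)
class Resolution:
    """One candidate correction for a complex ('multiple situations') component."""

    kind: str  # no_change | transfer_portion | merge
    description: str
    deciding_evidence: str


@dataclass
class GenePairPosition:
    """A matched cross-version gene pair with normalized chromosome positions."""

    id_a: str
    id_b: str
    chrom_a: str
    chrom_b: str
    pos_a_pct: float
    pos_b_pct: float
    placement_a: str
    placement_b: str
    pair_category: Optional[str] = None  # same_chrom | unknown_involved | different_or_random
    modification: str = "none"

    def __post_init__(self) -> None:
        for v in (self.pos_a_pct, self.pos_b_pct):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"position percentage out of range: {v}")


SAME_CHROM = "same_chrom"
UNKNOWN_INVOLVED = "unknown_involved"
DIFFERENT_OR_RANDOM = "different_or_random"
PAIR_CATEGORIES = (SAME_CHROM, UNKNOWN_INVOLVED, DIFFERENT_OR_RANDOM)

MOD_NONE = "none"
MOD_FROM_UNKNOWN = "newly_placed_from_unknown"
MOD_FROM_RANDOM = "newly_placed_from_random"
MOD_INVERTED = "inverted_block_member"
MOD_REASSIGNED = "reassigned"


@dataclass
class InversionRun:
    """A maximal block of matched genes whose order is reversed between versions."""

    chromosome: str
    member_pairs: list  # ordered (id_a, id_b) along the newer version
    orientation_score: float = -1.0

    @property
    def length(self) -> int:
        return len(self.member_pairs)


@dataclass(frozen=True)
class SourcePriority:
    """Ordered source labels, highest priority first."""

    sources: tuple

    def __init__(self, sources: Sequence[str]):
        sources = tuple(sources)
        if not sources:
            raise ValueError("priority list must be non-empty")
        if len(set(sources)) != len(sources):
            raise ValueError("priority list contains duplicates")
        object.__setattr__(self, "sources", sources)

    def rank(self, source: str) -> int:
        """1-based rank; raises for unknown sources."""
        return self.sources.index(source) + 1


@dataclass
class CorrespondenceRecord:
    """One row of the unified correspondence table."""

    unique_id: str
    source_rank: int
    ids_by_source: dict
    positions_by_source: dict = field(default_factory=dict)
    cardinality_comment: str = ""
    track: str = MAIN
    annotation: str = ""
    categories: list = field(default_factory=list)
    needs_review: bool = False
    four_group: str = ""

    MAX_CATEGORIES = 7

    def __post_init__(self) -> None:
        if len(self.categories) > self.MAX_CATEGORIES:
            raise ValueError(
                f"{self.unique_id}: at most {self.MAX_CATEGORIES} categories per gene "
                f"(got {len(self.categories)})"
            )
        if self.track not in TRACKS:
            raise ValueError(f"{self.unique_id}: bad track {self.track!r}")


FOUR_GROUPS = ("known_function", "unknown_function", "viral_te", "no_hit")
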