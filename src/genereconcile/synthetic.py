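"""Synthetic assembly-pair generator with known ground-truth edit events.

Two gene-set "versions" are derived from a common ancestral gene complement:
version A plays the older, lower-coverage assembly and version B the newer
one.  Structural edit events are planted on disjoint ancestral genes so that
every downstream classification is scoreable against the event log:

* ``split_in_B`` — one ancestral gene emitted as two parts in B (B wrongly
  split; expected call: overlap);
* ``merge_in_B`` — one ancestral gene emitted as two parts in A and whole in
  B (B correctly merged; expected call: merged);
* ``tandem_expand_in_B`` — two adjacent copies in B, one gene in A
  (collapsed tandem repeat; expected call: redundant);
* ``chimera_in_B`` — k ∈ {2,3} adjacent ancestral genes fused into one B
  gene (artificial chimera; expected call: to_split with k parts);
* ``chimera_in_A`` — the mirror fusion in A (expected call: split);
* ``invert_block`` — a contiguous run of genes emitted in reversed order and
  orientation in B;
* ``relocate`` — a gene moved to a different chromosome in B;
* ``unplace_in_A`` — a gene sitting on the unknown chromosome in A only;
* ``drop_from_A`` / ``drop_from_B`` — a gene absent from one version.

Sequences are uppercase ACGT; divergence ``d`` applies substitutions (no
indels) to the B copy only, so cross-version identity is analytically
``100·(1−d)`` percent.  The default configuration is the package's standard
benchmark: 2 chromosomes × 250 genes, 20 events per structural class (five
of the B chimeras triple), 3 inversion blocks, 10 relocations, 30
unplacements, zero divergence and full protein-level evidence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .aligner import revcomp
from .models import ChromNaming, GeneModel, MAIN, REPEAT

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic benchmark (defaults are the
    standard conditions; see module docstring)."""

    n_chromosomes: int = 2
    genes_per_chromosome: int = 250
    split_in_B: int = 20
    merge_in_B: int = 20
    tandem_expand_in_B: int = 20
    chimera_in_B: int = 20
    chimera_in_B_triples: int = 5
    chimera_in_A: int = 20
    chimera_in_A_triples: int = 0
    invert_blocks: int = 3
    invert_block_sizes: Optional[Sequence[int]] = None  # drawn 6..14 when None
    relocate: int = 10
    unplace_in_A: int = 30
    drop_from_A: int = 0
    drop_from_B: int = 0
    repeat_track_in_B: int = 0
    divergence: float = 0.0
    evidence_rate: float = 1.0
    seed: int = 0
    min_gene_length: int = 300
    max_gene_length: int = 3000
    min_spacing: int = 200
    max_spacing: int = 2000
    min_part_length: int = 150
    naming: ChromNaming = field(default_factory=ChromNaming)

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence < 0.05):
            raise ValueError("divergence must lie in [0, 0.05)")
        if not (0.0 <= self.evidence_rate <= 1.0):
            raise ValueError("evidence_rate must lie in [0, 1]")
        if self.chimera_in_B_triples > self.chimera_in_B:
            raise ValueError("more triple chimeras than chimeras in B")
        if self.chimera_in_A_triples > self.chimera_in_A:
            raise ValueError("more triple chimeras than chimeras in A")
        if self.min_gene_length < 2 * self.min_part_length:
            raise ValueError("genes must be long enough to split in two parts")


@dataclass
class AncestralGene:
    anc_id: str
    chromosome: str
    order_index: int
    length: int
    sequence_key: str
    protein_key: str


@dataclass
class EditEvent:
    event_type: str
    anc_ids: list
    params: dict = field(default_factory=dict)


@dataclass
class EventLog:
    """Ground truth: planted events plus the ancestral→emitted id map."""

    events: list
    truth_map: dict  # anc_id -> (tuple of A ids, tuple of B ids)
    seed: int

    def events_of(self, event_type: str) -> list:
        return [e for e in self.events if e.event_type == event_type]

    def b_ids_of(self, event_type: str) -> set:
        out = set()
        for e in self.events_of(event_type):
            for anc in e.anc_ids:
                out.update(self.truth_map[anc][1])
        return out

    def a_ids_of(self, event_type: str) -> set:
        out = set()
        for e in self.events_of(event_type):
            for anc in e.anc_ids:
                out.update(self.truth_map[anc][0])
        return out


@dataclass
class EvidenceSet:
    """Cross-species protein evidence: sequences plus existence flags."""

    sequences: dict  # protein_id -> sequence
    protein_level: dict  # protein_id -> bool ("existence demonstrated at protein level")

    @property
    def lengths(self) -> dict:
        return {pid: len(s) for pid, s in self.sequences.items()}


@dataclass
class SimulationResult:
    genes_a: list
    genes_b: list
    seqs_a: dict
    seqs_b: dict
    proteins: EvidenceSet
    log: EventLog
    config: SimulationConfig


# --------------------------------------------------------------------------


def _random_seq(rng, length: int) -> str:
    return rng.choice(_ALPHABET, size=length).tobytes().decode("ascii")


def _mutate(rng, seq: str, d: float) -> str:
    """Apply substitutions at rate d (never silently to the same base)."""
    if d <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n_mut = rng.binomial(len(arr), d)
    if n_mut == 0:
        return seq
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    cur = arr[pos]
    # draw a replacement from the three other bases
    shift = rng.integers(1, 4, size=n_mut).astype(np.uint8)
    cur_idx = np.searchsorted(_ALPHABET, cur).astype(np.uint8)  # ACGT is sorted
    arr[pos] = _ALPHABET[(cur_idx + shift) % 4]
    return arr.tobytes().decode("ascii")


class _EventPlanner:
    """Pick disjoint ancestral genes / contiguous runs for the events."""

    def __init__(self, rng, per_chrom: dict):
        self.rng = rng
        self.free = {c: set(range(n)) for c, n in per_chrom.items()}
        self.per_chrom = per_chrom
        self.chroms = sorted(per_chrom)

    def take_run(self, k: int) -> tuple[str, int]:
        """A contiguous run of k free genes; returns (chromosome, start)."""
        candidates = []
        for c in self.chroms:
            free = self.free[c]
            for start in range(self.per_chrom[c] - k + 1):
                if all(start + j in free for j in range(k)):
                    candidates.append((c, start))
        if not candidates:
            raise ValueError("infeasible configuration: no free run of "
                             f"{k} genes left")
        c, start = candidates[self.rng.integers(len(candidates))]
        for j in range(k):
            self.free[c].remove(start + j)
        return c, start

    def take_single(self) -> tuple[str, int]:
        candidates = [(c, i) for c in self.chroms for i in sorted(self.free[c])]
        if not candidates:
            raise ValueError("infeasible configuration: more event genes than genes")
        c, i = candidates[self.rng.integers(len(candidates))]
        self.free[c].remove(i)
        return c, i


def make_protein_evidence(
    ancestral: Sequence[AncestralGene],
    seqs: dict,
    evidence_rate: float,
    rng,
) -> EvidenceSet:
    """Emit each ancestral gene's cognate evidence protein with probability
    ``evidence_rate`` and flag it as existence-demonstrated."""
    if not (0.0 < evidence_rate <= 1.0):
        raise ValueError("evidence_rate must lie in (0, 1]")
    sequences, flags = {}, {}
    for anc in ancestral:
        if rng.random() <= evidence_rate:
            sequences[anc.protein_key] = seqs[anc.sequence_key]
            flags[anc.protein_key] = True
    return EvidenceSet(sequences=sequences, protein_level=flags)


def simulate_pair(config: SimulationConfig = SimulationConfig()) -> SimulationResult:
    """Generate the version pair, the evidence set and the ground-truth log.

    Deterministic: identical config (including seed) gives byte-identical
    outputs.  Structural events are planted on disjoint genes; an infeasible
    configuration is rejected before any output is produced.
    """
    rng = np.random.default_rng(config.seed)
    naming = config.naming

    # --- ancestral complement
    ancestral: list[AncestralGene] = []
    seqs_anc: dict[str, str] = {}
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    for c in chrom_names:
        for i in range(config.genes_per_chromosome):
            anc_id = f"anc_{c}_{i:04d}"
            # log-uniform gene lengths
            lo, hi = np.log(config.min_gene_length), np.log(config.max_gene_length)
            length = int(np.exp(rng.uniform(lo, hi)))
            seqs_anc[anc_id] = _random_seq(rng, length)
            ancestral.append(AncestralGene(
                anc_id=anc_id, chromosome=c, order_index=i, length=length,
                sequence_key=anc_id, protein_key=f"P_{anc_id}",
            ))
    anc_by_pos = {(a.chromosome, a.order_index): a for a in ancestral}

    # --- plan events on disjoint genes
    per_chrom = {c: config.genes_per_chromosome for c in chrom_names}
    planner = _EventPlanner(rng, per_chrom)
    events: list[EditEvent] = []
    assignment: dict[str, EditEvent] = {}

    def _plant_run(event_type: str, k: int, **params):
        c, start = planner.take_run(k)
        anc_ids = [anc_by_pos[(c, start + j)].anc_id for j in range(k)]
        ev = EditEvent(event_type=event_type, anc_ids=anc_ids,
                       params={"k": k, **params})
        events.append(ev)
        for a in anc_ids:
            assignment[a] = ev
        return ev

    def _plant_single(event_type: str, **params):
        c, i = planner.take_single()
        anc_id = anc_by_pos[(c, i)].anc_id
        ev = EditEvent(event_type=event_type, anc_ids=[anc_id], params=params)
        events.append(ev)
        assignment[anc_id] = ev
        return ev

    if config.invert_block_sizes is not None:
        block_sizes = list(config.invert_block_sizes)
        if len(block_sizes) != config.invert_blocks:
            raise ValueError("invert_block_sizes length must equal invert_blocks")
    else:
        block_sizes = [int(rng.integers(6, 15)) for _ in range(config.invert_blocks)]
    for size in block_sizes:
        if size < 3:
            raise ValueError("inversion blocks need at least 3 genes")
        _plant_run("invert_block", size)
    for i in range(config.chimera_in_B):
        k = 3 if i < config.chimera_in_B_triples else 2
        _plant_run("chimera_in_B", k)
    for i in range(config.chimera_in_A):
        k = 3 if i < config.chimera_in_A_triples else 2
        _plant_run("chimera_in_A", k)
    for _ in range(config.split_in_B):
        _plant_single("split_in_B")
    for _ in range(config.merge_in_B):
        _plant_single("merge_in_B")
    for _ in range(config.tandem_expand_in_B):
        _plant_single("tandem_expand_in_B")
    for _ in range(config.relocate):
        _plant_single("relocate")
    for _ in range(config.unplace_in_A):
        _plant_single("unplace_in_A")
    for _ in range(config.drop_from_A):
        _plant_single("drop_from_A")
    for _ in range(config.drop_from_B):
        _plant_single("drop_from_B")

    # --- evidence proteins (drawn before emission so the draw order is
    # independent of the event layout)
    proteins = make_protein_evidence(ancestral, seqs_anc,
                                     config.evidence_rate or 1.0, rng) \
        if config.evidence_rate > 0 else EvidenceSet({}, {})

    # --- emit version A
    truth_a: dict[str, list] = defaultdict(list)
    truth_b: dict[str, list] = defaultdict(list)
    seqs_a: dict[str, str] = {}
    seqs_b: dict[str, str] = {}
    order_a: dict[str, list] = {c: [] for c in chrom_names}
    order_a[naming.unknown_label] = []
    counter_a = 0

    def _emit_a(chrom, seq, anc_ids, strand="+"):
        nonlocal counter_a
        counter_a += 1
        gid = f"GA{counter_a:05d}"
        seqs_a[gid] = seq
        order_a[chrom].append((gid, len(seq), strand))
        for a in anc_ids:
            truth_a[a].append(gid)
        return gid

    for c in chrom_names:
        i = 0
        while i < config.genes_per_chromosome:
            anc = anc_by_pos[(c, i)]
            ev = assignment.get(anc.anc_id)
            etype = ev.event_type if ev else None
            if etype == "chimera_in_A" and anc.anc_id == ev.anc_ids[0]:
                fused = "".join(seqs_anc[a] for a in ev.anc_ids)
                _emit_a(c, fused, ev.anc_ids)
                i += len(ev.anc_ids)
                continue
            if etype == "chimera_in_A":
                i += 1  # member already emitted with the fusion
                continue
            if etype == "merge_in_B":
                # A carries the gene incorrectly split in two
                seq = seqs_anc[anc.anc_id]
                bp = int(rng.integers(config.min_part_length,
                                      len(seq) - config.min_part_length + 1))
                ev.params["breakpoint_a"] = bp
                _emit_a(c, seq[:bp], [anc.anc_id])
                _emit_a(c, seq[bp:], [anc.anc_id])
            elif etype == "unplace_in_A":
                gid = _emit_a(naming.unknown_label, seqs_anc[anc.anc_id],
                              [anc.anc_id])
                ev.params["a_gene"] = gid
            elif etype == "drop_from_A":
                pass
            else:
                _emit_a(c, seqs_anc[anc.anc_id], [anc.anc_id])
            i += 1
    # scramble the unknown-chromosome scaffold order
    if order_a[naming.unknown_label]:
        perm = rng.permutation(len(order_a[naming.unknown_label]))
        order_a[naming.unknown_label] = [order_a[naming.unknown_label][j] for j in perm]

    # --- emit version B
    order_b: dict[str, list] = {c: [] for c in chrom_names}
    counter_b = 0
    relocated: list[tuple[str, str]] = []  # (gene_id, source chromosome)

    def _emit_b(chrom, seq, anc_ids, strand="+", defer=False):
        nonlocal counter_b
        counter_b += 1
        gid = f"GB{counter_b:05d}"
        seqs_b[gid] = _mutate(rng, seq, config.divergence)
        if not defer:
            order_b[chrom].append((gid, len(seq), strand))
        for a in anc_ids:
            truth_b[a].append(gid)
        return gid

    for c in chrom_names:
        i = 0
        while i < config.genes_per_chromosome:
            anc = anc_by_pos[(c, i)]
            ev = assignment.get(anc.anc_id)
            etype = ev.event_type if ev else None
            if etype == "invert_block" and anc.anc_id == ev.anc_ids[0]:
                for a in reversed(ev.anc_ids):
                    _emit_b(c, revcomp(seqs_anc[a]), [a], strand="-")
                i += len(ev.anc_ids)
                continue
            if etype == "chimera_in_B" and anc.anc_id == ev.anc_ids[0]:
                fused = "".join(seqs_anc[a] for a in ev.anc_ids)
                _emit_b(c, fused, ev.anc_ids)
                i += len(ev.anc_ids)
                continue
            if etype in ("invert_block", "chimera_in_B"):
                i += 1
                continue
            if etype == "split_in_B":
                seq = seqs_anc[anc.anc_id]
                bp = int(rng.integers(config.min_part_length,
                                      len(seq) - config.min_part_length + 1))
                ev.params["breakpoint_b"] = bp
                _emit_b(c, seq[:bp], [anc.anc_id])
                _emit_b(c, seq[bp:], [anc.anc_id])
            elif etype == "tandem_expand_in_B":
                _emit_b(c, seqs_anc[anc.anc_id], [anc.anc_id])
                _emit_b(c, seqs_anc[anc.anc_id], [anc.anc_id])
            elif etype == "relocate":
                others = [x for x in chrom_names if x != c] or [c]
                target = others[int(rng.integers(len(others)))]
                ev.params["from"], ev.params["to"] = c, target
                gid = _emit_b(target, seqs_anc[anc.anc_id], [anc.anc_id],
                              defer=True)
                relocated.append((gid, target))
            elif etype == "drop_from_B":
                pass
            else:
                _emit_b(c, seqs_anc[anc.anc_id], [anc.anc_id])
            i += 1
    for gid, target in relocated:
        pos = int(rng.integers(len(order_b[target]) + 1))
        order_b[target].insert(pos, (gid, len(seqs_b[gid]), "+"))
    # speculative repeat-track genes (random sequences, excluded from matching)
    repeat_ids = []
    for j in range(config.repeat_track_in_B):
        counter_b += 1
        gid = f"GB{counter_b:05d}"
        seqs_b[gid] = _random_seq(rng, int(rng.integers(config.min_gene_length,
                                                        config.max_gene_length)))
        c = chrom_names[j % len(chrom_names)]
        order_b[c].append((gid, len(seqs_b[gid]), "+"))
        repeat_ids.append(gid)

    # --- lay out coordinates
    def _layout(order, version, repeat_set=frozenset()):
        genes = []
        for chrom in order:
            pos = 0
            for gid, length, strand in order[chrom]:
                gap = int(rng.integers(config.min_spacing, config.max_spacing + 1))
                start = pos + gap
                end = start + length - 1
                pos = end
                genes.append(GeneModel.with_naming(
                    gene_id=gid, version_label=version, chromosome=chrom,
                    start=start, end=end, strand=strand,
                    track=REPEAT if gid in repeat_set else MAIN,
                    naming=naming,
                ))
        return genes

    genes_a = _layout(order_a, "A")
    genes_b = _layout(order_b, "B", frozenset(repeat_ids))

    truth_map = {
        a.anc_id: (tuple(truth_a.get(a.anc_id, ())), tuple(truth_b.get(a.anc_id, ())))
        for a in ancestral
    }
    log = EventLog(events=events, truth_map=truth_map, seed=config.seed)
    return SimulationResult(
        genes_a=genes_a, genes_b=genes_b, seqs_a=seqs_a, seqs_b=seqs_b,
        proteins=proteins, log=log, config=config,
    )


# --------------------------------------------------------------------------
# Recovery scoring against the ground truth

#: expected cardinality call (on version-B genes) per planted event class
EXPECTED_CALL = {
    "tandem_expand_in_B": "redundant",
    "split_in_B": "overlap",
    "merge_in_B": "merged",
    "chimera_in_B": "to_split",
    "chimera_in_A": "split",
}

#: expected positional modification per planted event class
EXPECTED_MOD = {
    "relocate": "reassigned",
    "unplace_in_A": "newly_placed_from_unknown",
}


def score_recovery(log: EventLog, calls, positions=None, runs=None) -> dict:
    """Per-class precision/recall of the planted events.

    Cardinality classes are scored on version-B gene labels; positional
    classes on per-pair modification labels; inversions on run membership.
    Precision of an empty prediction set is reported as 1.0.
    """
    version_b = "B"
    pred_by_call: dict[str, set] = defaultdict(set)
    for c in calls:
        if c.version_label == version_b:
            pred_by_call[c.call].add(c.gene_id)
    result = {}

    def _prf(truth: set, pred: set):
        tp = len(truth & pred)
        precision = tp / len(pred) if pred else 1.0
        recall = tp / len(truth) if truth else 1.0
        return {"precision": precision, "recall": recall,
                "tp": tp, "fp": len(pred - truth), "fn": len(truth - pred)}

    for etype, expected in EXPECTED_CALL.items():
        truth = log.b_ids_of(etype)
        result[etype] = _prf(truth, pred_by_call.get(expected, set()))

    if positions is not None:
        mod_pred: dict[str, set] = defaultdict(set)
        for p in positions:
            mod_pred[p.modification].add(p.id_b)
        for etype, expected in EXPECTED_MOD.items():
            truth = log.b_ids_of(etype)
            result[etype] = _prf(truth, mod_pred.get(expected, set()))
    if runs is not None:
        truth = log.b_ids_of("invert_block")
        pred = {idb for r in runs for (_ida, idb) in r.member_pairs}
        result["invert_block"] = _prf(truth, pred)
        result["invert_block"]["n_runs"] = len(runs)
        result["invert_block"]["n_planted"] = len(log.events_of("invert_block"))
    return result
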