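"""Small-scale seeded nucleotide aligner.

A desk-scale local aligner used to compare the two versions' gene sequences
when no external tabular hits are supplied, and as a test oracle.  It follows
the classic seed-and-extend recipe:

1. exact k-mer seeds (default k=16) located through a sorted-hash index of
   the subject set;
2. seeds bucketed per (subject gene, diagonal) and merged across nearby
   diagonals;
3. ungapped X-drop extension along the dominant diagonal; clusters spanning
   several diagonals (i.e. containing indels) are refined with a banded
   edit-distance alignment (edlib) over the seeded window.

Both query strands are searched; minus-strand hits are reported BLAST-style
with ``s_start > s_end``.

The e-value is a *surrogate*: a Karlin–Altschul-style formula
``E = m·n·2^(-bits)`` with fixed parameters ``lambda=1.28``, ``K=0.46`` over a
+1/−2 match/mismatch scoring (megablast-like rewards).  It is monotone in the
raw score and adequate for thresholding, but it is not a calibrated database
statistic.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

try:  # gapped refinement; the ungapped path never needs it
    import edlib
except ImportError:  # pragma: no cover
    edlib = None

from .models import MatchHit

# scoring and statistics (surrogate Karlin–Altschul parameters)
MATCH = 1
MISMATCH = -2
GAP = -3  # per gap column
LAMBDA = 1.28
KPARAM = 0.46
LN2 = math.log(2.0)

#: refuse in-memory alignment above this length; supply external hits instead
MAX_ALIGN_LEN = 50_000

_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
    _CODES[_b + 32] = _i  # lowercase
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    if isinstance(seq, np.ndarray):
        return seq
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODES[np.frombuffer(seq, dtype=np.uint8)]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def revcomp(seq: str) -> str:
    table = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(table)[::-1]


def _kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All valid k-mer hashes and their start positions (windows with non-ACGT
    codes are dropped)."""
    n = len(codes)
    if n < k:
        return np.empty(0, np.uint64), np.empty(0, np.int64)
    w = np.lib.stride_tricks.sliding_window_view(codes, k)
    pows = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
    h = w.astype(np.uint64) @ pows
    valid = ~np.any(w == 4, axis=1)
    pos = np.nonzero(valid)[0].astype(np.int64)
    return h[valid], pos


class KmerIndex:
    """Sorted k-mer hash index over a set of subject sequences."""

    def __init__(self, seqs: Mapping[str, str], k: int = 16):
        if k < 8 or k > 16:
            raise ValueError("k must be in 8..16")
        self.k = k
        self.names: list[str] = list(seqs)
        self.codes: list[np.ndarray] = [encode(seqs[n]) for n in self.names]
        self.lengths = np.array([len(c) for c in self.codes], dtype=np.int64)
        # concatenate with a sentinel code (4) so no k-mer spans two genes
        offsets = np.zeros(len(self.codes), dtype=np.int64)
        pos = 0
        chunks = []
        sentinel = np.array([4], dtype=np.uint8)
        for i, c in enumerate(self.codes):
            offsets[i] = pos
            chunks.append(c)
            chunks.append(sentinel)
            pos += len(c) + 1
        self.offsets = offsets
        concat = np.concatenate(chunks) if chunks else np.empty(0, np.uint8)
        h, p = _kmer_hashes(concat, k)
        order = np.argsort(h, kind="stable")
        self._h = h[order]
        self._p = p[order]
        self._name_index = {n: i for i, n in enumerate(self.names)}

    def sequence(self, name: str) -> np.ndarray:
        return self.codes[self._name_index[name]]


def _seed_matches(index: KmerIndex, qh, qpos, max_hits_per_kmer: int = 64):
    """Match query k-mer hashes against the index.

    Returns (q_positions, subject_gene_indices, subject_positions) arrays.
    Over-abundant k-mers are skipped to bound repeat blow-up.
    """
    left = np.searchsorted(index._h, qh, side="left")
    right = np.searchsorted(index._h, qh, side="right")
    cnt = right - left
    keep = (cnt > 0) & (cnt <= max_hits_per_kmer)
    if not np.any(keep):
        e = np.empty(0, np.int64)
        return e, e, e
    l, c, qp = left[keep], cnt[keep], qpos[keep]
    total = int(c.sum())
    grp_start = np.cumsum(c) - c
    offs = np.arange(total, dtype=np.int64) - np.repeat(grp_start, c)
    spos = index._p[np.repeat(l, c) + offs]
    qrep = np.repeat(qp, c)
    gi = np.searchsorted(index.offsets, spos, side="right") - 1
    s_in = spos - index.offsets[gi]
    return qrep, gi, s_in


def _ungapped_extend(q, s, diag, seed_lo, seed_hi, x_drop=20):
    """X-drop extension on one diagonal.

    ``seed_lo``/``seed_hi`` bound the seeded region in query coordinates
    (hi exclusive).  Returns (q0, q1, matches, length) with q1 exclusive, the
    alignment trimmed to start and end on a matching column.
    """
    lo = max(0, diag)
    hi = min(len(q), len(s) + diag)
    qseg = q[lo:hi]
    sseg = s[lo - diag:hi - diag]
    eq = (qseg == sseg) & (qseg != 4)
    sc = np.where(eq, MATCH, MISMATCH).astype(np.int32)
    a = seed_lo - lo
    b = seed_hi - lo
    # right extension
    if b < len(sc):
        cs = np.cumsum(sc[b:])
        run = np.maximum.accumulate(cs)
        dead = run - cs > x_drop
        stop = int(np.argmax(dead)) if dead.any() else len(cs)
        ext_r = int(np.argmax(cs[:stop])) + 1 if stop > 0 and cs[:stop].max() > 0 else 0
    else:
        ext_r = 0
    # left extension (mirror)
    if a > 0:
        rs = sc[:a][::-1]
        cs = np.cumsum(rs)
        run = np.maximum.accumulate(cs)
        dead = run - cs > x_drop
        stop = int(np.argmax(dead)) if dead.any() else len(cs)
        ext_l = int(np.argmax(cs[:stop])) + 1 if stop > 0 and cs[:stop].max() > 0 else 0
    else:
        ext_l = 0
    start = a - ext_l
    end = b + ext_r
    # trim terminal mismatches
    while start < end and not eq[start]:
        start += 1
    while end > start and not eq[end - 1]:
        end -= 1
    if end <= start:
        return None
    matches = int(eq[start:end].sum())
    return lo + start, lo + end, matches, end - start


def _bit_and_evalue(score: float, qlen: int, slen: int) -> tuple[float, float]:
    bits = (LAMBDA * score - math.log(KPARAM)) / LN2
    if bits > 1000:
        ev = 0.0
    else:
        ev = qlen * slen * math.pow(2.0, -bits)
    return bits, ev


def _cluster_seeds(qrep, gi, s_in, band=100, min_seeds=2):
    """Group seed matches into per-(gene, diagonal-band) clusters."""
    diag = qrep - s_in
    order = np.lexsort((qrep, diag, gi))
    gi, diag, qrep, s_in = gi[order], diag[order], qrep[order], s_in[order]
    clusters = []
    i, n = 0, len(gi)
    while i < n:
        j = i + 1
        while j < n and gi[j] == gi[i] and diag[j] - diag[j - 1] <= band:
            j += 1
        if j - i >= min_seeds:
            clusters.append((int(gi[i]), qrep[i:j], diag[i:j]))
        i = j
    return clusters


def _align_one_strand(qcodes, index, k, minus, qlen, min_seeds, x_drop):
    raw = []
    qh, qpos = _kmer_hashes(qcodes, k)
    if len(qh) == 0:
        return raw
    qrep, gi, s_in = _seed_matches(index, qh, qpos)
    if len(qrep) == 0:
        return raw
    for gene_i, qp, dg in _cluster_seeds(qrep, gi, s_in, min_seeds=min_seeds):
        scodes = index.codes[gene_i]
        slen = int(index.lengths[gene_i])
        seed_lo = int(qp.min())
        seed_hi = int(qp.max()) + k
        spread = int(dg.max() - dg.min())
        if spread == 0:
            r = _ungapped_extend(qcodes, scodes, int(dg[0]), seed_lo, seed_hi,
                                 x_drop=x_drop)
            if r is None:
                continue
            q0, q1, matches, length = r
            gapcols = 0
            mism = length - matches
            s0 = q0 - int(dg[0])
            s1 = q1 - int(dg[0])
        else:
            r = _gapped_refine(qcodes, scodes, qp, dg, k)
            if r is None:
                continue
            q0, q1, s0, s1, matches, length, gapcols = r
            mism = length - matches - gapcols
        score = MATCH * matches + MISMATCH * mism + GAP * gapcols
        if score <= 0:
            continue
        raw.append(
            dict(gene=index.names[gene_i], slen=slen, q0=q0, q1=q1, s0=s0, s1=s1,
                 matches=matches, length=length, mism=mism, gaps=gapcols,
                 score=score, minus=minus)
        )
    return raw


def _gapped_refine(qcodes, scodes, qp, dg, k, pad=50):
    """Refine a multi-diagonal seed cluster with a banded edit-distance
    alignment of the seeded query window against the subject window."""
    if edlib is None:  # pragma: no cover - edlib is a hard dependency
        return None
    q_lo = max(0, int(qp.min()) - pad)
    q_hi = min(len(qcodes), int(qp.max()) + k + pad)
    s_lo = max(0, int((qp - dg).min()) - pad)
    s_hi = min(len(scodes), int((qp - dg).max()) + k + pad)
    qs = "".join("ACGTN"[c] for c in qcodes[q_lo:q_hi])
    ss = "".join("ACGTN"[c] for c in scodes[s_lo:s_hi])
    res = edlib.align(qs, ss, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    t0, t1 = res["locations"][0]
    cigar = res["cigar"] or ""
    # edlib emits extended CIGAR: '=' match, 'X' mismatch, 'I'/'D' gaps
    # (plain 'M' is tolerated and disambiguated via the edit distance)
    cols = eq_cols = m_cols = x_cols = i_cols = d_cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        cols += n
        if ch == "=":
            eq_cols += n
        elif ch == "X":
            x_cols += n
        elif ch == "M":
            m_cols += n
        elif ch == "I":
            i_cols += n
        elif ch == "D":
            d_cols += n
    errors = res["editDistance"]
    subs_in_m = errors - x_cols - i_cols - d_cols
    matches = eq_cols + m_cols - subs_in_m
    return q_lo, q_hi, s_lo + t0, s_lo + t1 + 1, matches, cols, i_cols + d_cols


def _dedupe(raws):
    """Collapse near-duplicate hits on the same subject, keeping distinct
    portions (needed for chimera detection) but dropping shadowed repeats."""
    raws = sorted(raws, key=lambda r: -r["score"])
    kept = []
    for r in raws:
        shadowed = False
        for kr in kept:
            if kr["gene"] != r["gene"] or kr["minus"] != r["minus"]:
                continue
            qo = min(kr["q1"], r["q1"]) - max(kr["q0"], r["q0"])
            so = min(kr["s1"], r["s1"]) - max(kr["s0"], r["s0"])
            shorter_q = min(kr["q1"] - kr["q0"], r["q1"] - r["q0"])
            shorter_s = min(kr["s1"] - kr["s0"], r["s1"] - r["s0"])
            if qo > 0.5 * shorter_q and so > 0.5 * shorter_s:
                shadowed = True
                break
        if not shadowed:
            kept.append(r)
    return kept


def _raw_to_hit(r, query_id, qlen) -> MatchHit:
    if r["minus"]:
        # coordinates were computed on the reverse-complemented query; map
        # back to the forward query and flip the subject interval
        q0 = qlen - r["q1"]
        q1 = qlen - r["q0"]
        s_start, s_end = r["s1"], r["s0"] + 1  # 1-based, descending
    else:
        q0, q1 = r["q0"], r["q1"]
        s_start, s_end = r["s0"] + 1, r["s1"]
    bits, ev = _bit_and_evalue(r["score"], qlen, r["slen"])
    return MatchHit(
        query_id=query_id,
        subject_id=r["gene"],
        pct_identity=100.0 * r["matches"] / r["length"],
        aln_length=r["length"],
        mismatches=r["mism"],
        gap_opens=r["gaps"],
        q_start=q0 + 1,
        q_end=q1,
        s_start=s_start,
        s_end=s_end,
        e_value=ev,
        bit_score=bits,  # unrounded; tabular writers round for display
    )


def align_query(query_id: str, qseq, index: KmerIndex, *, min_seeds: int = 2,
                x_drop: int = 20) -> list[MatchHit]:
    """Align one query against an indexed subject set, both strands."""
    qcodes = encode(qseq)
    qlen = len(qcodes)
    if qlen > MAX_ALIGN_LEN:
        raise ValueError(
            f"query {query_id} is {qlen} bp, above the {MAX_ALIGN_LEN} bp cap; "
            "supply external tabular hits instead"
        )
    raws = _align_one_strand(qcodes, index, index.k, False, qlen, min_seeds, x_drop)
    raws += _align_one_strand(revcomp_codes(qcodes), index, index.k, True, qlen,
                              min_seeds, x_drop)
    hits = [_raw_to_hit(r, query_id, qlen) for r in _dedupe(raws)]
    hits.sort(key=lambda h: (-h.bit_score, -h.pct_identity, -h.aln_length, h.subject_id))
    return hits


def align_sets(queries: Mapping[str, str], subjects, *, k: int = 16,
               min_seeds: int = 2, x_drop: int = 20) -> list[MatchHit]:
    """Align every query against a subject set (or a prebuilt KmerIndex)."""
    index = subjects if isinstance(subjects, KmerIndex) else KmerIndex(subjects, k=k)
    for name, seq in queries.items():
        if len(seq) > MAX_ALIGN_LEN:
            raise ValueError(
                f"query {name} exceeds the {MAX_ALIGN_LEN} bp cap; "
                "supply external tabular hits instead"
            )
    hits: list[MatchHit] = []
    for name, seq in queries.items():
        hits.extend(align_query(name, seq, index, min_seeds=min_seeds, x_drop=x_drop))
    return hits


def align_small(query: str, subject: str, query_id: str = "query",
                subject_id: str = "subject", **kw) -> list[MatchHit]:
    """Align a single query/subject pair (both at most 50 kb)."""
    if len(subject) > MAX_ALIGN_LEN:
        raise ValueError(
            f"subject is {len(subject)} bp, above the {MAX_ALIGN_LEN} bp cap; "
            "supply external tabular hits instead"
        )
    return align_query(query_id, query, KmerIndex({subject_id: subject}), **kw)
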