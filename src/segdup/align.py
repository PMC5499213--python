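"""Whole-genome self-alignment engine (seed - chain - extend).

The detection core: exact k-mer seeds on both strands are chained within
diagonal neighbourhoods (inter-seed gaps up to ``max_gap`` bp), chain ends
are extended by un-gapped x-drop extension, and each candidate is scored by
a banded affine-gap (Gotoh) alignment.  Low-scoring chains are dropped by a
score threshold that substitutes for a BLAST e-value cutoff: with the
default scoring (match +1, mismatch -2, gap open -5, gap extend -1) the
default ``min_score`` of 250 is exactly what a gapless 1 kb alignment at
75% identity achieves, preserving the intended sensitivity floor.

Identity is ``100 * matches / aligned_columns`` where aligned columns
include internal gap columns; terminal gap columns are trimmed.  Alignment
pairs are stored once, canonically ordered so that interval ``a`` is the
leftmost of the two.  Reverse-strand pairs keep both intervals in forward
coordinates with ``strand == '-'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .intervals import reciprocal_overlap
from .masking import CoordinateMap

log = logging.getLogger(__name__)

_NEG = -(1 << 40)

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else (incl. N) -> 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    rc = (3 - codes[::-1]).astype(np.int16)
    rc[rc < 0] = 4
    return rc.astype(np.uint8)


def kmer_array(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mers at every start position, plus a validity mask.

    Positions whose window contains a non-ACGT base are invalid.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in 1..31")
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    nk = n - k + 1
    km = np.zeros(nk, dtype=np.int64)
    bad = np.zeros(nk, dtype=np.int32)
    for j in range(k):
        window = codes[j : j + nk].astype(np.int64)
        km = (km << 2) | (window & 3)
        bad += (window == 4).astype(np.int32)
    return km, bad == 0


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()


@njit(cache=True)
def _gotoh_core(a, b, band, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Banded global affine-gap DP with traceback and terminal trimming.

    Returns (global_score, segment_score, matches, mismatches,
    gap_columns, lead_a, lead_b, trail_a, trail_b).  The optimal global
    alignment path is trimmed at both ends to its maximal-scoring
    contiguous subpath; counts and ``segment_score`` describe the trimmed
    segment, and lead/trail report how many bases of each sequence the
    trimmed ends consumed.  (Terminal gap columns always score negatively,
    so this subsumes plain terminal-gap trimming; it also discards
    poorly-aligned terminal sequence dragged in by a chance seed.)  Ties
    broken diagonal > gap-in-a (consume b) > gap-in-b (consume a); gap
    extension preferred over opening at equal score.
    """
    n = a.shape[0]
    m = b.shape[0]
    if n == 0 and m == 0:
        return 0, 0, 0, 0, 0, 0, 0, 0, 0
    if n == 0 or m == 0:
        sc = gap_open + gap_extend * (n + m)
        return sc, 0, 0, 0, 0, n, m, 0, 0
    lo_d = min(0, m - n) - band
    hi_d = max(0, m - n) + band
    if lo_d < -n:
        lo_d = -n
    if hi_d > m:
        hi_d = m
    w = hi_d - lo_d + 1
    H = np.full((n + 1, w), _NEG, dtype=np.int64)
    E = np.full((n + 1, w), _NEG, dtype=np.int64)
    F = np.full((n + 1, w), _NEG, dtype=np.int64)
    ptr = np.zeros((n + 1, w), dtype=np.uint8)
    # row 0
    for j in range(max(0, lo_d), min(m, hi_d) + 1):
        c = j - lo_d
        if j == 0:
            H[0, c] = 0
        else:
            E[0, c] = gap_open + gap_extend * j
            H[0, c] = E[0, c]
            p = 1  # H from E
            if j > 1:
                p |= 4  # E extends E
            ptr[0, c] = p
    for i in range(1, n + 1):
        jlo = max(0, i + lo_d)
        jhi = min(m, i + hi_d)
        if jlo > jhi:
            continue
        for j in range(jlo, jhi + 1):
            c = j - i - lo_d
            p = 0
            # F: gap in b (consume a), from row i-1 same j -> c+1
            fbest = _NEG
            if c + 1 < w:
                fh = H[i - 1, c + 1]
                fo = F[i - 1, c + 1]
                if fh > _NEG or fo > _NEG:
                    open_sc = fh + gap_open + gap_extend
                    ext_sc = fo + gap_extend
                    if ext_sc >= open_sc:
                        fbest = ext_sc
                        p |= 8
                    else:
                        fbest = open_sc
            F[i, c] = fbest
            # E: gap in a (consume b), from col j-1 same row -> c-1
            ebest = _NEG
            if j > 0 and c - 1 >= 0:
                eh = H[i, c - 1]
                eo = E[i, c - 1]
                if eh > _NEG or eo > _NEG:
                    open_sc = eh + gap_open + gap_extend
                    ext_sc = eo + gap_extend
                    if ext_sc >= open_sc:
                        ebest = ext_sc
                        p |= 4
                    else:
                        ebest = open_sc
            E[i, c] = ebest
            # H
            hbest = _NEG
            hfrom = 0
            if j > 0 and H[i - 1, c] > _NEG:
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    hbest = H[i - 1, c] + match
                else:
                    hbest = H[i - 1, c] + mismatch
            if ebest > hbest:
                hbest = ebest
                hfrom = 1
            if fbest > hbest:
                hbest = fbest
                hfrom = 2
            H[i, c] = hbest
            ptr[i, c] = p | hfrom
    # traceback from (n, m)
    i = n
    j = m
    state = 0  # 0=H, 1=E, 2=F
    score = H[n, m - n - lo_d]
    # collect the path backwards: op 0=substitution, 1=consume b, 2=consume a
    cap = n + m
    ops = np.empty(cap, dtype=np.uint8)
    colsc = np.empty(cap, dtype=np.int64)
    ismatch = np.empty(cap, dtype=np.uint8)
    ncols = 0
    while i > 0 or j > 0:
        c = j - i - lo_d
        p = ptr[i, c]
        if state == 0:
            hfrom = p & 3
            if hfrom == 0:
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    colsc[ncols] = match
                    ismatch[ncols] = 1
                else:
                    colsc[ncols] = mismatch
                    ismatch[ncols] = 0
                ops[ncols] = 0
                ncols += 1
                i -= 1
                j -= 1
                continue
            state = hfrom
            continue
        if state == 1:  # gap in a, consume b
            ext = (p & 4) != 0
            ops[ncols] = 1
            ismatch[ncols] = 0
            colsc[ncols] = gap_extend if ext else gap_open + gap_extend
            ncols += 1
            j -= 1
            state = 1 if ext else 0
            continue
        # state == 2: gap in b, consume a
        ext = (p & 8) != 0
        ops[ncols] = 2
        ismatch[ncols] = 0
        colsc[ncols] = gap_extend if ext else gap_open + gap_extend
        ncols += 1
        i -= 1
        state = 2 if ext else 0
    # forward order is ncols-1 .. 0; Kadane for the maximal-scoring subpath
    best = 0
    run = 0
    run_start = 0  # forward index of the running segment start
    b0 = 0
    b1 = -1  # empty segment by default
    for f in range(ncols):
        idx = ncols - 1 - f
        run += colsc[idx]
        if run > best:
            best = run
            b0 = run_start
            b1 = f
        if run < 0:
            run = 0
            run_start = f + 1
    matches = 0
    mismatches = 0
    gaps = 0
    lead_a = 0
    lead_b = 0
    trail_a = 0
    trail_b = 0
    for f in range(ncols):
        idx = ncols - 1 - f
        op = ops[idx]
        if f < b0 or f > b1:
            consume_a = op == 0 or op == 2
            consume_b = op == 0 or op == 1
            if f < b0:
                lead_a += 1 if consume_a else 0
                lead_b += 1 if consume_b else 0
            else:
                trail_a += 1 if consume_a else 0
                trail_b += 1 if consume_b else 0
        else:
            if op == 0:
                if ismatch[idx]:
                    matches += 1
                else:
                    mismatches += 1
            else:
                gaps += 1
    return score, best, matches, mismatches, gaps, lead_a, lead_b, trail_a, trail_b


@njit(cache=True)
def _xdrop_extend(q, t, q0, t0, direction, xdrop, match, mismatch):  # pragma: no cover
    """Un-gapped diagonal extension; returns columns advanced at best score."""
    nq = q.shape[0]
    nt = t.shape[0]
    best = 0
    cur = 0
    besti = 0
    i = 0
    while True:
        if direction == 1:
            qi = q0 + i
            ti = t0 + i
        else:
            qi = q0 - 1 - i
            ti = t0 - 1 - i
        if qi < 0 or ti < 0 or qi >= nq or ti >= nt:
            break
        if q[qi] == t[ti] and q[qi] < 4:
            cur += match
        else:
            cur += mismatch
        i += 1
        if cur > best:
            best = cur
            besti = i
        if cur < best - xdrop:
            break
    return besti


@dataclass
class AlignmentPair:
    """A local pairwise alignment between two genomic intervals."""

    seq_a: str
    start_a: int
    end_a: int
    seq_b: str
    start_b: int
    end_b: int
    strand: str
    matches: int
    mismatches: int
    gap_columns: int
    score: int
    stale: bool = False  # set after liftover until refine recomputes stats

    @property
    def aligned_columns(self) -> int:
        return self.matches + self.mismatches + self.gap_columns

    @property
    def identity(self) -> float:
        cols = self.aligned_columns
        return 100.0 * self.matches / cols if cols else 0.0

    @property
    def len_a(self) -> int:
        return self.end_a - self.start_a

    @property
    def len_b(self) -> int:
        return self.end_b - self.start_b

    def interval_a(self) -> Tuple[str, int, int]:
        return (self.seq_a, self.start_a, self.end_a)

    def interval_b(self) -> Tuple[str, int, int]:
        return (self.seq_b, self.start_b, self.end_b)

    def canonical(self) -> "AlignmentPair":
        if (self.seq_b, self.start_b, self.end_b) < (self.seq_a, self.start_a, self.end_a):
            return replace(
                self,
                seq_a=self.seq_b,
                start_a=self.start_b,
                end_a=self.end_b,
                seq_b=self.seq_a,
                start_b=self.start_a,
                end_b=self.end_a,
            )
        return self


class SeqCollection:
    """A genome concatenated into one coded array with N separators.

    The separator is longer than ``max_gap`` plus the seed size so no seed,
    chain or extension can bridge two sequences.
    """

    def __init__(self, genome: Dict[str, str], sep: int):
        self.names: List[str] = list(genome.keys())
        self.offsets: List[int] = []
        parts = []
        pos = 0
        for name in self.names:
            self.offsets.append(pos)
            parts.append(encode(genome[name]))
            pos += len(genome[name])
            parts.append(np.full(sep, 4, dtype=np.uint8))
            pos += sep
        self.codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        self.lengths = [len(genome[n]) for n in self.names]

    def locate(self, pos: int) -> Tuple[str, int]:
        idx = int(np.searchsorted(np.array(self.offsets), pos, side="right")) - 1
        local = pos - self.offsets[idx]
        if local >= self.lengths[idx]:
            raise ValueError(f"position {pos} falls in a separator")
        return self.names[idx], local

    def interval_in_one_seq(self, start: int, end: int) -> Optional[Tuple[str, int, int]]:
        try:
            na, sa = self.locate(start)
            nb, sb = self.locate(end - 1)
        except ValueError:
            return None
        if na != nb:
            return None
        return na, sa, sb + 1


class KmerIndex:
    """Sorted k-mer index over a genome, forward and reverse-complement."""

    def __init__(self, genome: Dict[str, str], k: int = 14, max_gap: int = 1000):
        self.k = k
        self.coll = SeqCollection(genome, sep=max_gap + 2 * k + 16)
        self.codes = self.coll.codes
        self.rc_codes = revcomp_codes(self.codes)
        self.total = len(self.codes)
        km, valid = kmer_array(self.codes, k)
        pos = np.nonzero(valid)[0]
        vals = km[pos]
        order = np.argsort(vals, kind="stable")
        self.fwd_vals = vals[order]
        self.fwd_pos = pos[order]
        km_rc, valid_rc = kmer_array(self.rc_codes, k)
        pos_rc = np.nonzero(valid_rc)[0]
        vals_rc = km_rc[pos_rc]
        order_rc = np.argsort(vals_rc, kind="stable")
        self.rc_vals = vals_rc[order_rc]
        self.rc_pos = pos_rc[order_rc]


def _lookup(qkmers: np.ndarray, qvalid: np.ndarray, sorted_vals: np.ndarray,
            sorted_pos: np.ndarray, max_occ: int) -> Tuple[np.ndarray, np.ndarray]:
    qidx = np.nonzero(qvalid)[0]
    if len(qidx) == 0 or len(sorted_vals) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    q = qkmers[qidx]
    lo = np.searchsorted(sorted_vals, q, side="left")
    hi = np.searchsorted(sorted_vals, q, side="right")
    cnt = hi - lo
    keep = (cnt > 0) & (cnt <= max_occ)
    qidx = qidx[keep]
    lo = lo[keep]
    cnt = cnt[keep]
    total = int(cnt.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    qpos = np.repeat(qidx, cnt)
    offs = np.arange(total, dtype=np.int64) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    tpos = sorted_pos[np.repeat(lo, cnt) + offs]
    return qpos.astype(np.int64), tpos.astype(np.int64)


def _chain_hits(qpos: np.ndarray, tpos: np.ndarray, k: int, max_gap: int) -> List[List[int]]:
    """Greedy collinear chaining: exact-diagonal runs, then cross-diagonal
    merging of runs within ``max_gap`` of each other.  Deterministic (ties
    broken by leftmost start)."""
    if len(qpos) == 0:
        return []
    diag = tpos - qpos
    order = np.lexsort((qpos, diag))
    runs: List[List[int]] = []  # [qs, qe, ts, te, nseeds]
    cq = ct = cd = None
    for idx in order:
        q, t, d = int(qpos[idx]), int(tpos[idx]), int(diag[idx])
        if cd == d and q > cq and q - cq <= max_gap:
            runs[-1][1] = q + k
            runs[-1][3] = t + k
            runs[-1][4] += 1
            cq, ct = q, t
        else:
            runs.append([q, q + k, t, t + k, 1])
            cq, ct, cd = q, t, d
    # merge runs chainable across nearby diagonals
    runs.sort(key=lambda r: (r[0], r[2]))
    merged: List[List[int]] = []
    slop = k
    for r in runs:
        done = False
        for o in reversed(merged[-30:]):
            if r[0] - o[1] > max_gap:
                break
            d_r = r[2] - r[0]
            d_o = o[2] - o[0]
            if (
                abs(d_r - d_o) <= max_gap
                and r[0] >= o[0]
                and r[2] >= o[2] - slop
                and r[0] - o[1] <= max_gap
                and r[2] - o[3] <= max_gap
                and r[2] - o[3] >= -max(slop, o[3] - o[2])
            ):
                o[1] = max(o[1], r[1])
                o[3] = max(o[3], r[3])
                o[4] += r[4]
                done = True
                break
        if not done:
            merged.append(list(r))
    return merged


def _band_for(la: int, lb: int, minimum: int = 32) -> int:
    return max(minimum, abs(la - lb) + 16)


def align_codes(a: np.ndarray, b: np.ndarray, band: Optional[int] = None,
                scoring: Scoring = DEFAULT_SCORING) -> Tuple[int, int, int, int]:
    """Banded global affine alignment of two coded sequences.

    Returns ``(segment_score, matches, mismatches, gap_columns)`` for the
    terminally-trimmed alignment; ``band=None`` selects a full (unbanded)
    DP.
    """
    r = align_codes_ext(a, b, band, scoring)
    return (r[1], r[2], r[3], r[4])


def align_codes_ext(a: np.ndarray, b: np.ndarray, band: Optional[int] = None,
                    scoring: Scoring = DEFAULT_SCORING) -> Tuple[int, ...]:
    """Full alignment detail: ``(global_score, segment_score, matches,
    mismatches, gap_columns, lead_a, lead_b, trail_a, trail_b)`` — see
    the DP core docstring for trimming semantics."""
    if band is None:
        band = max(len(a), len(b))
    return _gotoh_core(
        np.ascontiguousarray(a), np.ascontiguousarray(b), max(1, int(band)),
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )


def align_strings(a: str, b: str, band: Optional[int] = None,
                  scoring: Scoring = DEFAULT_SCORING) -> Tuple[int, int, int, int]:
    return align_codes(encode(a), encode(b), band, scoring)


def _evaluate_chain(codes_q: np.ndarray, codes_t: np.ndarray, ch: Sequence[int],
                    scoring: Scoring, xdrop: int) -> Tuple[int, int, int, int, int, int, int, int]:
    qs, qe, ts, te = ch[0], ch[1], ch[2], ch[3]
    left = _xdrop_extend(codes_q, codes_t, qs, ts, -1, xdrop, scoring.match, scoring.mismatch)
    right = _xdrop_extend(codes_q, codes_t, qe, te, 1, xdrop, scoring.match, scoring.mismatch)
    qs, ts = qs - left, ts - left
    qe, te = qe + right, te + right
    band = _band_for(qe - qs, te - ts)
    _, score, mat, mis, gap, lead_a, lead_b, trail_a, trail_b = align_codes_ext(
        codes_q[qs:qe], codes_t[ts:te], band, scoring
    )
    # trim the interval ends the DP discarded (chance seeds can drag in junk)
    qs, qe = qs + lead_a, qe - trail_a
    ts, te = ts + lead_b, te - trail_b
    return qs, qe, ts, te, score, mat, mis, gap


def _dedupe(pairs: List[AlignmentPair], min_ro: float = 0.9) -> List[AlignmentPair]:
    """Collapse near-identical pairs (mirror hits, bucket-split rediscoveries)."""
    pairs = sorted(
        pairs,
        key=lambda p: (-p.score, p.seq_a, p.start_a, p.seq_b, p.start_b, p.strand),
    )
    kept: List[AlignmentPair] = []
    for p in pairs:
        dup = False
        for q in kept:
            if (
                p.strand == q.strand
                and p.seq_a == q.seq_a
                and p.seq_b == q.seq_b
                and reciprocal_overlap((p.start_a, p.end_a), (q.start_a, q.end_a)) >= min_ro
                and reciprocal_overlap((p.start_b, p.end_b), (q.start_b, q.end_b)) >= min_ro
            ):
                dup = True
                break
        if not dup:
            kept.append(p)
    kept.sort(key=lambda p: (p.seq_a, p.start_a, p.seq_b, p.start_b, p.strand))
    return kept


def self_align(
    fugu: Dict[str, str],
    k: int = 14,
    max_gap: int = 1000,
    min_score: int = 250,
    scoring: Scoring = DEFAULT_SCORING,
    max_occ: int = 64,
    xdrop: int = 20,
) -> List[AlignmentPair]:
    """Self-align a (repeat-excised) genome; returns fugu-coordinate pairs.

    Sequences shorter than ``k`` contribute nothing.  The trivial full-length
    self-hit is never generated (seed pairs require distinct positions);
    residual near-self hits are handled by :func:`discard_self`.
    """
    if all(len(s) < k for s in fugu.values()):
        return []
    index = KmerIndex(fugu, k=k, max_gap=max_gap)
    km, valid = kmer_array(index.codes, k)
    pairs: List[AlignmentPair] = []

    # forward strand: all co-occurring k-mer position pairs with t > q
    qpos, tpos = _lookup(km, valid, index.fwd_vals, index.fwd_pos, max_occ)
    keep = tpos > qpos
    chains = _chain_hits(qpos[keep], tpos[keep], k, max_gap)
    for ch in chains:
        qs, qe, ts, te, score, mat, mis, gap = _evaluate_chain(
            index.codes, index.codes, ch, scoring, xdrop
        )
        if score < min_score:
            continue
        loc_a = index.coll.interval_in_one_seq(qs, qe)
        loc_b = index.coll.interval_in_one_seq(ts, te)
        if loc_a is None or loc_b is None:
            continue
        pairs.append(
            AlignmentPair(*loc_a, *loc_b, "+", mat, mis, gap, score).canonical()
        )

    # reverse strand: forward k-mers vs k-mers of the reverse complement
    qpos, tpos = _lookup(km, valid, index.rc_vals, index.rc_pos, max_occ)
    if len(qpos):
        partner_fwd_start = index.total - tpos - k
        keep = qpos <= partner_fwd_start  # one orientation of each mirror pair
        chains = _chain_hits(qpos[keep], tpos[keep], k, max_gap)
        for ch in chains:
            qs, qe, ts, te, score, mat, mis, gap = _evaluate_chain(
                index.codes, index.rc_codes, ch, scoring, xdrop
            )
            if score < min_score:
                continue
            fs, fe = index.total - te, index.total - ts  # rc -> forward coords
            loc_a = index.coll.interval_in_one_seq(qs, qe)
            loc_b = index.coll.interval_in_one_seq(fs, fe)
            if loc_a is None or loc_b is None:
                continue
            pairs.append(
                AlignmentPair(*loc_a, *loc_b, "-", mat, mis, gap, score).canonical()
            )
    return _dedupe(pairs)


def discard_self(pairs: Sequence[AlignmentPair], max_self_overlap: float = 0.5) -> List[AlignmentPair]:
    """Drop trivial self-hits.

    Removes forward pairs whose two intervals are identical, and forward
    same-sequence pairs whose intervals overlap by more than
    ``max_self_overlap`` of the shorter side (near-self diagonal hits);
    tandem pairs at <= 50% overlap are kept.  Mirrors were already collapsed
    by canonical ordering during alignment.
    """
    out: List[AlignmentPair] = []
    for p in pairs:
        if p.strand == "+" and p.interval_a() == p.interval_b():
            continue
        if p.strand == "+" and p.seq_a == p.seq_b:
            ov = min(p.end_a, p.end_b) - max(p.start_a, p.start_b)
            if ov > max_self_overlap * min(p.len_a, p.len_b):
                continue
        out.append(p)
    return out


def _trim_to_anchor(cmap: CoordinateMap, seq: str, start: int, end: int,
                    min_anchor: int) -> Tuple[int, int]:
    """Shrink a fugu interval so each end keeps >= ``min_anchor`` bp of its
    terminal block (when the interval spans several kept blocks).

    A few chance-matched bases extending across an excision would otherwise
    re-include the whole excised repeat on liftover and inflate the
    original-coordinate interval far beyond the aligned sequence.
    """
    b = cmap.blocks[seq]
    fstarts = b[:, 0]
    while True:
        i0 = int(np.searchsorted(fstarts, start, side="right")) - 1
        i1 = int(np.searchsorted(fstarts, end - 1, side="right")) - 1
        if i0 == i1:
            return start, end
        head = int(fstarts[i0] + b[i0, 2]) - start
        tail = end - int(fstarts[i1])
        if head < min_anchor:
            start = int(fstarts[i0 + 1])
        elif tail < min_anchor:
            end = int(fstarts[i1])
        else:
            return start, end


def reinsert(
    pairs: Sequence[AlignmentPair], cmap: CoordinateMap, min_anchor: int = 25
) -> List[AlignmentPair]:
    """Lift fugu-coordinate pairs back to original coordinates.

    Intervals expand by exactly the excised bp interior to them; alignment
    statistics become stale until :func:`refine` recomputes them on the
    repeat-inclusive sequence.  Interval ends anchored by fewer than
    ``min_anchor`` bp of kept sequence are trimmed first so a spurious
    boundary extension cannot drag a whole excised repeat into the lifted
    interval.
    """
    out: List[AlignmentPair] = []
    for p in pairs:
        sa_f, ea_f = _trim_to_anchor(cmap, p.seq_a, p.start_a, p.end_a, min_anchor)
        sb_f, eb_f = _trim_to_anchor(cmap, p.seq_b, p.start_b, p.end_b, min_anchor)
        (sa, ea), = cmap.lift(p.seq_a, (sa_f, ea_f), "fugu->orig")
        (sb, eb), = cmap.lift(p.seq_b, (sb_f, eb_f), "fugu->orig")
        out.append(
            replace(p, start_a=sa, end_a=ea, start_b=sb, end_b=eb, stale=True).canonical()
        )
    return out


def refine(
    pairs: Sequence[AlignmentPair],
    genomes: Dict[str, str],
    band: int = 32,
    max_interval: int = 200_000,
    scoring: Scoring = DEFAULT_SCORING,
) -> List[AlignmentPair]:
    """Re-align each pair globally on the unmasked genome.

    A banded affine-gap realignment of the two original-coordinate intervals
    recomputes matches/gaps/identity on repeat-inclusive sequence.  The band
    is widened automatically to cover the length difference of the two
    intervals.  Terminal gap columns are trimmed from both the statistics
    and the interval endpoints, so repeat bases re-included at a boundary by
    liftover but unmatched on the partner side do not inflate the SD
    interval.  Intervals longer than ``max_interval`` are skipped with a
    warning (quadratic DP cost bound).
    """
    out: List[AlignmentPair] = []
    for p in pairs:
        if p.len_a > max_interval or p.len_b > max_interval:
            log.warning(
                "refine: skipping pair %s:%d-%d / %s:%d-%d (interval exceeds %d bp)",
                p.seq_a, p.start_a, p.end_a, p.seq_b, p.start_b, p.end_b, max_interval,
            )
            continue
        a = encode(genomes[p.seq_a][p.start_a:p.end_a])
        b = encode(genomes[p.seq_b][p.start_b:p.end_b])
        if p.strand == "-":
            b = revcomp_codes(b)
        eff_band = max(band, _band_for(len(a), len(b)))
        _, score, mat, mis, gap, lead_a, lead_b, trail_a, trail_b = align_codes_ext(
            a, b, eff_band, scoring
        )
        start_a, end_a = p.start_a + lead_a, p.end_a - trail_a
        if p.strand == "-":
            # b was reverse-complemented: alignment start is forward end_b
            start_b, end_b = p.start_b + trail_b, p.end_b - lead_b
        else:
            start_b, end_b = p.start_b + lead_b, p.end_b - trail_b
        if end_a <= start_a or end_b <= start_b:
            continue  # alignment was all terminal gaps: unrelated intervals
        out.append(
            replace(
                p, start_a=start_a, end_a=end_a, start_b=start_b, end_b=end_b,
                matches=mat, mismatches=mis, gap_columns=gap, score=score, stale=False,
            ).canonical()
        )
    return out


@dataclass
class Hit:
    """A qualifying local hit of a query interval in a target genome."""

    seq: str
    start: int
    end: int
    matches: int
    mismatches: int
    gap_columns: int
    score: int

    @property
    def identity(self) -> float:
        cols = self.matches + self.mismatches + self.gap_columns
        return 100.0 * self.matches / cols if cols else 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


def search_sequence(
    query: str,
    index: KmerIndex,
    max_gap: int = 1000,
    min_score: int = 250,
    scoring: Scoring = DEFAULT_SCORING,
    max_occ: int = 64,
    xdrop: int = 20,
) -> List[Hit]:
    """Find local alignments of ``query`` in an indexed genome (both strands)."""
    k = index.k
    qcodes = encode(query)
    km, valid = kmer_array(qcodes, k)
    hits: List[Hit] = []
    for vals, pos, codes_t, is_rc in (
        (index.fwd_vals, index.fwd_pos, index.codes, False),
        (index.rc_vals, index.rc_pos, index.rc_codes, True),
    ):
        qpos, tpos = _lookup(km, valid, vals, pos, max_occ)
        for ch in _chain_hits(qpos, tpos, k, max_gap):
            qs, qe, ts, te, score, mat, mis, gap = _evaluate_chain(
                qcodes, codes_t, ch, scoring, xdrop
            )
            if score < min_score:
                continue
            if is_rc:
                ts, te = index.total - te, index.total - ts
            loc = index.coll.interval_in_one_seq(ts, te)
            if loc is None:
                continue
            hits.append(Hit(*loc, mat, mis, gap, score))
    hits.sort(key=lambda h: (h.seq, h.start, h.end))
    return hits
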