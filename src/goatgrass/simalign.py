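"""Self-contained pairwise similarity engine.

A seeded local aligner that produces :class:`~goatgrass.formats_io.Hit`
records so the whole pipeline can run without any external search tool.
Shared exact k-mers nominate candidate diagonals on both strands; a banded
affine-gap Smith-Waterman (numba-compiled) then finds the best local
alignment around the seeded diagonals.  When the dynamic-programming matrix
is small the band covers the whole matrix, so results on short sequences are
exactly the unrestricted local optimum.

E-values use the ungapped Karlin-Altschul form

    E = K * m * n * exp(-lambda * S)

with the classic ungapped DNA defaults lambda = 1.33, K = 0.621 (match +1 /
mismatch -2 scoring).  This is a ranking device whose thresholds are always
configurable; it is not calibrated to any external tool's statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .formats_io import Hit, SeqRecord

__all__ = [
    "AlignParams",
    "SubjectDatabase",
    "align_pair",
    "all_vs_all",
    "encode",
    "revcomp",
]

_NEG = -(10**9)
_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True, slots=True)
class AlignParams:
    """Scoring and significance parameters for the seeded local aligner.

    A gap of length L costs ``gap_open + L * gap_extend`` (both negative).
    """

    kmer: int = 12
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    max_evalue: float = 1e-6
    karlin_lambda: float = 1.33
    karlin_k: float = 0.621
    band_pad: int = 16

    def __post_init__(self) -> None:
        if self.kmer < 8:
            raise ValueError("kmer seed length must be >= 8")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("penalties must be negative")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.karlin_k * m * n * math.exp(-self.karlin_lambda * score)

    def bitscore(self, score: float) -> float:
        return (self.karlin_lambda * score - math.log(self.karlin_k)) / math.log(2)


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A,C,G,T -> 0..3; anything else 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Seeding


def _kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 hashes of all k-windows free of N; returns (positions, hashes)."""
    n = codes.shape[0]
    if n < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    hashes = win.astype(np.int64) @ powers
    pos = np.nonzero(valid)[0]
    return pos, hashes[valid]


def _index_kmers(codes: np.ndarray, k: int) -> dict[int, list[int]]:
    index: dict[int, list[int]] = {}
    pos, hashes = _kmer_hashes(codes, k)
    for p, h in zip(pos.tolist(), hashes.tolist()):
        index.setdefault(h, []).append(p)
    return index


def _seed_diagonals(
    q_kmers: tuple[np.ndarray, np.ndarray], s_index: dict[int, list[int]]
) -> list[int]:
    """Sorted unique diagonals (qpos - spos) of exact shared k-mers, from
    precomputed query k-mer (positions, hashes)."""
    diags: set[int] = set()
    pos, hashes = q_kmers
    for p, h in zip(pos.tolist(), hashes.tolist()):
        hits = s_index.get(h)
        if hits:
            for sp in hits:
                diags.add(p - sp)
    return sorted(diags)


def _diagonal_clusters(diags: Sequence[int], gap: int) -> list[tuple[int, int]]:
    """Group sorted diagonals into runs separated by more than ``gap``."""
    clusters: list[tuple[int, int]] = []
    lo = hi = diags[0]
    for d in diags[1:]:
        if d - hi > gap:
            clusters.append((lo, hi))
            lo = d
        hi = d
    clusters.append((lo, hi))
    return clusters


# ---------------------------------------------------------------------------
# Banded affine Smith-Waterman (numba).  Cell (i, b) scores alignments ending
# at query prefix i and subject prefix j = i + dmin + b; the band spans
# diagonals dmin .. dmin + width - 1 where a diagonal is j - i.


@njit(cache=True)
def _sw_band(q, s, dmin, width, match, mismatch, gap_open, gap_extend):
    n = q.shape[0]
    m = s.shape[0]
    H = np.full((n + 1, width), _NEG, np.int64)
    E = np.full((n + 1, width), _NEG, np.int64)
    F = np.full((n + 1, width), _NEG, np.int64)
    best = 0
    bi = -1
    bb = -1
    for b in range(width):
        j = dmin + b
        if 0 <= j <= m:
            H[0, b] = 0
    for i in range(1, n + 1):
        for b in range(width):
            j = i + dmin + b
            if j < 0 or j > m:
                continue
            e = _NEG
            if b - 1 >= 0:
                hp = H[i, b - 1]
                ep = E[i, b - 1]
                if hp > _NEG // 2:
                    e = hp + gap_open + gap_extend
                if ep > _NEG // 2 and ep + gap_extend > e:
                    e = ep + gap_extend
            E[i, b] = e
            f = _NEG
            if b + 1 < width:
                hp = H[i - 1, b + 1]
                fp = F[i - 1, b + 1]
                if hp > _NEG // 2:
                    f = hp + gap_open + gap_extend
                if fp > _NEG // 2 and fp + gap_extend > f:
                    f = fp + gap_extend
            F[i, b] = f
            d = _NEG
            if j - 1 >= 0:
                hp = H[i - 1, b]
                if hp > _NEG // 2:
                    qc = q[i - 1]
                    sc = s[j - 1]
                    if qc == sc and qc < 4:
                        d = hp + match
                    else:
                        d = hp + mismatch
            h = 0
            if d > h:
                h = d
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, b] = h
            if h > best:
                best = h
                bi = i
                bb = b
    return best, bi, bb, H, E, F


@njit(cache=True)
def _traceback(q, s, H, E, F, dmin, bi, bb, match, mismatch, gap_open, gap_extend):
    """Walk back from the best cell; returns alignment stats and the matched
    column path (0-based query/subject positions of substitution columns)."""
    i = bi
    b = bb
    n_match = 0
    n_mismatch = 0
    n_gap_open = 0
    n_gap_cols = 0
    cap = q.shape[0] + s.shape[0]
    qpath = np.empty(cap, np.int64)
    spath = np.empty(cap, np.int64)
    npath = 0
    state = 0  # 0 = H, 1 = E (gap consumes subject), 2 = F (gap consumes query)
    while True:
        j = i + dmin + b
        if state == 0:
            val = H[i, b]
            if val == 0:
                break
            diag_ok = False
            if i >= 1 and j >= 1 and H[i - 1, b] > _NEG // 2:
                qc = q[i - 1]
                sc = s[j - 1]
                sub = match if (qc == sc and qc < 4) else mismatch
                if val == H[i - 1, b] + sub:
                    diag_ok = True
            if diag_ok:
                qpath[npath] = i - 1
                spath[npath] = j - 1
                npath += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    n_match += 1
                else:
                    n_mismatch += 1
                i -= 1
            elif val == E[i, b]:
                state = 1
            else:
                state = 2
        elif state == 1:
            val = E[i, b]
            n_gap_cols += 1
            opened = H[i, b - 1] > _NEG // 2 and val == H[i, b - 1] + gap_open + gap_extend
            b -= 1
            if opened:
                n_gap_open += 1
                state = 0
        else:
            val = F[i, b]
            n_gap_cols += 1
            opened = H[i - 1, b + 1] > _NEG // 2 and val == H[i - 1, b + 1] + gap_open + gap_extend
            i -= 1
            b += 1
            if opened:
                n_gap_open += 1
                state = 0
    j = i + dmin + b
    return (
        i,
        j,
        n_match,
        n_mismatch,
        n_gap_open,
        n_gap_cols,
        qpath[:npath][::-1].copy(),
        spath[:npath][::-1].copy(),
    )


# ---------------------------------------------------------------------------
# Per-pair alignment


@dataclass(slots=True)
class _RawAln:
    score: int
    q_start0: int  # 0-based half-open on the query
    q_end0: int
    s_start0: int  # 0-based half-open on the *oriented* subject
    s_end0: int
    n_match: int
    n_mismatch: int
    n_gap_open: int
    n_gap_cols: int
    qpath: np.ndarray
    spath: np.ndarray


def _align_oriented(q_codes, s_codes, diags, params: AlignParams) -> _RawAln | None:
    """Best banded local alignment of q against one orientation of s."""
    n = q_codes.shape[0]
    m = s_codes.shape[0]
    pad = params.band_pad
    small = n * m <= 65536
    if small:
        # full matrix: every diagonal j - i from 1-n to m-1
        bands = [(1 - n, m - 1)]
    else:
        # seed diagonals are qpos - spos; the kernel's diagonal is j - i = -(qpos - spos)
        bands = [
            (max(-hi - pad, 1 - n), min(-lo + pad, m - 1))
            for lo, hi in _diagonal_clusters(diags, gap=2 * pad)
        ]
    best: _RawAln | None = None
    for t_lo, t_hi in bands:
        width = t_hi - t_lo + 1
        if width <= 0:
            continue
        score, bi, bb, H, E, F = _sw_band(
            q_codes, s_codes, t_lo, width,
            params.match, params.mismatch, params.gap_open, params.gap_extend,
        )
        if score <= 0 or bi < 0:
            continue
        (qs, ss, n_match, n_mismatch, n_gap_open, n_gap_cols, qpath, spath) = _traceback(
            q_codes, s_codes, H, E, F, t_lo, bi, bb,
            params.match, params.mismatch, params.gap_open, params.gap_extend,
        )
        aln = _RawAln(
            score=int(score),
            q_start0=int(qs),
            q_end0=int(bi),
            s_start0=int(ss),
            s_end0=int(bi + t_lo + bb),
            n_match=n_match,
            n_mismatch=n_mismatch,
            n_gap_open=n_gap_open,
            n_gap_cols=n_gap_cols,
            qpath=qpath,
            spath=spath,
        )
        if best is None or aln.score > best.score or (
            aln.score == best.score and (aln.q_start0, aln.s_start0) < (best.q_start0, best.s_start0)
        ):
            best = aln
    return best


@dataclass(slots=True)
class _PreppedSubject:
    record: SeqRecord
    codes: dict  # strand -> encoded array
    index: dict  # strand -> kmer hash -> [positions]


def _prep_subject(record: SeqRecord, k: int) -> _PreppedSubject:
    fwd = encode(record.sequence)
    rc = encode(revcomp(record.sequence))
    return _PreppedSubject(
        record=record,
        codes={1: fwd, -1: rc},
        index={1: _index_kmers(fwd, k), -1: _index_kmers(rc, k)},
    )


def _hit_from_raw(
    query: SeqRecord,
    subject: SeqRecord,
    aln: _RawAln,
    strand: int,
    params: AlignParams,
    search_space_nt: int,
) -> Hit | None:
    n = len(query.sequence)
    m = len(subject.sequence)
    evalue = params.evalue(aln.score, n, search_space_nt)
    if evalue > params.max_evalue:
        return None
    aln_len = aln.n_match + aln.n_mismatch + aln.n_gap_cols
    if strand == 1:
        s_start, s_end = aln.s_start0 + 1, aln.s_end0
    else:
        # map back from reverse-complement coordinates; s_start > s_end
        s_start, s_end = m - aln.s_start0, m - aln.s_end0 + 1
    return Hit(
        query_id=query.id,
        subject_id=subject.id,
        pct_identity=100.0 * aln.n_match / aln_len,
        aln_len=aln_len,
        mismatches=aln.n_mismatch,
        gap_opens=aln.n_gap_open,
        q_start=aln.q_start0 + 1,
        q_end=aln.q_end0,
        s_start=s_start,
        s_end=s_end,
        evalue=evalue,
        bitscore=params.bitscore(aln.score),
        score=aln.score,
    ).with_query_cov(n)


def _align_prepped(
    query: SeqRecord,
    q_codes: np.ndarray,
    prepped: _PreppedSubject,
    params: AlignParams,
    search_space_nt: int,
    return_path: bool,
    q_kmers: tuple[np.ndarray, np.ndarray] | None = None,
):
    n = q_codes.shape[0]
    m = len(prepped.record.sequence)
    if q_kmers is None:
        q_kmers = _kmer_hashes(q_codes, params.kmer)
    best: tuple[_RawAln, int] | None = None  # (raw, strand)
    for strand in (1, -1):
        diags = _seed_diagonals(q_kmers, prepped.index[strand])
        if not diags:
            if n * m > 65536:
                continue
            diags = [0]  # small case: full matrix regardless of seeding
        aln = _align_oriented(q_codes, prepped.codes[strand], diags, params)
        if aln is not None and (best is None or aln.score > best[0].score):
            best = (aln, strand)
    if best is None:
        return None
    aln, strand = best
    hit = _hit_from_raw(query, prepped.record, aln, strand, params, search_space_nt)
    if hit is None:
        return None
    if return_path:
        return hit, aln.qpath, aln.spath
    return hit


def align_pair(
    query: SeqRecord,
    subject: SeqRecord,
    params: AlignParams | None = None,
    search_space_nt: int | None = None,
    return_path: bool = False,
):
    """Best local alignment of ``query`` against ``subject`` over both strands.

    Returns a :class:`Hit` (or ``(Hit, qpath, spath)`` with the 0-based
    matched-column coordinates when ``return_path`` is set), or ``None`` when
    no alignment passes ``max_evalue``.  On sequence pairs too large for an
    unrestricted dynamic program, a missing k-mer seed also yields ``None``.
    Reverse-strand hits report ``s_start > s_end`` (1-based inclusive); their
    path coordinates refer to the reverse-complemented subject.
    """
    params = params or AlignParams()
    if search_space_nt is None:
        search_space_nt = len(subject)
    return _align_prepped(
        query,
        encode(query.sequence),
        _prep_subject(subject, params.kmer),
        params,
        search_space_nt,
        return_path,
    )


class SubjectDatabase:
    """A set of subject sequences prepared for repeated seeded search.

    Subjects are encoded and k-mer indexed once; each query is hashed once
    and aligned only against subjects sharing an exact k-mer on either
    strand.  This is the engine behind :func:`all_vs_all`, library
    screening and read pileup construction.
    """

    def __init__(
        self,
        subjects: Sequence[SeqRecord],
        params: AlignParams | None = None,
        search_space_nt: int | None = None,
    ):
        if not subjects:
            raise ValueError("subject set must be non-empty")
        self.params = params or AlignParams()
        self.subjects = list(subjects)
        self.search_space_nt = search_space_nt or sum(len(s) for s in subjects)
        self._prepped = [_prep_subject(s, self.params.kmer) for s in self.subjects]
        self._global: dict[int, set[int]] = {}
        for si, prep in enumerate(self._prepped):
            for h in prep.index[1]:
                self._global.setdefault(h, set()).add(si)
        self._qcache: tuple[int, tuple] | None = None

    def _query_prep(self, query: SeqRecord):
        """Encode and hash a query once per call sequence (cached by id)."""
        key = id(query)
        if self._qcache is not None and self._qcache[0] == key:
            return self._qcache[1]
        q_codes = encode(query.sequence)
        fwd = _kmer_hashes(q_codes, self.params.kmer)
        rc = _kmer_hashes(encode(revcomp(query.sequence)), self.params.kmer)
        prep = (q_codes, fwd, rc)
        self._qcache = (key, prep)
        return prep

    def candidates(self, query: SeqRecord) -> list[int]:
        """Indices of subjects sharing an exact k-mer with the query on
        either strand, in ascending order."""
        _, fwd, rc = self._query_prep(query)
        cands: set[int] = set()
        for _, hashes in (fwd, rc):
            for h in set(hashes.tolist()):
                sis = self._global.get(h)
                if sis:
                    cands.update(sis)
        return sorted(cands)

    def align(self, query: SeqRecord, subject_index: int, return_path: bool = False):
        q_codes, fwd, _ = self._query_prep(query)
        return _align_prepped(
            query,
            q_codes,
            self._prepped[subject_index],
            self.params,
            self.search_space_nt,
            return_path,
            q_kmers=fwd,
        )

    def hits_for(self, query: SeqRecord) -> list[Hit]:
        """All passing hits of one query, sorted by (e-value, subject id)."""
        hits = []
        for si in self.candidates(query):
            hit = self.align(query, si)
            if hit is not None:
                hits.append(hit)
        hits.sort(key=lambda h: (h.evalue, h.subject_id))
        return hits


def all_vs_all(
    queries: Sequence[SeqRecord],
    subjects: Sequence[SeqRecord],
    params: AlignParams | None = None,
    search_space_nt: int | None = None,
) -> list[Hit]:
    """Best hit per (query, subject) pair for every passing pair.

    Candidate subjects are nominated through a shared k-mer index over both
    strands; each candidate pair is then aligned.  Output order is
    deterministic: (query input order, ascending e-value, subject id).
    """
    if not queries:
        raise ValueError("all_vs_all requires a non-empty query set")
    db = SubjectDatabase(subjects, params, search_space_nt)
    out: list[Hit] = []
    for q in queries:
        out.extend(db.hits_for(q))
    return out
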