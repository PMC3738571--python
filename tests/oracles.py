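"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results by the most direct method available
(full dynamic programming, exhaustive enumeration, direct set algebra) and
share no code with the implementation paths they check.
"""

from __future__ import annotations


def sw_score(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-2) -> int:
    """Unrestricted affine-gap local alignment score of two strings (one
    orientation).  A gap of length L costs gap_open + L * gap_extend."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    best = 0
    prev_h = [0] * (m + 1)
    prev_f = [NEG] * (m + 1)
    for i in range(1, n + 1):
        cur_h = [0] * (m + 1)
        cur_f = [NEG] * (m + 1)
        e = NEG
        for j in range(1, m + 1):
            e = max(e + gap_extend, cur_h[j - 1] + gap_open + gap_extend)
            f = max(prev_f[j] + gap_extend, prev_h[j] + gap_open + gap_extend)
            sub = match if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else mismatch
            h = max(0, prev_h[j - 1] + sub, e, f)
            cur_h[j] = h
            cur_f[j] = f
            if h > best:
                best = h
        prev_h, prev_f = cur_h, cur_f
    return best


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def sw_score_both_strands(a: str, b: str, **kw) -> int:
    return max(sw_score(a, b, **kw), sw_score(a, revcomp(b), **kw))


def brbh_bruteforce(forward_hits, reciprocal_hits, max_evalue):
    """Mutually-best pairs by exhaustive scan over full hit lists.

    Hits are (query, subject, evalue, bitscore) tuples.  Best = minimal
    e-value, ties by higher bitscore then lexicographic subject.
    """
    def best_map(hits):
        out = {}
        for q, s, e, b in hits:
            if e > max_evalue:
                continue
            cur = out.get(q)
            if cur is None or (e, -b, s) < (cur[1], -cur[2], cur[0]):
                out[q] = (s, e, b)
        return {q: v[0] for q, v in out.items()}

    fwd = best_map(forward_hits)
    rev = best_map(reciprocal_hits)
    return {(q, s) for q, s in fwd.items() if rev.get(s) == q}


def n50_bruteforce(lengths):
    """Largest length L in the multiset whose >=L sequences hold at least
    half the total nucleotides, by trying every candidate."""
    total = sum(lengths)
    qualifying = [L for L in set(lengths) if sum(x for x in lengths if x >= L) * 2 >= total]
    return max(qualifying)


def venn_regions_bruteforce(sets: dict):
    """Region counts of an n-set membership lattice by per-element scan."""
    from collections import Counter

    counts = Counter()
    universe = set().union(*sets.values())
    for x in universe:
        key = tuple(sorted(name for name, s in sets.items() if x in s))
        counts[key] += 1
    return dict(counts)
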