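"""NB-LRR resistance-gene mining.

Plant NB-LRR immune receptors are under strong diversifying selection, so
no single route finds them all.  This module implements the two
complementary prediction routes and their comparison:

1. a two-stage domain cascade -- sequences with a nucleotide-binding
   (NB-ARC) domain hit at a domain e-value of at most 0.1 are searched,
   and only they, for an intracellular leucine-rich-repeat (LRR) clan hit
   at the same threshold; sequences passing both stages are NB-LRR calls;
2. a lexical route -- a case-insensitive substring search for "nblrr" or
   "nb-lrr" in annotation-term descriptions.

Profile scanning is pluggable.  The production path consumes externally
produced domain-hit tables (profile-HMM searches); the built-in scanner is
a deliberately simple position-weight-matrix matcher over nucleotide motif
consensi, sufficient to exercise the cascade on planted synthetic domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import SeqRecord
from .simalign import encode

__all__ = [
    "DomainHit",
    "RGeneReport",
    "select_domain_hits",
    "nblrr_cascade",
    "lexical_search",
    "compare_predictions",
    "pwm_scan",
    "NBARC_CONSENSUS",
    "LRR_CONSENSUS",
]

PROFILE_CLASSES = ("NB_ARC", "LRR_clan", "other")
LEXICAL_TOKENS = ("nblrr", "nb-lrr")

# Nucleotide motif consensi used by the toy scanner and by the synthetic
# universe to plant degenerate domain copies.  They are arbitrary fixed
# 60-mers, not biological profiles.
NBARC_CONSENSUS = "GGTGTTGGTAAAACAACTCTTGCTCGTAAAGTTTACGATGATCCTGAAGTTCAACGTCAC"
LRR_CONSENSUS = "CTTGATCTTTCTAACAACCAACTTTCTGGTGAAATTCCTGCTTCTCTTGGTAACCTTACT"


@dataclass(slots=True)
class DomainHit:
    """One profile match on a sequence (0-based half-open envelope)."""

    seq_id: str
    profile_name: str
    profile_class: str
    domain_evalue: float
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if self.profile_class not in PROFILE_CLASSES:
            raise ValueError(f"unknown profile class {self.profile_class!r}")
        if self.domain_evalue < 0:
            raise ValueError("domain e-value must be >= 0")
        if not self.env_start < self.env_end:
            raise ValueError("domain envelope must be non-empty")


@dataclass(slots=True)
class RGeneReport:
    nbarc_ids: set[str]
    nblrr_ids: set[str]
    lexical_ids: set[str] = field(default_factory=set)
    brbh_nbarc_count: int | None = None
    brbh_nblrr_count: int | None = None

    def __post_init__(self) -> None:
        if not self.nblrr_ids <= self.nbarc_ids:
            raise ValueError("cascade containment violated: nblrr_ids must be within nbarc_ids")

    @property
    def overlap(self) -> set[str]:
        return self.nblrr_ids & self.lexical_ids

    def to_dict(self) -> dict:
        return {
            "nbarc_count": len(self.nbarc_ids),
            "nblrr_count": len(self.nblrr_ids),
            "lexical_count": len(self.lexical_ids),
            "overlap_count": len(self.overlap),
            "brbh_nbarc_count": self.brbh_nbarc_count,
            "brbh_nblrr_count": self.brbh_nblrr_count,
        }


def select_domain_hits(
    hits: Iterable[DomainHit],
    profile_class: str,
    max_domain_evalue: float = 0.1,
) -> set[str]:
    """Ids with at least one hit of the class at or under the e-value cutoff
    (0.1, the strict per-domain threshold that removes most false hits)."""
    if profile_class not in PROFILE_CLASSES:
        raise ValueError(f"unknown profile class {profile_class!r}")
    return {
        h.seq_id
        for h in hits
        if h.profile_class == profile_class and h.domain_evalue <= max_domain_evalue
    }


def nblrr_cascade(
    all_hits: Sequence[DomainHit], max_domain_evalue: float = 0.1
) -> RGeneReport:
    """Two-stage cascade: NB-ARC positives first, then the LRR-clan search
    restricted to that set.  A sequence with an LRR hit but no NB-ARC hit is
    excluded from both result sets."""
    nbarc = select_domain_hits(all_hits, "NB_ARC", max_domain_evalue)
    lrr = select_domain_hits(all_hits, "LRR_clan", max_domain_evalue)
    return RGeneReport(nbarc_ids=nbarc, nblrr_ids=lrr & nbarc)


def lexical_search(annotations: Mapping[str, Sequence[str]]) -> set[str]:
    """Ids whose any annotation term contains "nblrr" or "nb-lrr",
    case-insensitively."""
    out: set[str] = set()
    for seq_id, terms in annotations.items():
        for term in terms:
            low = term.lower()
            if any(tok in low for tok in LEXICAL_TOKENS):
                out.add(seq_id)
                break
    return out


def compare_predictions(cascade_ids: set[str], lexical_ids: set[str]) -> dict[str, int]:
    """Disjoint overlap counts of the two prediction routes."""
    return {
        "both": len(cascade_ids & lexical_ids),
        "only_cascade": len(cascade_ids - lexical_ids),
        "only_lexical": len(lexical_ids - cascade_ids),
    }


# ---------------------------------------------------------------------------
# Toy position-weight-matrix scanner


def _pwm_from_consensus(consensus: str, p_match: float = 0.85) -> np.ndarray:
    """Log-odds matrix (motif length x 4) against a uniform background."""
    codes = encode(consensus)
    if (codes >= 4).any():
        raise ValueError("motif consensus must be unambiguous DNA")
    w = np.full((len(consensus), 4), math.log2((1 - p_match) / 3 / 0.25))
    w[np.arange(len(consensus)), codes] = math.log2(p_match / 0.25)
    return w


def pwm_scan(
    seqs: Sequence[SeqRecord],
    consensus: str,
    profile_name: str,
    profile_class: str,
    report_max_evalue: float = 10.0,
) -> list[DomainHit]:
    """Scan each sequence with a log-odds PWM built from ``consensus``.

    The best-scoring window per sequence is reported when its e-value --
    (number of windows) * 2^(-score), a simple expected-hit-count under the
    uniform background -- is at or under ``report_max_evalue``.  Forward
    strand only: domain callers run on oriented transcripts.
    """
    pwm = _pwm_from_consensus(consensus)
    w = pwm.shape[0]
    out: list[DomainHit] = []
    for rec in seqs:
        codes = encode(rec.sequence)
        if codes.shape[0] < w:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, w)
        valid = (windows < 4).all(axis=1)
        if not valid.any():
            continue
        safe = np.where(windows < 4, windows, 0)
        scores = pwm[np.arange(w), safe].sum(axis=1)
        scores[~valid] = -np.inf
        best = int(np.argmax(scores))
        evalue = float(windows.shape[0]) * 2.0 ** (-float(scores[best]))
        if evalue <= report_max_evalue:
            out.append(
                DomainHit(
                    seq_id=rec.id,
                    profile_name=profile_name,
                    profile_class=profile_class,
                    domain_evalue=evalue,
                    env_start=best,
                    env_end=best + w,
                )
            )
    return out
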