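"""Allelic-ratio heterozygosity estimation.

At every called SNP site, each accession's reads show the two SNP alleles in
some ratio.  A truly homozygous accession shows essentially one allele
(ratio near infinity, minor reads only from sequencing error); a site that
is heterozygous within an accession shows a ~1:1 mixture.  Sites with
adequate depth (sum of the two allele counts >= 20 by default) are scored by
the ratio of the most- to least-frequent allele, sites at ratio <= 3
(1:1 up to 3:1) are classed heterozygous, and a sequence is heterozygous in
an accession when any of its eligible sites is.  The per-accession
heterozygosity rate is the percentage of eligible SNP-bearing sequences
classed heterozygous.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .orthology import MapPlacement
from .variants import PileupSet, SnpCall

__all__ = [
    "AllelicRatioRecord",
    "HetCall",
    "allelic_ratios",
    "classify_heterozygous",
    "het_rate",
    "ratio_histogram",
    "bin_het_on_map",
    "conversion_rate",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(slots=True)
class AllelicRatioRecord:
    seq_id: str
    pos: int  # 0-based
    accession: str
    n_major: int
    n_minor: int

    def __post_init__(self) -> None:
        if self.n_major < self.n_minor or self.n_minor < 0:
            raise ValueError("require n_major >= n_minor >= 0")

    @property
    def ratio(self) -> float:
        return math.inf if self.n_minor == 0 else self.n_major / self.n_minor

    @property
    def depth(self) -> int:
        return self.n_major + self.n_minor


@dataclass(slots=True)
class HetCall:
    seq_id: str
    accession: str
    n_eligible_sites: int
    n_het_sites: int
    is_het: bool


def allelic_ratios(
    snp_calls: Sequence[SnpCall],
    pileups: PileupSet,
    min_depth: int = 20,
) -> list[AllelicRatioRecord]:
    """Per-site, per-accession counts of the two SNP alleles.

    Depth is the sum of the two SNP alleles' counts only (error bases are
    excluded); records below ``min_depth`` are suppressed.
    """
    out: list[AllelicRatioRecord] = []
    for call in snp_calls:
        b1 = _BASE_CODE[call.allele_acc1]
        b2 = _BASE_CODE[call.allele_acc2]
        for acc in pileups.counts:
            col = pileups.counts[acc][call.seq_id][call.pos]
            n_a, n_b = int(col[b1]), int(col[b2])
            if n_a + n_b < min_depth:
                continue
            out.append(
                AllelicRatioRecord(
                    seq_id=call.seq_id,
                    pos=call.pos,
                    accession=acc,
                    n_major=max(n_a, n_b),
                    n_minor=min(n_a, n_b),
                )
            )
    return out


def classify_heterozygous(
    records: Sequence[AllelicRatioRecord],
    max_ratio: float = 3.0,
    rule: str = "any",
) -> list[HetCall]:
    """Sequence-level heterozygosity per accession.

    A site is heterozygous iff its allelic ratio is <= ``max_ratio``
    (a 3.0 cutoff spans 1:1 through 3:1 mixtures).  Under the default "any"
    rule a sequence is heterozygous when at least one eligible site is;
    the "majority" alternative requires more than half.  Sequences with no
    eligible site produce no call at all (they are excluded from rate
    denominators).
    """
    if rule not in ("any", "majority"):
        raise ValueError("rule must be 'any' or 'majority'")
    grouped: dict[tuple[str, str], list[AllelicRatioRecord]] = defaultdict(list)
    for r in records:
        grouped[(r.seq_id, r.accession)].append(r)
    calls: list[HetCall] = []
    for (seq_id, acc), recs in sorted(grouped.items()):
        n_het = sum(1 for r in recs if r.ratio <= max_ratio)
        if rule == "any":
            is_het = n_het >= 1
        else:
            is_het = n_het > len(recs) / 2
        calls.append(HetCall(seq_id, acc, len(recs), n_het, is_het))
    return calls


def het_rate(het_calls: Sequence[HetCall]) -> float:
    """Percent of eligible sequences classed heterozygous, to 1 decimal.

    The denominator is the number of SNP-bearing sequences with at least
    one depth-eligible site in the accession under study.
    """
    if not het_calls:
        raise ValueError("het_rate of an empty call set is undefined")
    return round(100.0 * sum(c.is_het for c in het_calls) / len(het_calls), 1)


def ratio_histogram(
    records: Sequence[AllelicRatioRecord], bin_edges: Sequence[float]
) -> np.ndarray:
    """Counts per ratio bin plus a trailing overflow bin.

    Finite ratios are histogrammed over ``bin_edges`` (right-open bins,
    as in numpy); ratios at or beyond the last edge, including infinite
    ratios from monoallelic sites, land in the overflow bin.  Counts sum to
    the record count.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("need at least two bin edges")
    ratios = np.array([r.ratio for r in records], dtype=float)
    finite = ratios[np.isfinite(ratios) & (ratios < edges[-1])]
    counts, _ = np.histogram(finite, bins=edges)
    overflow = len(records) - int(counts.sum())
    return np.append(counts, overflow)


def bin_het_on_map(
    het_calls: Sequence[HetCall],
    placements: Sequence[MapPlacement],
    bin_width_cM: float = 5.0,
) -> tuple[dict[tuple[str, int], dict[str, int]], dict[str, int]]:
    """Heterozygous-sequence counts per (chromosome, genetic bin), per
    accession; heterozygous sequences without a placement are tallied in the
    returned unplaced counter."""
    if bin_width_cM <= 0:
        raise ValueError("bin width must be positive")
    placed = {p.query_id: p for p in placements}
    bins: dict[tuple[str, int], dict[str, int]] = defaultdict(lambda: defaultdict(int))
    unplaced: dict[str, int] = defaultdict(int)
    for call in het_calls:
        if not call.is_het:
            continue
        p = placed.get(call.seq_id)
        if p is None:
            unplaced[call.accession] += 1
            continue
        key = (p.chromosome, int(math.floor(p.position_cM / bin_width_cM)))
        bins[key][call.accession] += 1
    return {k: dict(v) for k, v in bins.items()}, dict(unplaced)


def conversion_rate(n_converted: int, n_tested: int) -> float:
    """Marker conversion bookkeeping: percent of assayed SNPs successfully
    converted into co-dominant genotyping markers."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if not 0 <= n_converted <= n_tested:
        raise ValueError("n_converted out of range")
    return 100.0 * n_converted / n_tested
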