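"""Pileup construction and Bayesian inter-accession SNP calling.

Reads from each of two accessions are placed on a pseudo-reference (a de
novo contig set) at their best local alignment, giving per-column base
counts per accession.  Each accession's column is genotyped under a
standard symmetric-error diploid likelihood:

* homozygote aa: a read matches a with probability 1 - eps and shows any
  specific other base with probability eps/3;
* heterozygote ab: each of a, b is seen with probability (1-eps)/2 + eps/6,
  any other base with eps/3;

with prior mass 1 - theta shared equally by the four homozygotes and theta
by the six heterozygotes.  A SNP between the accessions is emitted when the
two accessions' maximum-posterior genotypes differ in allele content, the
joint posterior probability that the genotypes differ reaches
``min_posterior``, and each emitted allele is supported by at least 2 reads
in its accession (the minimum-evidence rule, applied to both accessions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formats_io import SeqRecord, SnpGffRecord
from .simalign import AlignParams, SubjectDatabase, encode

__all__ = [
    "CallerModel",
    "PileupSet",
    "SnpCall",
    "GENOTYPES",
    "build_pileups",
    "genotype_posteriors",
    "call_snps",
    "snp_calls_to_gff",
    "summarise_calls",
]

#: The 10 unordered diploid genotypes over A,C,G,T (base codes 0..3).
GENOTYPES: tuple[tuple[int, int], ...] = tuple(
    (a, b) for a in range(4) for b in range(a, 4)
)
_HOM = [i for i, (a, b) in enumerate(GENOTYPES) if a == b]
_HET = [i for i, (a, b) in enumerate(GENOTYPES) if a != b]
_BASES = "ACGT"


@dataclass(frozen=True, slots=True)
class CallerModel:
    """Error rate, heterozygosity prior and decision threshold of the caller."""

    error_rate: float = 0.01
    het_prior: float = 0.001
    min_posterior: float = 0.9
    min_reads_per_allele: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError("error_rate must be in (0, 0.5)")
        if not 0.0 < self.het_prior < 1.0:
            raise ValueError("het_prior must be in (0, 1)")

    def log_emission(self) -> np.ndarray:
        """(10 genotypes x 4 bases) log emission probabilities."""
        eps = self.error_rate
        P = np.full((len(GENOTYPES), 4), eps / 3.0)
        for gi, (a, b) in enumerate(GENOTYPES):
            if a == b:
                P[gi, a] = 1.0 - eps
            else:
                P[gi, a] = P[gi, b] = (1.0 - eps) / 2.0 + eps / 6.0
        return np.log(P)

    def log_prior(self) -> np.ndarray:
        lp = np.empty(len(GENOTYPES))
        lp[_HOM] = np.log((1.0 - self.het_prior) / 4.0)
        lp[_HET] = np.log(self.het_prior / 6.0)
        return lp


@dataclass(slots=True)
class PileupSet:
    """Per-accession base counts along each reference sequence.

    ``counts[acc][seq_id]`` is an (L, 4) array of A/C/G/T read counts;
    ambiguous read bases (N) are excluded from counts and tallied in
    ``n_counts``.  Reads without a passing alignment, and reads whose best
    alignment score is tied between reference locations, are dropped and
    counted.
    """

    reference_ids: list[str]
    counts: dict[str, dict[str, np.ndarray]]
    n_counts: dict[str, dict[str, np.ndarray]]
    dropped_unaligned: dict[str, int] = field(default_factory=dict)
    dropped_ties: dict[str, int] = field(default_factory=dict)


@dataclass(slots=True)
class SnpCall:
    """An inter-accession SNP: a site whose genotypes separate the two
    accessions, carrying one distinguishing allele per accession."""

    seq_id: str
    pos: int  # 0-based on the reference sequence
    allele_acc1: str
    allele_acc2: str
    posterior: float
    depth_acc1: int
    depth_acc2: int
    # read support of (allele_acc1, allele_acc2) in each accession
    counts_acc1: tuple[int, int] = (0, 0)
    counts_acc2: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.allele_acc1 == self.allele_acc2:
            raise ValueError("SNP alleles must differ between accessions")
        if not 0.0 <= self.posterior <= 1.0:
            raise ValueError("posterior must be a probability")


def build_pileups(
    reads_by_accession: Mapping[str, Sequence[SeqRecord]],
    reference: Sequence[SeqRecord],
    aligner_params: AlignParams | None = None,
) -> PileupSet:
    """Place every read at its best reference alignment and tally columns.

    Placement is by best local alignment over both strands; only aligned
    (substitution) columns contribute counts, so placement is effectively
    gapless on indel-free data.  A read whose best score is achieved on two
    reference sequences is ambiguous and dropped.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    db = SubjectDatabase(reference, aligner_params)
    counts = {
        acc: {r.id: np.zeros((len(r), 4), dtype=np.int32) for r in reference}
        for acc in reads_by_accession
    }
    n_counts = {
        acc: {r.id: np.zeros(len(r), dtype=np.int32) for r in reference}
        for acc in reads_by_accession
    }
    dropped_unaligned: dict[str, int] = {}
    dropped_ties: dict[str, int] = {}
    for acc, reads in reads_by_accession.items():
        dropped_unaligned[acc] = 0
        dropped_ties[acc] = 0
        for read in reads:
            best = None  # (score, si, hit, qpath, spath)
            tied = False
            for si in db.candidates(read):
                res = db.align(read, si, return_path=True)
                if res is None:
                    continue
                hit, qpath, spath = res
                if best is None or hit.score > best[0]:
                    best = (hit.score, si, hit, qpath, spath)
                    tied = False
                elif hit.score == best[0]:
                    tied = True
            if best is None:
                dropped_unaligned[acc] += 1
                continue
            if tied:
                dropped_ties[acc] += 1
                continue
            _, si, hit, qpath, spath = best
            ref = reference[si]
            q_codes = encode(read.sequence)
            bases = q_codes[qpath]
            if hit.is_reverse:
                # path subject coords refer to the reverse complement
                spos = len(ref) - 1 - spath
                bases = np.where(bases < 4, 3 - bases, 4)
            else:
                spos = spath
            acgt = bases < 4
            np.add.at(counts[acc][ref.id], (spos[acgt], bases[acgt]), 1)
            np.add.at(n_counts[acc][ref.id], spos[~acgt], 1)
    return PileupSet(
        reference_ids=[r.id for r in reference],
        counts=counts,
        n_counts=n_counts,
        dropped_unaligned=dropped_unaligned,
        dropped_ties=dropped_ties,
    )


def genotype_posteriors(column: np.ndarray, model: CallerModel) -> np.ndarray:
    """Posterior over the 10 genotypes for one accession's column of counts.

    ``column`` is a length-4 vector of A/C/G/T counts with depth >= 1.
    """
    column = np.asarray(column)
    if column.ndim != 1 or column.shape[0] != 4:
        raise ValueError("column must be a length-4 count vector")
    if column.sum() < 1:
        raise ValueError("genotyping requires depth >= 1")
    return _posterior_matrix(column[None, :], model)[0]


def _posterior_matrix(counts: np.ndarray, model: CallerModel) -> np.ndarray:
    """Vectorised genotype posteriors for an (L, 4) block of columns."""
    loglik = counts @ model.log_emission().T + model.log_prior()
    loglik -= loglik.max(axis=1, keepdims=True)
    w = np.exp(loglik)
    return w / w.sum(axis=1, keepdims=True)


def _consensus_alleles(counts: np.ndarray) -> np.ndarray:
    """(L, 10) consensus allele per genotype: the genotype's majority allele
    in the column (homozygotes trivially; heterozygote ties break to the
    lexicographically smaller base)."""
    L = counts.shape[0]
    cons = np.empty((L, len(GENOTYPES)), dtype=np.int8)
    for gi, (a, b) in enumerate(GENOTYPES):
        if a == b:
            cons[:, gi] = a
        else:
            cons[:, gi] = np.where(counts[:, b] > counts[:, a], b, a)
    return cons


def _distinguishing_allele(
    own: tuple[int, int], other: tuple[int, int], counts_row: np.ndarray, consensus: int
) -> int:
    """The allele best characterising ``own`` against ``other``: an allele
    unique to ``own`` (the better-supported one on ties), falling back to
    the accession's consensus when its alleles are a subset of the other's."""
    only = sorted(set(own) - set(other))
    if not only:
        return consensus
    return max(only, key=lambda b: counts_row[b])


def call_snps(
    pileups: PileupSet,
    model: CallerModel | None = None,
    accessions: tuple[str, str] = ("acc1", "acc2"),
) -> tuple[list[SnpCall], dict]:
    """Call inter-accession SNPs from a two-accession pileup set.

    Returns (calls, tally).  Each accession's column is genotyped
    independently; a candidate arises wherever the two maximum-posterior
    genotypes differ in allele content -- a fixed difference (AA vs GG) or a
    polymorphism segregating in one accession only (AA vs AG), the latter
    being how residual heterozygosity surfaces in a two-sample comparison.
    The emitted allele for each accession is the allele distinguishing it
    from the other (its consensus allele when its genotype is a subset of
    the other's).  A call is kept when the joint posterior that the two
    genotypes differ reaches ``min_posterior`` and each emitted allele has
    the per-allele minimum read support in its own accession.  Sites where
    more than two alleles have credible (>= 2 read) support are skipped and
    counted.
    """
    model = model or CallerModel()
    a1, a2 = accessions
    calls: list[SnpCall] = []
    tally = {"sites_considered": 0, "multiallelic_skipped": 0, "low_posterior": 0,
             "low_allele_support": 0}
    min_n = model.min_reads_per_allele
    for seq_id in pileups.reference_ids:
        c1 = pileups.counts[a1][seq_id]
        c2 = pileups.counts[a2][seq_id]
        d1 = c1.sum(axis=1)
        d2 = c2.sum(axis=1)
        mask = (d1 > 0) & (d2 > 0)
        if not mask.any():
            continue
        rows = np.nonzero(mask)[0]
        p1 = _posterior_matrix(c1[rows], model)
        p2 = _posterior_matrix(c2[rows], model)
        cons1 = _consensus_alleles(c1[rows])
        cons2 = _consensus_alleles(c2[rows])
        g1 = p1.argmax(axis=1)
        g2 = p2.argmax(axis=1)
        tally["sites_considered"] += int(rows.size)
        for k in np.nonzero(g1 != g2)[0]:
            pos = int(rows[k])
            ga = GENOTYPES[int(g1[k])]
            gb = GENOTYPES[int(g2[k])]
            base1 = _distinguishing_allele(ga, gb, c1[pos], int(cons1[k, g1[k]]))
            base2 = _distinguishing_allele(gb, ga, c2[pos], int(cons2[k, g2[k]]))
            if base1 == base2:  # same allele content sampled differently
                continue
            pooled = c1[pos] + c2[pos]
            if int((pooled >= min_n).sum()) > 2:
                tally["multiallelic_skipped"] += 1
                continue
            # P(the two genotypes differ)
            p_diff = float(1.0 - p1[k] @ p2[k])
            if p_diff < model.min_posterior:
                tally["low_posterior"] += 1
                continue
            if c1[pos, base1] < min_n or c2[pos, base2] < min_n:
                tally["low_allele_support"] += 1
                continue
            calls.append(
                SnpCall(
                    seq_id=seq_id,
                    pos=pos,
                    allele_acc1=_BASES[base1],
                    allele_acc2=_BASES[base2],
                    posterior=p_diff,
                    depth_acc1=int(d1[pos]),
                    depth_acc2=int(d2[pos]),
                    counts_acc1=(int(c1[pos, base1]), int(c1[pos, base2])),
                    counts_acc2=(int(c2[pos, base1]), int(c2[pos, base2])),
                )
            )
    return calls, tally


def snp_calls_to_gff(calls: Sequence[SnpCall]) -> list[SnpGffRecord]:
    """1-based GFF3 records (internal 0-based positions shifted by one)."""
    return [
        SnpGffRecord(
            seq_id=c.seq_id,
            start=c.pos + 1,
            score=c.posterior,
            allele_acc1=c.allele_acc1,
            allele_acc2=c.allele_acc2,
            depth_acc1=c.depth_acc1,
            depth_acc2=c.depth_acc2,
        )
        for c in calls
    ]


def summarise_calls(
    calls: Sequence[SnpCall], brbh_query_ids: set[str] | None = None
) -> dict:
    """Headline counts: total SNPs, SNP-bearing sequences, and SNPs falling
    in sequences that have a reciprocal-best-hit ortholog (when supplied)."""
    seqs = {c.seq_id for c in calls}
    out = {
        "total_snps": len(calls),
        "snp_bearing_sequences": len(seqs),
    }
    if brbh_query_ids is not None:
        out["snps_in_brbh"] = sum(1 for c in calls if c.seq_id in brbh_query_ids)
    return out
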