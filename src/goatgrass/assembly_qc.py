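"""Assembly statistics and reliability diagnostics.

Besides the basic contig statistics (N50, longest, total nucleotides) this
module implements the two reliability checks used to vet de novo transcript
assemblies: the correlation between contig length and the number of reads
that built the contig (a reliable assembly shows a clear positive trend on
log-log axes), and self-alignment redundancy (chimeric, repeated or
erroneously mated contigs surface as significant non-self hits when a contig
set is aligned against itself).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .formats_io import SeqRecord
from .simalign import AlignParams, all_vs_all

__all__ = [
    "AssemblyStats",
    "RedundancyReport",
    "n50",
    "assembly_stats",
    "length_vs_reads",
    "self_redundancy",
]


@dataclass(slots=True)
class AssemblyStats:
    n_sequences: int
    n50: int
    longest: int
    total_nt: int


@dataclass(slots=True)
class RedundancyReport:
    n_sequences: int
    n_significant_nonself_pairs: int
    n_sequences_in_pairs: int

    @property
    def proportion(self) -> float:
        """Percent of contigs participating in >= 1 significant non-self pair."""
        return 100.0 * self.n_sequences_in_pairs / self.n_sequences

    def to_dict(self) -> dict:
        return {
            "n_sequences": self.n_sequences,
            "n_significant_nonself_pairs": self.n_significant_nonself_pairs,
            "n_sequences_in_pairs": self.n_sequences_in_pairs,
            "proportion": self.proportion,
        }


def n50(lengths: Sequence[int]) -> int:
    """The contig length that spans the median nucleotide of the assembly:
    the largest length L in the set such that contigs of length >= L together
    hold at least half the assembly's nucleotides."""
    if not lengths:
        raise ValueError("n50 of an empty assembly is undefined")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    half = arr.sum() / 2.0
    cum = np.cumsum(arr)
    return int(arr[np.searchsorted(cum, half)])


def assembly_stats(contigs: Sequence[SeqRecord]) -> AssemblyStats:
    lengths = [len(c) for c in contigs]
    return AssemblyStats(
        n_sequences=len(contigs),
        n50=n50(lengths),
        longest=max(lengths),
        total_nt=sum(lengths),
    )


def length_vs_reads(
    contigs: Sequence[SeqRecord], reads_per_contig: Mapping[str, int]
) -> dict:
    """Pearson r and Spearman rho of (log length, log read count).

    Every contig must be annotated with the number of constituent reads
    (>= 1); fewer than three contigs leave the coefficients undefined.
    """
    if len(contigs) < 3:
        raise ValueError("length-vs-reads correlation needs at least 3 contigs")
    lengths = []
    counts = []
    for c in contigs:
        n = reads_per_contig.get(c.id, 0)
        if n < 1:
            raise ValueError(f"contig {c.id!r} has no read count")
        lengths.append(len(c))
        counts.append(n)
    log_len = np.log(np.asarray(lengths, dtype=float))
    log_reads = np.log(np.asarray(counts, dtype=float))
    pearson = stats.pearsonr(log_len, log_reads).statistic
    spearman = stats.spearmanr(log_len, log_reads).statistic
    return {
        "pearson_r_loglog": float(pearson),
        "spearman_rho": float(spearman),
        "n": len(contigs),
    }


def self_redundancy(
    contigs: Sequence[SeqRecord],
    aligner_params: AlignParams | None = None,
    max_evalue: float = 1e-10,
    min_query_cov: float = 50.0,
) -> RedundancyReport:
    """All-vs-all of the contig set against itself, self-hits discarded.

    A pair is significant when its best hit passes ``max_evalue`` and covers
    at least ``min_query_cov`` percent of the query; each unordered pair is
    counted once.  The proportion reported is the fraction of contigs that
    participate in at least one significant pair.
    """
    if len(contigs) < 2:
        raise ValueError("self-redundancy needs at least 2 contigs")
    from dataclasses import replace

    params = replace(aligner_params or AlignParams(), max_evalue=max_evalue)
    hits = all_vs_all(list(contigs), list(contigs), params)
    pairs: set[tuple[str, str]] = set()
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.evalue <= max_evalue and h.q_cov is not None and h.q_cov >= min_query_cov:
            pairs.add(tuple(sorted((h.query_id, h.subject_id))))
    in_pairs = {x for pair in pairs for x in pair}
    return RedundancyReport(
        n_sequences=len(contigs),
        n_significant_nonself_pairs=len(pairs),
        n_sequences_in_pairs=len(in_pairs),
    )
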