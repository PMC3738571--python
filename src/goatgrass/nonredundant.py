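"""Greedy identity-threshold clustering of pooled assemblies.

Incremental greedy clustering in the style of CD-HIT-EST: sequences are
visited longest first, each joining the first existing cluster whose
representative aligns at or above the identity threshold over at least 80%
of the shorter sequence, otherwise founding a new cluster.  Representatives
(the longest member of each cluster) form the non-redundant sequence set.
Identity is computed over the local alignment; the shorter-sequence coverage
floor stops short fragments being absorbed by spurious partial matches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .formats_io import SeqRecord
from .simalign import AlignParams, align_pair

__all__ = ["Cluster", "cluster_greedy", "representatives", "threshold_sweep"]

DEFAULT_SWEEP = (70.0, 80.0, 90.0, 95.0, 98.0)


@dataclass(slots=True)
class Cluster:
    representative_id: str
    member_ids: list[str]
    threshold_used: float


def _similar(
    candidate: SeqRecord,
    rep: SeqRecord,
    identity_threshold: float,
    min_short_cov: float,
    params: AlignParams,
) -> bool:
    # candidate is never longer than rep (length-descending processing order),
    # so query coverage is coverage of the shorter sequence
    hit = align_pair(candidate, rep, params)
    return (
        hit is not None
        and hit.pct_identity >= identity_threshold
        and hit.q_cov is not None
        and hit.q_cov >= min_short_cov
    )


def cluster_greedy(
    seqs: Sequence[SeqRecord],
    identity_threshold: float = 90.0,
    min_short_cov: float = 80.0,
    aligner_params: AlignParams | None = None,
) -> list[Cluster]:
    """Greedy first-fit clustering; clusters partition the input.

    The input order is irrelevant: sequences are canonically sorted by
    descending length (ties lexicographic by id) before processing, so the
    representative of every cluster is its longest member.
    """
    if not seqs:
        raise ValueError("cannot cluster an empty sequence set")
    # permissive e-value: membership is decided by identity and coverage
    params = replace(aligner_params or AlignParams(), max_evalue=10.0)
    order = sorted(seqs, key=lambda r: (-len(r), r.id))
    clusters: list[Cluster] = []
    reps: list[SeqRecord] = []
    for rec in order:
        for cluster, rep in zip(clusters, reps):
            if _similar(rec, rep, identity_threshold, min_short_cov, params):
                cluster.member_ids.append(rec.id)
                break
        else:
            clusters.append(Cluster(rec.id, [rec.id], identity_threshold))
            reps.append(rec)
    assert sum(len(c.member_ids) for c in clusters) == len(seqs)
    return clusters


def representatives(
    clusters: Sequence[Cluster], seqs: Sequence[SeqRecord]
) -> list[SeqRecord]:
    """One record per cluster: its longest member (the founder)."""
    by_id = {r.id: r for r in seqs}
    return [by_id[c.representative_id] for c in clusters]


def threshold_sweep(
    seqs: Sequence[SeqRecord],
    thresholds: Sequence[float] = DEFAULT_SWEEP,
    min_short_cov: float = 80.0,
    aligner_params: AlignParams | None = None,
) -> dict[float, int]:
    """Cluster counts across identity thresholds (robustness check: the count
    is non-increasing as the threshold is lowered)."""
    for t in thresholds:
        if not 0 < t <= 100:
            raise ValueError(f"identity threshold {t} outside (0, 100]")
    return {
        t: len(cluster_greedy(seqs, t, min_short_cov, aligner_params))
        for t in sorted(thresholds)
    }
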