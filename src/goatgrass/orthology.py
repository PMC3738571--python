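"""Reciprocal-best-hit orthology, core-ortholog set algebra and map placement.

A best reciprocal hit (BRBH) pair (q, s) is the standard operational proxy
for orthology: s is q's best-scoring partner in the reference set, q is s's
best-scoring partner in the query set, and both directions clear an e-value
ceiling (1e-10 by default).  Unions of BRBH sets across reference collections
measure the breadth of an assembly; the 4-way intersection lattice over four
annotated reference proteomes yields the "core ortholog" set; and BRBH
against genes anchored on a genetic map transfers chromosome/cM positions to
unanchored transcripts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .formats_io import Hit, MapEntry

__all__ = [
    "BrbhPair",
    "CoreSetReport",
    "MapPlacement",
    "best_hit",
    "best_hits_by_query",
    "brbh",
    "unique_hit_union",
    "core_intersection",
    "place_on_map",
]


@dataclass(slots=True)
class BrbhPair:
    query_id: str
    subject_id: str
    ref_set_name: str
    forward_evalue: float
    reciprocal_evalue: float


@dataclass(slots=True)
class CoreSetReport:
    """Counts of the full 15-region inclusion lattice of four BRBH sets,
    keyed by the sorted tuple of set names each region belongs to."""

    set_names: tuple[str, str, str, str]
    region_counts: dict[tuple[str, ...], int]
    union_count: int

    @property
    def core_count(self) -> int:
        return self.region_counts[self.set_names]

    @property
    def core_pct(self) -> float:
        return 100.0 * self.core_count / self.union_count if self.union_count else 0.0

    def to_dict(self) -> dict:
        return {
            "set_names": list(self.set_names),
            "regions": {"+".join(k): v for k, v in sorted(self.region_counts.items())},
            "union_count": self.union_count,
            "core_count": self.core_count,
            "core_pct": self.core_pct,
        }


@dataclass(slots=True)
class MapPlacement:
    query_id: str
    gene_id: str
    chromosome: str
    position_cM: float
    bin_index: int


def _hit_rank(h: Hit) -> tuple:
    # minimal e-value, then higher bitscore, then lexicographic subject id
    return (h.evalue, -h.bitscore, h.subject_id)


def best_hit(hits: Sequence[Hit], max_evalue: float = 1e-10) -> Hit | None:
    """The minimal-e-value hit at or under the ceiling, ties broken by higher
    bitscore then lexicographic subject id.  All hits must share a query."""
    passing = [h for h in hits if h.evalue <= max_evalue]
    if not passing:
        return None
    if len({h.query_id for h in passing}) > 1:
        raise ValueError("best_hit expects hits of a single query")
    return min(passing, key=_hit_rank)


def best_hits_by_query(hits: Iterable[Hit], max_evalue: float) -> dict[str, Hit]:
    by_query: dict[str, Hit] = {}
    for h in hits:
        if h.evalue > max_evalue:
            continue
        cur = by_query.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            by_query[h.query_id] = h
    return by_query


def brbh(
    forward_hits: Iterable[Hit],
    reciprocal_hits: Iterable[Hit],
    max_evalue: float = 1e-10,
    ref_set_name: str = "reference",
) -> list[BrbhPair]:
    """Mutually-best pairs between a query set and a reference set.

    ``forward_hits`` align pipeline sequences against the reference,
    ``reciprocal_hits`` the reference against the pipeline sequences; a pair
    is reported iff each side is the other's best hit under ``max_evalue``.
    Each query appears at most once.  Output sorted by query id.
    """
    fwd = best_hits_by_query(forward_hits, max_evalue)
    rev = best_hits_by_query(reciprocal_hits, max_evalue)
    pairs: list[BrbhPair] = []
    for q, fh in sorted(fwd.items()):
        rh = rev.get(fh.subject_id)
        if rh is not None and rh.subject_id == q:
            pairs.append(
                BrbhPair(
                    query_id=q,
                    subject_id=fh.subject_id,
                    ref_set_name=ref_set_name,
                    forward_evalue=fh.evalue,
                    reciprocal_evalue=rh.evalue,
                )
            )
    return pairs


def unique_hit_union(brbh_sets: Mapping[str, Sequence[BrbhPair]]) -> set[str]:
    """Distinct query ids across all per-reference BRBH sets (the breadth
    measure: how many pipeline sequences have an ortholog anywhere)."""
    if not brbh_sets:
        raise ValueError("need at least one BRBH set")
    return {p.query_id for pairs in brbh_sets.values() for p in pairs}


def core_intersection(brbh_sets: Mapping[str, Sequence[BrbhPair]]) -> CoreSetReport:
    """Full 15-region membership lattice of exactly four BRBH sets, keyed by
    query id; the all-four region is the core ortholog set."""
    if len(brbh_sets) != 4:
        raise ValueError(f"core intersection is defined over 4 sets, got {len(brbh_sets)}")
    names = tuple(sorted(brbh_sets))
    members = {name: {p.query_id for p in brbh_sets[name]} for name in names}
    region_counts: dict[tuple[str, ...], int] = {}
    union = set().union(*members.values())
    for r in range(1, 5):
        for combo in combinations(names, r):
            inside = set.intersection(*(members[n] for n in combo))
            outside = set().union(*(members[n] for n in names if n not in combo)) if r < 4 else set()
            region_counts[combo] = len(inside - outside)
    assert sum(region_counts.values()) == len(union)
    return CoreSetReport(set_names=names, region_counts=region_counts, union_count=len(union))


def place_on_map(
    pairs: Sequence[BrbhPair],
    genetic_map: Sequence[MapEntry],
    bin_width_cM: float = 5.0,
) -> tuple[list[MapPlacement], int]:
    """Transfer map positions to queries through their BRBH partners.

    Returns (placements, n_skipped); queries whose partner is absent from the
    map are skipped with a warning and counted.
    """
    if bin_width_cM <= 0:
        raise ValueError("bin width must be positive")
    by_gene = {e.gene_id: e for e in genetic_map}
    placements: list[MapPlacement] = []
    skipped = 0
    for p in pairs:
        entry = by_gene.get(p.subject_id)
        if entry is None:
            skipped += 1
            continue
        placements.append(
            MapPlacement(
                query_id=p.query_id,
                gene_id=entry.gene_id,
                chromosome=entry.chromosome,
                position_cM=entry.position_cM,
                bin_index=int(math.floor(entry.position_cM / bin_width_cM)),
            )
        )
    if skipped:
        warnings.warn(f"{skipped} BRBH partner(s) absent from the genetic map", stacklevel=2)
    return placements, skipped
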