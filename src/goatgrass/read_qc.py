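"""Sequential read-preprocessing cascade.

Raw long reads pass through an ordered series of per-read filters: a length
floor (size selection above 45 nt), then removal of reads matching a
transposon-repeat library, organelle genomes, and human repeat sequences.
Each stage sees only the survivors of the previous one, and each removal
percentage is reported against the reads *entering* that stage (sequential
denominators), which is the only convention under which the published
per-stage percentages are arithmetically self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Sequence

from .formats_io import SeqRecord
from .simalign import AlignParams, all_vs_all

__all__ = [
    "ScreenRule",
    "StageResult",
    "QcReport",
    "length_filter",
    "screen_by_library",
    "run_cascade",
    "replay_removals",
    "DEFAULT_RULESET",
]

RULE_NAMES = ("short_reads", "triticeae_repeats", "organelle", "human_repeats")


@dataclass(slots=True)
class ScreenRule:
    """One cascade stage: either a length floor or an alignment screen.

    Alignment screens remove a read when it has at least one library hit with
    ``evalue <= max_evalue``, query coverage ``>= min_query_cov`` percent and
    ``pct_identity >= min_identity`` percent.
    """

    name: str
    library: list[SeqRecord] = field(default_factory=list)
    max_evalue: float = 1e-6
    min_query_cov: float = 85.0
    min_identity: float = 85.0
    min_len: int = 46  # short_reads only: keep reads of at least this length

    def __post_init__(self) -> None:
        if self.name not in RULE_NAMES:
            raise ValueError(f"unknown rule name {self.name!r}")
        if not 0 <= self.min_query_cov <= 100 or not 0 <= self.min_identity <= 100:
            raise ValueError("coverage/identity thresholds must be within [0, 100]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


#: The published cascade thresholds: repeats at 85/85, organelle and human at
#: 90/90, all at e-value <= 1e-6, after a >45 nt size selection.
def DEFAULT_RULESET(repeats, organelle, human) -> list[ScreenRule]:
    return [
        ScreenRule("short_reads", min_len=46),
        ScreenRule("triticeae_repeats", library=list(repeats),
                   min_query_cov=85.0, min_identity=85.0),
        ScreenRule("organelle", library=list(organelle),
                   min_query_cov=90.0, min_identity=90.0),
        ScreenRule("human_repeats", library=list(human),
                   min_query_cov=90.0, min_identity=90.0),
    ]


@dataclass(slots=True)
class StageResult:
    name: str
    input_count: int
    removed_count: int

    @property
    def removed_pct(self) -> float:
        if self.input_count == 0:
            return 0.0
        return round(100.0 * self.removed_count / self.input_count, 2)

    @property
    def surviving(self) -> int:
        return self.input_count - self.removed_count


@dataclass(slots=True)
class QcReport:
    input_count: int
    stages: list[StageResult]
    disposition: dict[str, str]  # read id -> "kept" or removing stage name

    @property
    def final_count(self) -> int:
        return self.input_count - sum(s.removed_count for s in self.stages)

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "final_count": self.final_count,
            "stages": [
                {
                    "name": s.name,
                    "input_count": s.input_count,
                    "removed_count": s.removed_count,
                    "removed_pct": s.removed_pct,
                }
                for s in self.stages
            ],
        }


def length_filter(
    reads: Sequence[SeqRecord], min_len: int = 46
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Size selection: removes reads strictly shorter than ``min_len``
    (the published floor removes reads of 45 nt and below)."""
    kept = [r for r in reads if len(r) >= min_len]
    removed = [r for r in reads if len(r) < min_len]
    return kept, removed


def screen_by_library(
    reads: Sequence[SeqRecord],
    rule: ScreenRule,
    aligner_params: AlignParams | None = None,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Remove reads with a qualifying alignment to the rule's library."""
    if not rule.library:
        raise ValueError(f"rule {rule.name!r} has an empty library")
    if not reads:
        return [], []
    params = _dc_replace(aligner_params or AlignParams(), max_evalue=rule.max_evalue)
    hits = all_vs_all(list(reads), rule.library, params)
    flagged = {
        h.query_id
        for h in hits
        if h.evalue <= rule.max_evalue
        and h.q_cov is not None
        and h.q_cov >= rule.min_query_cov
        and h.pct_identity >= rule.min_identity
    }
    kept = [r for r in reads if r.id not in flagged]
    removed = [r for r in reads if r.id in flagged]
    return kept, removed


def run_cascade(
    reads: Sequence[SeqRecord],
    rules: Sequence[ScreenRule],
    aligner_params: AlignParams | None = None,
) -> tuple[list[SeqRecord], QcReport]:
    """Run the ordered rule cascade; returns (survivors, report).

    A read matching several libraries is attributed to the first stage that
    removes it, so stage counts never double-count and always satisfy
    ``input(stage k+1) == input(stage k) - removed(stage k)``.
    """
    current = list(reads)
    stages: list[StageResult] = []
    disposition = {r.id: "kept" for r in current}
    for rule in rules:
        entering = len(current)
        if rule.name == "short_reads":
            kept, removed = length_filter(current, rule.min_len)
        else:
            kept, removed = screen_by_library(current, rule, aligner_params)
        for r in removed:
            disposition[r.id] = rule.name
        stages.append(StageResult(rule.name, entering, len(removed)))
        current = kept
    report = QcReport(input_count=len(reads), stages=stages, disposition=disposition)
    assert report.final_count == len(current)
    return current, report


def replay_removals(raw_count: int, removals: Sequence[tuple[str, int]]) -> QcReport:
    """Sequential accounting from externally supplied per-stage removal counts
    (e.g. a published preprocessing table, whose adapter-clipping stage we do
    not recompute).  Returns the same report type as :func:`run_cascade`."""
    stages: list[StageResult] = []
    entering = raw_count
    for name, removed in removals:
        if removed < 0 or removed > entering:
            raise ValueError(f"stage {name!r}: removal count {removed} out of range")
        stages.append(StageResult(name, entering, removed))
        entering -= removed
    return QcReport(input_count=raw_count, stages=stages, disposition={})
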