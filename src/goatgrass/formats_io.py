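"""Readers and writers for every on-disk format the pipeline touches.

All other modules exchange in-memory records; this module is the only place
that knows about FASTA/FASTQ, 12-column tabular similarity-hit files, GFF3,
genetic-map TSVs and domain/annotation tables.

Coordinate conventions
----------------------
Internal coordinates are 0-based half-open.  Everything written to disk
(hit tables, GFF3) is 1-based inclusive, matching the conventions of the
tools these formats come from.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SeqRecord",
    "Hit",
    "MapEntry",
    "SnpGffRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "read_hit_table",
    "write_hit_table",
    "write_snp_gff",
    "read_snp_gff",
    "read_genetic_map",
    "write_genetic_map",
    "read_domain_table",
    "write_domain_table",
    "read_annotation_table",
    "write_annotation_table",
    "write_json_report",
]

IUPAC_DNA = set("ACGTN")

SOURCE_LABELS = frozenset({"read", "contig", "isotig", "reference", "contaminant"})


class FormatError(ValueError):
    """Raised on malformed or invariant-violating input files."""


@dataclass(slots=True)
class SeqRecord:
    """An identified nucleotide sequence (read, contig, isotig, reference gene).

    ``sequence`` is uppercase IUPAC DNA restricted to A, C, G, T, N.
    """

    id: str
    sequence: str
    description: str = ""
    source_label: str = "read"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        if len(self.sequence) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")
        if self.source_label not in SOURCE_LABELS:
            raise FormatError(f"unknown source_label {self.source_label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(slots=True)
class Hit:
    """One pairwise similarity alignment in the 12-column tabular dialect.

    Coordinates are 1-based inclusive; reverse-strand alignments carry
    ``s_start > s_end``.  ``q_cov`` (percent of the query length aligned) is
    always recomputed internally from the query length, never read from disk,
    so externally produced and internally produced tables are interchangeable.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    q_cov: float | None = None
    score: float | None = None  # raw alignment score (internal aligner only)

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: q_start > q_end"
            )
        if not 0.0 <= self.pct_identity <= 100.0:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: identity out of [0,100]"
            )
        if self.evalue < 0:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: negative e-value"
            )

    @property
    def is_reverse(self) -> bool:
        return self.s_start > self.s_end

    def with_query_cov(self, query_length: int) -> "Hit":
        self.q_cov = 100.0 * (self.q_end - self.q_start + 1) / query_length
        return self


@dataclass(slots=True)
class MapEntry:
    """One gene anchored on a genetic map (chromosome + centimorgan position)."""

    gene_id: str
    chromosome: str
    position_cM: float

    def __post_init__(self) -> None:
        if self.position_cM < 0 or self.position_cM != self.position_cM:
            raise FormatError(f"map entry {self.gene_id!r}: bad cM position")


@dataclass(slots=True)
class SnpGffRecord:
    """A single-nucleotide variant line for GFF3 export (1-based, start == end)."""

    seq_id: str
    start: int
    score: float
    allele_acc1: str
    allele_acc2: str
    depth_acc1: int
    depth_acc2: int
    source: str = "goatgrass"

    def __post_init__(self) -> None:
        if self.allele_acc1 == self.allele_acc2:
            raise FormatError("SNP record alleles must differ")
        for a in (self.allele_acc1, self.allele_acc2):
            if a not in "ACGT":
                raise FormatError(f"bad SNP allele {a!r}")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _check_unique_ids(records: Sequence[SeqRecord], path) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


def read_fasta(path, source_label: str = "read") -> list[SeqRecord]:
    """Load a FASTA file; ids are the first whitespace token of each header.

    Duplicate ids are a hard error; an empty file yields an empty list with
    a warning.
    """
    records = [
        SeqRecord(
            id=r.id,
            sequence=str(r.seq),
            description=r.description[len(r.id):].strip(),
            source_label=source_label,
        )
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
    _check_unique_ids(records, path)
    return records


def read_fastq(path, source_label: str = "read") -> list[SeqRecord]:
    """Load a FASTQ file.  Per-base qualities are discarded: downstream
    filters only ever look at read length and N content."""
    records = [
        SeqRecord(id=r.id, sequence=str(r.seq), source_label=source_label)
        for r in SeqIO.parse(str(path), "fastq")
    ]
    if not records:
        warnings.warn(f"{path}: empty FASTQ file", stacklevel=2)
    _check_unique_ids(records, path)
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# 12-column tabular similarity-hit files (the classic tab-separated layout:
# query, subject, %identity, length, mismatches, gap opens, qstart, qend,
# sstart, send, evalue, bitscore)


def read_hit_table(path, query_lengths: Mapping[str, int] | None = None) -> list[Hit]:
    """Parse a whitespace/tab-separated 12-column hit table.

    ``q_cov`` is computed from ``query_lengths`` where the query is known and
    left ``None`` (flagged unknown) otherwise.  A malformed row raises
    :class:`FormatError` naming the line number.
    """
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, found {len(parts)}"
                )
            try:
                hit = Hit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    pct_identity=float(parts[2]),
                    aln_len=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if query_lengths is not None and hit.query_id in query_lengths:
                hit.with_query_cov(query_lengths[hit.query_id])
            hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[Hit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t{h.aln_len}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}\t"
                f"{h.s_start}\t{h.s_end}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 SNP export


def write_snp_gff(records: Iterable[SnpGffRecord], path) -> None:
    """Write SNPs as GFF3, one line per site, sorted by (seq_id, start)."""
    rows = sorted(records, key=lambda r: (r.seq_id, r.start))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            attrs = (
                f"allele_acc1={r.allele_acc1};allele_acc2={r.allele_acc2};"
                f"depth_acc1={r.depth_acc1};depth_acc2={r.depth_acc2}"
            )
            fh.write(
                f"{r.seq_id}\t{r.source}\tSNP\t{r.start}\t{r.start}\t"
                f"{r.score:.4f}\t.\t.\t{attrs}\n"
            )


def read_snp_gff(path) -> list[SnpGffRecord]:
    out: list[SnpGffRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if kv)
            out.append(
                SnpGffRecord(
                    seq_id=parts[0],
                    source=parts[1],
                    start=int(parts[3]),
                    score=float(parts[5]),
                    allele_acc1=attrs["allele_acc1"],
                    allele_acc2=attrs["allele_acc2"],
                    depth_acc1=int(attrs["depth_acc1"]),
                    depth_acc2=int(attrs["depth_acc2"]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Genetic map TSV (gene_id, chromosome, cM)


def read_genetic_map(path) -> list[MapEntry]:
    entries: list[MapEntry] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene_id", "chromosome", "cM"]:
            raise FormatError(f"{path}: expected header gene_id<TAB>chromosome<TAB>cM")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            gene_id, chrom, cm = parts
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                entry = MapEntry(gene_id, chrom, float(cm))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            entries.append(entry)
    return entries


def write_genetic_map(entries: Iterable[MapEntry], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchromosome\tcM\n")
        for e in entries:
            fh.write(f"{e.gene_id}\t{e.chromosome}\t{e.position_cM:g}\n")


# ---------------------------------------------------------------------------
# Domain-hit and annotation tables (consumed by the resistance-gene module)


def read_domain_table(path):
    """TSV of (seq_id, profile_name, profile_class, domain_evalue, start, end).

    Returns :class:`goatgrass.rgenes.DomainHit` records; coordinates in the
    file are 0-based half-open, as produced by :func:`write_domain_table`.
    """
    from .rgenes import DomainHit  # local import: avoid cycle

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            try:
                out.append(
                    DomainHit(
                        seq_id=parts[0],
                        profile_name=parts[1],
                        profile_class=parts[2],
                        domain_evalue=float(parts[3]),
                        env_start=int(parts[4]),
                        env_end=int(parts[5]),
                    )
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_domain_table(hits, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.profile_name}\t{h.profile_class}\t"
                f"{h.domain_evalue:.3g}\t{h.env_start}\t{h.env_end}\n"
            )


def read_annotation_table(path) -> dict[str, list[str]]:
    """TSV of (seq_id, term description); one row per term, grouped by id."""
    terms: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            terms.setdefault(parts[0], []).append(parts[1])
    return terms


def write_annotation_table(terms: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        for seq_id in sorted(terms):
            for term in terms[seq_id]:
                fh.write(f"{seq_id}\t{term}\n")


# ---------------------------------------------------------------------------


def write_json_report(report, path) -> None:
    """Serialise a report dataclass (or plain mapping) as indented JSON."""
    if hasattr(report, "to_dict"):
        payload = report.to_dict()
    elif hasattr(report, "__dataclass_fields__"):
        payload = asdict(report)
    else:
        payload = report
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
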