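"""Synthetic transcript universes with planted, fully-known ground truth.

The generator emulates the data a normalised-cDNA long-read survey of a wild
diploid grass produces:

* a focal species' leaf transcript set, plus diverged ortholog sets standing
  in for reference proteomes/unigene collections of related species;
* two accessions of the focal species separated by a configurable per-site
  SNP density, each diploid with a configurable fraction of genes carrying
  two distinct haplotypes (residual heterozygosity / recent outcrossing);
* long reads (default 300-800 nt) with substitution errors, a short-read
  tail, and ambiguous bases (N) skewed to the 3' half of the read, as 454
  pyrosequencing chemistry produces;
* contaminant read classes (transposon repeats, organelle DNA, human-like
  repeats) spiked in at configurable fractions.

Everything is deterministic under ``SimConfig.seed``; all downstream
recovery tests read planted truth from :class:`TruthSet` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .formats_io import MapEntry, SeqRecord
from .simalign import revcomp

__all__ = [
    "SimConfig",
    "TruthSet",
    "ReadOrigin",
    "ReadSet",
    "generate_universe",
    "simulate_reads",
    "spike_contaminants",
    "pseudo_assembly",
    "read_counts",
    "synthetic_genetic_map",
    "synthetic_annotations",
    "mean_reads_per_gene_for_coverage",
]

ACCESSIONS = ("acc1", "acc2")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
CONTAMINANT_CLASSES = ("repeat", "organelle", "human")


@dataclass(frozen=True, slots=True)
class SimConfig:
    """Study conditions for the synthetic universe.

    Defaults mirror the sequencing survey the package models: insert sizes
    of 600-800 bp give reads of 300-800 nt, ~4% of reads fall at or below
    the 45 nt size-selection floor, contaminant classes appear at sub-percent
    levels, and the two accessions differ at ~2 SNPs per kilobase with very
    different residual heterozygosity (1.6% vs 30% of genes).
    """

    seed: int
    n_genes: int = 100
    n_species: int = 5
    gene_len_range: tuple[int, int] = (600, 1600)
    paralog_family_rate: float = 0.05
    paralog_divergence: float = 0.10
    ortholog_divergence: float = 0.05
    snp_rate: float = 0.002
    het_fraction_acc1: float = 0.016
    het_fraction_acc2: float = 0.30
    het_site_rate: float = 0.01
    read_len_range: tuple[int, int] = (300, 800)
    reads_per_gene_mean: float = 20.0
    error_rate: float = 0.005
    n_rate_3prime: float = 0.0026
    n_3prime_skew: float = 0.919
    short_read_fraction: float = 0.04
    contaminant_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"repeat": 0.007, "organelle": 0.007, "human": 0.0002}
    )
    nbarc_gene_fraction: float = 0.05
    lrr_given_nbarc_fraction: float = 0.25
    n_chromosomes: int = 3
    map_length_cM: float = 150.0

    def __post_init__(self) -> None:
        for name in (
            "paralog_family_rate", "paralog_divergence", "ortholog_divergence",
            "snp_rate", "het_fraction_acc1", "het_fraction_acc2", "het_site_rate",
            "error_rate", "n_rate_3prime", "n_3prime_skew", "short_read_fraction",
            "nbarc_gene_fraction", "lrr_given_nbarc_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.read_len_range
        if not (45 < lo <= hi <= 828):
            raise ValueError("read_len_range must lie within (45, 828]")
        if self.n_species < 2:
            raise ValueError("need the focal species plus >= 1 reference species")
        for k in self.contaminant_fractions:
            if k not in CONTAMINANT_CLASSES:
                raise ValueError(f"unknown contaminant class {k!r}")


@dataclass(slots=True)
class ReadOrigin:
    """Provenance of one simulated read (gene coordinates, 0-based half-open)."""

    accession: str
    gene_id: str | None  # None for contaminants
    haplotype: int
    start: int
    end: int
    strand: int
    label: str = "transcript"  # or a contaminant class


@dataclass(slots=True)
class ReadSet:
    reads_by_accession: dict[str, list[SeqRecord]]
    provenance: dict[str, ReadOrigin]

    def labels(self) -> dict[str, str]:
        return {rid: o.label for rid, o in self.provenance.items()}


@dataclass(slots=True)
class TruthSet:
    """Planted ground truth for one synthetic universe."""

    config: SimConfig
    # species index (1 = focal) -> {reference gene id -> sequence}
    species_genes: dict[int, dict[str, str]]
    gene_ids: list[str]  # focal-species gene ids, includes paralog copies
    ortholog_of: dict[int, dict[str, str]]  # species -> {focal gene -> ref gene id}
    paralog_parent: dict[str, str]  # paralog copy -> founding gene
    # accession -> {gene -> (hapA, hapB)}; hapA is the accession consensus
    haplotypes: dict[str, dict[str, tuple[str, str]]]
    # gene -> {0-based pos -> (acc1 allele, acc2 allele)}
    snp_positions: dict[str, dict[int, tuple[str, str]]]
    # accession -> {gene -> {0-based pos -> (consensus allele, alternate allele)}}
    het_sites: dict[str, dict[str, dict[int, tuple[str, str]]]]
    het_genes: dict[str, set[str]]
    contaminant_libraries: dict[str, list[SeqRecord]]
    nbarc_genes: set[str]
    nblrr_genes: set[str]
    map_assignment: dict[str, tuple[str, float]]  # focal gene -> (chromosome, cM)

    @property
    def focal_genes(self) -> dict[str, str]:
        return self.species_genes[1]

    def reference_set(self, species: int) -> list[SeqRecord]:
        return [
            SeqRecord(gid, seq, source_label="reference")
            for gid, seq in sorted(self.species_genes[species].items())
        ]


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, length, dtype=np.int64)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Substitute each site independently at ``rate``; returns (mutant, positions)."""
    out = codes.copy()
    pos = np.nonzero(rng.random(codes.shape[0]) < rate)[0]
    if pos.size:
        out[pos] = (out[pos] + rng.integers(1, 4, pos.size)) % 4
    return out, pos


def generate_universe(config: SimConfig) -> TruthSet:
    """Build the multi-species transcript universe and plant all truth.

    Species ``k >= 2`` derive from the focal species by independent per-site
    substitution at ``ortholog_divergence``; paralog copies arise within the
    focal species at ``paralog_family_rate`` and diverge at
    ``paralog_divergence``.  Accession 2 differs from accession 1 at
    ``snp_rate`` per site, and within each accession a configurable fraction
    of genes carries a second haplotype diverged at ``het_site_rate``.
    """
    from .rgenes import NBARC_CONSENSUS, LRR_CONSENSUS  # motif definitions live with the scanner

    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.gene_len_range
    width = max(4, len(str(config.n_genes)))

    gene_ids = [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    base_genes: dict[str, np.ndarray] = {
        gid: _random_dna(rng, int(rng.integers(lo, hi + 1))) for gid in gene_ids
    }

    # resistance-gene mimicry: embed degenerate domain motifs in a subset
    n_nbarc = round(config.nbarc_gene_fraction * config.n_genes)
    nbarc_genes = set(
        rng.choice(gene_ids, size=n_nbarc, replace=False).tolist() if n_nbarc else []
    )
    n_nblrr = round(config.lrr_given_nbarc_fraction * len(nbarc_genes))
    nblrr_genes = set(
        rng.choice(sorted(nbarc_genes), size=n_nblrr, replace=False).tolist()
        if n_nblrr
        else []
    )
    nbarc_codes = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in NBARC_CONSENSUS])
    lrr_codes = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in LRR_CONSENSUS])
    for gid in sorted(nbarc_genes):
        g = base_genes[gid]
        motif, _ = _mutate(rng, nbarc_codes, 0.10)
        start = int(rng.integers(0, len(g) // 2 - len(motif)))
        g[start:start + len(motif)] = motif
        if gid in nblrr_genes:
            motif2, _ = _mutate(rng, lrr_codes, 0.10)
            start2 = int(rng.integers(len(g) // 2, len(g) - len(motif2)))
            g[start2:start2 + len(motif2)] = motif2

    # paralog copies inside the focal species
    paralog_parent: dict[str, str] = {}
    for gid in gene_ids:
        if rng.random() < config.paralog_family_rate:
            copy, _ = _mutate(rng, base_genes[gid], config.paralog_divergence)
            pid = f"{gid}p"
            paralog_parent[pid] = gid
            base_genes[pid] = copy
    all_gene_ids = gene_ids + sorted(paralog_parent)

    species_genes: dict[int, dict[str, str]] = {
        1: {gid: _to_str(codes) for gid, codes in base_genes.items()}
    }
    ortholog_of: dict[int, dict[str, str]] = {}
    for k in range(2, config.n_species + 1):
        genes_k: dict[str, str] = {}
        orth_k: dict[str, str] = {}
        for gid in gene_ids:  # paralog copies have no cross-species partner
            mutant, _ = _mutate(rng, base_genes[gid], config.ortholog_divergence)
            ref_id = f"sp{k}_{gid}"
            genes_k[ref_id] = _to_str(mutant)
            orth_k[gid] = ref_id
        species_genes[k] = genes_k
        ortholog_of[k] = orth_k

    # two-accession consensus + within-accession haplotypes
    snp_positions: dict[str, dict[int, tuple[str, str]]] = {}
    haplotypes: dict[str, dict[str, tuple[str, str]]] = {a: {} for a in ACCESSIONS}
    het_sites: dict[str, dict[str, dict[int, tuple[str, str]]]] = {a: {} for a in ACCESSIONS}
    het_fraction = {
        "acc1": config.het_fraction_acc1,
        "acc2": config.het_fraction_acc2,
    }
    het_genes: dict[str, set[str]] = {a: set() for a in ACCESSIONS}
    for gid in all_gene_ids:
        acc1_cons = base_genes[gid]
        acc2_cons, pos = _mutate(rng, acc1_cons, config.snp_rate)
        snp_positions[gid] = {
            int(p): (_to_str(acc1_cons[p:p + 1]), _to_str(acc2_cons[p:p + 1]))
            for p in pos
        }
        for acc, cons in (("acc1", acc1_cons), ("acc2", acc2_cons)):
            if rng.random() < het_fraction[acc]:
                hap_b, hpos = _mutate(rng, cons, config.het_site_rate)
                while hpos.size == 0:  # a het gene must differ somewhere
                    hap_b, hpos = _mutate(rng, cons, config.het_site_rate)
                het_genes[acc].add(gid)
                het_sites[acc][gid] = {
                    int(p): (_to_str(cons[p:p + 1]), _to_str(hap_b[p:p + 1]))
                    for p in hpos
                }
            else:
                hap_b = cons
                het_sites[acc][gid] = {}
            haplotypes[acc][gid] = (_to_str(cons), _to_str(hap_b))

    # contaminant libraries: transposon repeats, organelle genomes, human repeats
    contaminant_libraries = {
        "repeat": [
            SeqRecord(f"rep{i}", _to_str(_random_dna(rng, 2000)), source_label="contaminant")
            for i in range(8)
        ],
        "organelle": [
            SeqRecord(f"org{i}", _to_str(_random_dna(rng, 3000)), source_label="contaminant")
            for i in range(4)
        ],
        "human": [
            SeqRecord(f"hum{i}", _to_str(_random_dna(rng, 2000)), source_label="contaminant")
            for i in range(4)
        ],
    }

    chroms = [f"{i}H" for i in range(1, config.n_chromosomes + 1)]
    map_assignment = {
        gid: (chroms[int(rng.integers(0, len(chroms)))], float(np.round(rng.uniform(0, config.map_length_cM), 2)))
        for gid in gene_ids
    }

    return TruthSet(
        config=config,
        species_genes=species_genes,
        gene_ids=all_gene_ids,
        ortholog_of=ortholog_of,
        paralog_parent=paralog_parent,
        haplotypes=haplotypes,
        snp_positions=snp_positions,
        het_sites=het_sites,
        het_genes=het_genes,
        contaminant_libraries=contaminant_libraries,
        nbarc_genes=nbarc_genes,
        nblrr_genes=nblrr_genes,
        map_assignment=map_assignment,
    )


def _apply_read_noise(rng: np.random.Generator, codes: np.ndarray, config: SimConfig) -> str:
    """Substitution errors plus 3'-skewed ambiguous bases on a finished read."""
    out, _ = _mutate(rng, codes, config.error_rate)
    length = out.shape[0]
    half = length // 2
    rate_3p = config.n_rate_3prime
    skew = config.n_3prime_skew
    rate_5p = rate_3p * (1.0 - skew) / skew if skew > 0 else 0.0
    seq = _to_str(out)
    if rate_3p > 0:
        mask = np.zeros(length, dtype=bool)
        mask[:half] = rng.random(half) < rate_5p
        mask[half:] = rng.random(length - half) < rate_3p
        if mask.any():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            arr[mask] = ord("N")
            seq = arr.tobytes().decode("ascii")
    return seq


def simulate_reads(truth: TruthSet, config: SimConfig | None = None) -> ReadSet:
    """Draw reads for both accessions from the planted haplotypes.

    Read counts per gene are Poisson; fragments anchor with equal probability
    at the 5' or 3' transcript end and are truncated at the boundary, so
    expected coverage is flat along the transcript body, matching the absence
    of positional bias in randomly primed normalised cDNA.  A configurable
    fraction of reads falls at or below the 45 nt size-selection floor.
    Heterozygous genes emit reads from their two haplotypes at 1:1.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 2])
    lo, hi = config.read_len_range
    mean_gene_len = (config.gene_len_range[0] + config.gene_len_range[1]) / 2.0
    reads_by_accession: dict[str, list[SeqRecord]] = {a: [] for a in ACCESSIONS}
    provenance: dict[str, ReadOrigin] = {}
    counter = {a: 0 for a in ACCESSIONS}
    for acc in ACCESSIONS:
        for gid in truth.gene_ids:
            hap_a, hap_b = truth.haplotypes[acc][gid]
            gene_len = len(hap_a)
            # longer transcripts yield proportionally more fragments, keeping
            # fold-coverage roughly constant across genes
            n_reads = rng.poisson(config.reads_per_gene_mean * gene_len / mean_gene_len)
            for _ in range(n_reads):
                if rng.random() < config.short_read_fraction:
                    nominal = int(rng.integers(20, 46))
                else:
                    nominal = int(rng.integers(lo, hi + 1))
                nominal = min(nominal, gene_len)
                if rng.random() < 0.5:  # 5'-anchored fragment
                    start = int(rng.integers(0, max(1, gene_len - 45 + 1)))
                    end = min(gene_len, start + nominal)
                else:  # 3'-anchored fragment
                    end = int(rng.integers(min(45, gene_len), gene_len + 1))
                    start = max(0, end - nominal)
                hap_idx = int(rng.random() < 0.5)
                hap = (hap_a, hap_b)[hap_idx]
                frag = np.frombuffer(hap[start:end].encode(), dtype=np.uint8)
                codes = np.searchsorted(_BASES, frag)
                strand = 1 if rng.random() < 0.5 else -1
                seq = _apply_read_noise(rng, codes, config)
                if strand == -1:
                    seq = revcomp(seq)
                counter[acc] += 1
                rid = f"{acc}_r{counter[acc]:06d}"
                reads_by_accession[acc].append(
                    SeqRecord(rid, seq, source_label="read")
                )
                provenance[rid] = ReadOrigin(
                    accession=acc, gene_id=gid, haplotype=hap_idx,
                    start=start, end=end, strand=strand,
                )
    return ReadSet(reads_by_accession=reads_by_accession, provenance=provenance)


def spike_contaminants(
    readset: ReadSet, truth: TruthSet, config: SimConfig | None = None
) -> ReadSet:
    """Insert contaminant reads at the configured per-class fractions.

    Contaminant counts are binomial in the transcript read count; every read
    carries a provenance label, so labels partition the final read set.
    Fractions summing above 0.5 are rejected as unrealistic.
    """
    config = config or truth.config
    if sum(config.contaminant_fractions.values()) > 0.5:
        raise ValueError("contaminant fractions sum above 0.5; not a plausible library")
    rng = np.random.default_rng([config.seed, 3])
    lo, hi = config.read_len_range
    for acc in ACCESSIONS:
        reads = readset.reads_by_accession[acc]
        n_transcript = len(reads)
        for cls in CONTAMINANT_CLASSES:
            frac = config.contaminant_fractions.get(cls, 0.0)
            if frac <= 0:
                continue
            n_spike = int(rng.binomial(n_transcript, frac))
            library = truth.contaminant_libraries[cls]
            for i in range(n_spike):
                src = library[int(rng.integers(0, len(library)))]
                length = min(int(rng.integers(lo, hi + 1)), len(src))
                start = int(rng.integers(0, len(src) - length + 1))
                codes = np.searchsorted(
                    _BASES, np.frombuffer(src.sequence[start:start + length].encode(), dtype=np.uint8)
                )
                seq = _apply_read_noise(rng, codes, config)
                rid = f"{acc}_{cls}{i + 1:05d}"
                reads.append(SeqRecord(rid, seq, source_label="read"))
                readset.provenance[rid] = ReadOrigin(
                    accession=acc, gene_id=None, haplotype=0,
                    start=start, end=start + length, strand=1, label=cls,
                )
        # deterministic interleaving: shuffle so contaminants are not a suffix
        order = rng.permutation(len(reads))
        readset.reads_by_accession[acc] = [reads[i] for i in order]
    return readset


def pseudo_assembly(truth: TruthSet) -> list[SeqRecord]:
    """Contig set standing in for a de novo assembly: one contig per focal
    gene, equal to the accession-1 consensus.  External assemblers are out of
    scope; any contig FASTA from a real assembler can be used instead."""
    return [
        SeqRecord(gid, truth.haplotypes["acc1"][gid][0], source_label="contig")
        for gid in truth.gene_ids
    ]


def read_counts(readset: ReadSet) -> dict[str, int]:
    """Transcript reads per gene, for the length-vs-reads diagnostic."""
    counts: dict[str, int] = {}
    for origin in readset.provenance.values():
        if origin.gene_id is not None:
            counts[origin.gene_id] = counts.get(origin.gene_id, 0) + 1
    return counts


def synthetic_genetic_map(truth: TruthSet, species: int = 2) -> list[MapEntry]:
    """Genetic map over one reference species' genes, using the planted
    chromosome/cM assignment of their focal orthologs."""
    entries = []
    for gid, ref_id in sorted(truth.ortholog_of[species].items()):
        chrom, cm = truth.map_assignment[gid]
        entries.append(MapEntry(ref_id, chrom, cm))
    return entries


def synthetic_annotations(truth: TruthSet, config: SimConfig | None = None) -> dict[str, list[str]]:
    """Annotation-term table emulating a homology-transfer annotation run.

    Most NB-LRR genes receive a matching lexical term, but some do not
    (novel family members escape homology annotation) and a few non-motif
    genes do (already-sequenced homologues assembled without their domains),
    so the lexical and domain-cascade routes genuinely disagree in part.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 4])
    generic = [
        "chlorophyll a-b binding protein",
        "serine/threonine protein kinase",
        "ribulose bisphosphate carboxylase small chain",
        "ubiquitin-conjugating enzyme",
        "leucine-rich repeat receptor kinase",  # lexically close but must NOT match
    ]
    annotations: dict[str, list[str]] = {}
    focal = [g for g in truth.gene_ids]
    for gid in focal:
        terms: list[str] = []
        if gid in truth.nblrr_genes:
            if rng.random() < 0.7:
                terms.append("NB-LRR disease resistance protein")
        elif gid not in truth.nbarc_genes and rng.random() < 0.02:
            terms.append("putative NB-LRR resistance protein homolog")
        if rng.random() < 0.8:
            terms.append(generic[int(rng.integers(0, len(generic)))])
        if terms:
            annotations[gid] = terms
    return annotations


def mean_reads_per_gene_for_coverage(config: SimConfig, coverage: float) -> float:
    """Poisson read mean per gene that yields roughly ``coverage`` fold depth
    mid-transcript, given the configured read/gene length distributions."""
    lo, hi = config.read_len_range
    glo, ghi = config.gene_len_range
    mean_len = (lo + hi) / 2.0
    mean_gene = (glo + ghi) / 2.0
    # expected clipped read length under boundary-anchored fragments
    over = max(0.0, mean_len - 45)
    span = max(1.0, mean_gene - 45)
    e_clip = mean_len - (over * over) / (2.0 * span) if over < span else (mean_gene + 45) / 2.0
    e_clip = (1 - config.short_read_fraction) * e_clip + config.short_read_fraction * 32.5
    return coverage * mean_gene / e_clip
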