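# Methods

This note documents the models, decision rules, numerical choices and
limitations behind `goatgrass`.  It is written for a reader who wants to
know exactly what each stage computes and what the synthetic benchmarks do
and do not demonstrate.

## Pairwise alignment engine

All similarity search inside the package runs on a self-contained seeded
local aligner rather than an external tool, so results are reproducible
from the repository alone and hit tables from real search tools can still
be imported through `formats_io.read_hit_table` (query coverage is always
recomputed from query length, never trusted from the file, which makes the
two sources interchangeable).

The engine finds exact shared k-mers (default k = 12; minimum 8) between
the query and both strands of the subject, groups the implied diagonals
into clusters separated by more than twice the band padding, and runs a
banded affine-gap Smith–Waterman (numba-compiled) over each cluster with
±16 diagonals of padding.  Scoring is match +1, mismatch −2, and a gap of
length L costs −5 − 2L.  On any pair whose full dynamic-programming matrix
has at most 65,536 cells the band is widened to the whole matrix, so small
instances are exact unrestricted local alignments regardless of seeding;
on larger pairs a pair without a seed is reported as no hit.  Ties in the
matrix are resolved deterministically (first-best cell in row-major order;
diagonal moves preferred in traceback), so outputs are stable across runs
and platforms.

Significance uses the ungapped Karlin–Altschul form E = K·m·n·e^(−λS)
with λ = 1.33 and K = 0.621, the classical values for +1/−2 nucleotide
scoring.  These e-values are a *ranking device*: the package makes no
claim that they match any external tool bit-for-bit, which is why every
threshold quoted from the study (10⁻⁶ for contamination screens, 10⁻¹⁰ for
reciprocal best hits) is an explicit, configurable parameter rather than a
constant.

Assumption to keep in mind: with substitution-only synthetic data the
banded path is effectively exact; on indel-rich real data the band padding
(16) bounds the detectable gap offset per seeded cluster.

## Read screening cascade

Stages run in a fixed order — length floor, transposon repeats, organelle,
human repeats — and each stage sees only the survivors of the previous
one.  A read is removed by an alignment screen iff some library hit has
e ≤ 10⁻⁶, query coverage and identity at or above the stage thresholds
(85/85 for repeats, 90/90 for organelle and human).  Removal percentages
are reported against the reads *entering* the stage: this
sequential-denominator convention is the only one under which the
published per-stage percentages are arithmetically self-consistent, and it
is what `replay_removals` reproduces.  Adapter clipping happens upstream
of this package (reads arrive clipped), so the clipping row of a
preprocessing table is replayed as an externally supplied count.  A read
matching several libraries is attributed to the first stage that removes
it.  Because every screen is a pure per-read predicate, permuting stages
can change per-stage counts but never the identity of the final survivor
set.

## Assembly QC

N50 is the largest contig length L in the set such that contigs of length
≥ L together contain at least half the assembly's nucleotides ("the contig
spanning the median nucleotide").  The length-vs-reads diagnostic reports
Pearson r and Spearman ρ on (log length, log read count) and refuses
fewer than three contigs.  Self-redundancy aligns the contig set against
itself, discards self-hits, counts each unordered pair once, and reports
the percentage of contigs participating in at least one significant pair.
"Significant" defaults to e ≤ 10⁻¹⁰ with ≥ 50% query coverage — the
source study states no threshold, so the reciprocal-best-hit significance
level was adopted; both knobs are parameters.  The denominator choice
(fraction of *sequences* in pairs, not pairs over possible pairs) is
likewise a documented package decision.

## Orthology

`best_hit` takes the minimal e-value at or under the ceiling, breaking
ties by higher bitscore then lexicographic subject id; this total order
makes reciprocal-best-hit detection deterministic even when the underlying
search reports ties, a case the source methods leave unspecified.  A BRBH
pair requires mutual bests under e ≤ 10⁻¹⁰ in both directions.  Venn
regions of four reference sets are keyed by query id only — a query
counts once per reference set regardless of which subject it pairs with —
because the quantity of interest is how many *transcripts* have orthologs,
not how many pairs exist.  Map placement transfers the BRBH partner's
chromosome and cM position and bins at floor(cM / bin width), default
5 cM.

## Non-redundant clustering

Greedy incremental clustering in decreasing length order (ties broken
lexicographically, so input order is irrelevant): each sequence joins the
first existing cluster whose representative aligns at ≥ 90% identity over
≥ 80% of the shorter sequence, else founds a new cluster.  Identity is
computed over the local alignment; the shorter-sequence coverage floor
prevents short fragments being absorbed by partial matches.  First-fit
(not best-fit) assignment matches the greedy tools used in this field.  A
consequence tested explicitly: representatives form an antichain — no two
representatives satisfy the joining predicate against each other.  The
threshold sweep (70/80/90/95/98%) checks that cluster counts are
non-increasing as the threshold drops.

## NB-LRR mining

The cascade is deliberately asymmetric: NB-ARC positives are selected at
per-domain e ≤ 0.1, and the LRR-clan search is evaluated only *within*
that set, so a sequence with an LRR hit but no NB-ARC hit appears in
neither output (NB-LRR ⊆ NB-ARC by construction, asserted by the report
type).  The lexical route is a case-insensitive substring search for
"nblrr" or "nb-lrr" over annotation-term descriptions — deliberately
literal, since near-miss vocabulary ("leucine-rich repeat kinase",
"NBS-LRR") must not match.  Profile scanning is pluggable: production
input is a domain-hit table from a real profile-HMM search; the built-in
scanner is a log-odds position-weight matrix over fixed nucleotide motif
consensi (match probability 0.85 against a uniform background, e-value =
window count × 2^(−score)).  That scanner is a toy by design — enough to
separate planted degenerate motifs from background by tens of bits — and
is not a profile-HMM replacement; it scans the forward strand only, since
domain callers run on oriented transcripts.

## SNP calling

Reads are placed at their best local alignment over the pseudo-reference;
a read whose best score ties across reference sequences is ambiguous and
dropped (counted), as are unalignable reads.  Only substitution columns of
the alignment path contribute counts; ambiguous bases (N) are excluded
from allele counts and tallied separately.

Each accession's column is genotyped over the 10 unordered diploid
genotypes with the symmetric-error likelihood given in the README
(ε default 0.01; heterozygote prior θ default 0.001 total across the six
heterozygotes).  The inter-accession decision rule: a candidate site is
one where the two maximum-posterior genotypes differ in allele content —
either a fixed difference (AA vs GG) or a polymorphism segregating in one
accession only (AA vs AG).  The emitted allele per accession is the allele
distinguishing it from the other accession (its consensus allele when its
genotype is a subset of the other's); the call is kept when
P(G₁ ≠ G₂) = 1 − Σ_g p₁(g)p₂(g) ≥ 0.9 and each emitted allele has ≥ 2
supporting reads in its own accession (the minimum-evidence rule, applied
bilaterally as the stricter reading).  Sites where more than two alleles
reach 2-read support are skipped and counted; "observed allele" is tied to
the same 2-read floor so that single sequencing errors do not disqualify
sites.

An earlier formulation emitted a call only when the two accessions'
*consensus* alleles differed.  Measured on planted truth, that rule
detects a within-accession heterozygous site only when the alternate
allele happens to be sampled as the site majority (probability ≈ 0.44 at
25× with a 1:1 mixture), and because all sites of a gene share one read
pool these failures are correlated gene-wide, biasing heterozygosity
recovery low by about 5 percentage points at a planted fraction of 0.3.
A two-sample caller that asks whether the genotypes differ does not have
this defect, and matches the downstream analysis, which expects called
SNPs exhibiting ~1:1 within-accession allele mixtures.  The
genotype-difference rule is therefore the package's definition.

## Heterozygosity

For each called SNP and accession, the two call alleles' read counts give
an allelic ratio (major/minor, ∞ when monoallelic).  Depth for the ≥ 20
gate is the *sum of the two SNP alleles' counts* — error bases are
excluded — a definition choice recorded here because "read coverage" is
otherwise ambiguous; the total-column alternative can be obtained by
passing pileup depths directly.  A site is heterozygous at ratio ≤ 3.0
(inclusive: 3:1 counts as mixed).  A sequence is heterozygous in an
accession when **any** eligible site is (a "majority of sites" alternative
is provided); sequences with no depth-eligible site are excluded from rate
denominators entirely, which resolves the ambiguity of what the
denominator of a published per-accession rate should be — both numerator
and denominator are exposed so either convention is auditable.  The
genotyping summary (`conversion_rate`) is plain bookkeeping: converted
markers over assayed markers as a percentage.

## Synthetic data: what it emulates, and what it does not

`generate_universe` builds focal-species transcripts (uniform random DNA,
default 600–1600 nt), reference species derived by independent per-site
substitution (default 5%), within-species paralog copies (rate 5%,
divergence 10%), two accessions separated by a per-site SNP rate (default
0.002), and per-accession heterozygous genes carrying a second haplotype
diverged at 1% of sites — the defaults for the heterozygous-gene fractions
(1.6% and 30%) mirror the two accessions the package models, one nearly
pure inbred line and one carrying the signature of a recent outcross
between distinct accessions.  Resistance-gene mimicry embeds degenerate
copies of fixed NB-ARC/LRR motif consensi in a configurable subset of
genes.

`simulate_reads` draws per-gene read counts as Poisson with mean
proportional to gene length (longer transcripts yield more fragments, so
fold-coverage is roughly constant across genes), anchors each fragment at
the 5' or 3' transcript end with equal probability and truncates at the
boundary — together these give near-flat coverage along the transcript
body, matching the absence of positional bias that random-primed
normalised cDNA shows.  Reads carry independent substitution errors
(default 0.5%), a short-read tail at or below the 45 nt size-selection
floor (4% of reads), and ambiguous bases at 0.26% per base in the 3' half
with the 5' half scaled so that ~92% of all Ns fall in the back half of
the read.  Contaminants are spiked binomially per class (defaults 0.7%
repeats, 0.7% organelle, 0.02% human).

Deliberately **not** modelled: 454 homopolymer indel errors (the default
universe is substitution-only, which keeps planted SNP coordinates exact;
an aligner stress path can introduce indels), cDNA normalisation kinetics,
expression-level variation between genes, sequence composition bias, and
real assembly (the "pseudo-assembly" is the accession-1 consensus per
gene; external assemblers are consumed as contig FASTA, never run).
Passing recovery tests therefore demonstrate the correctness of the
decision rules and estimators under known truth — not performance on real
454 chemistry or on mis-assembled references.  In particular, planted-truth
false-call rates exclude the assembled-paralog artifacts that inflate SNP
and heterozygosity calls in real transcriptome surveys, a limitation the
estimates inherit.

## Benchmark problem sizes

The recovery suites run at sizes chosen so that binomial sampling error is
comfortably inside the asserted tolerances: SNP recovery uses 40 genes of
600–1000 nt at ~20× per accession over 5 seeds (≈ 300 planted SNPs
pooled); heterozygosity recovery uses 60 genes at ~25× over 10 seeds per
planted fraction with snp_rate 0.005, so essentially every gene is
SNP-bearing and the eligibility denominator stays unbiased (sampling
standard error of the 10-seed mean ≈ 1.9 points at a planted fraction of
0.3, against a ±4-point band).  Coverage targets are met through
`mean_reads_per_gene_for_coverage`, which inverts the expected clipped
read length under the fragment-anchoring model.

## Numerical and degenerate-input conventions

Internal coordinates are 0-based half-open; every emitted file format
(hit tables, GFF3) is 1-based inclusive, with reverse-strand hits carrying
s_start > s_end.  Genotyping requires depth ≥ 1 and is evaluated in log
space with max-subtraction.  Empty inputs fail loudly (empty cluster
input, empty het-rate call set, n < 3 correlation) rather than returning
sentinel values; empty FASTA files parse to an empty list with a warning.
N50 of ties returns the largest qualifying contig length.  All generator
randomness flows from a single integer seed through named substreams, so
every artifact — including the end-to-end pipeline directory — is
byte-reproducible given the seed and config (the MANIFEST records both,
plus a SHA-256 of the config).
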