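import math

import numpy as np
import pytest

from goatgrass.synthetic_data import (
    SimConfig,
    generate_universe,
    mean_reads_per_gene_for_coverage,
    pseudo_assembly,
    read_counts,
    simulate_reads,
    spike_contaminants,
    synthetic_annotations,
    synthetic_genetic_map,
)
from goatgrass.simalign import revcomp


def _cfg(**kw):
    base = dict(seed=5, n_genes=20, n_species=3, gene_len_range=(600, 1000),
                paralog_family_rate=0.0, reads_per_gene_mean=10.0)
    base.update(kw)
    return SimConfig(**base)


class TestGenerateUniverse:
    def test_zero_divergence_gives_identical_species(self):
        truth = generate_universe(_cfg(ortholog_divergence=0.0))
        for gid, ref_id in truth.ortholog_of[2].items():
            assert truth.species_genes[2][ref_id] == truth.focal_genes[gid]

    def test_determinism_under_seed(self):
        cfg = _cfg()
        t1 = generate_universe(cfg)
        t2 = generate_universe(cfg)
        assert t1.species_genes == t2.species_genes
        assert t1.snp_positions == t2.snp_positions
        assert t1.het_sites == t2.het_sites
        assert t1.map_assignment == t2.map_assignment

    def test_planted_snp_count_binomial(self):
        cfg = _cfg(n_genes=300, gene_len_range=(1000, 1400), snp_rate=0.001,
                   n_species=2)
        truth = generate_universe(cfg)
        total_nt = sum(len(s) for s in truth.focal_genes.values())
        n_snps = sum(len(v) for v in truth.snp_positions.values())
        mean = total_nt * cfg.snp_rate
        sigma = math.sqrt(total_nt * cfg.snp_rate * (1 - cfg.snp_rate))
        assert abs(n_snps - mean) <= 3 * sigma

    def test_planted_snps_distinguish_consensi(self):
        truth = generate_universe(_cfg(snp_rate=0.01))
        for gid, sites in truth.snp_positions.items():
            a1 = truth.haplotypes["acc1"][gid][0]
            a2 = truth.haplotypes["acc2"][gid][0]
            for pos, (al1, al2) in sites.items():
                assert a1[pos] == al1 and a2[pos] == al2 and al1 != al2

    def test_het_genes_carry_two_distinct_haplotypes(self):
        truth = generate_universe(_cfg(het_fraction_acc2=0.5))
        for gid in truth.het_genes["acc2"]:
            hap_a, hap_b = truth.haplotypes["acc2"][gid]
            assert hap_a != hap_b
            assert len(truth.het_sites["acc2"][gid]) >= 1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            _cfg(snp_rate=1.5)
        with pytest.raises(ValueError):
            _cfg(read_len_range=(30, 800))
        with pytest.raises(ValueError):
            _cfg(contaminant_fractions={"plastic": 0.1})


class TestSimulateReads:
    def test_zero_error_reads_are_haplotype_substrings(self):
        cfg = _cfg(error_rate=0.0, n_rate_3prime=0.0, short_read_fraction=0.0)
        truth = generate_universe(cfg)
        rs = simulate_reads(truth, cfg)
        for acc, reads in rs.reads_by_accession.items():
            for read in reads:
                o = rs.provenance[read.id]
                hap = truth.haplotypes[acc][o.gene_id][o.haplotype]
                expected = hap[o.start:o.end]
                if o.strand == -1:
                    expected = revcomp(expected)
                assert read.sequence == expected

    def test_het_site_allele_ratio_is_binomial_half(self):
        # one long heterozygous gene, deep coverage, errors off
        cfg = _cfg(n_genes=1, gene_len_range=(800, 800), het_fraction_acc2=1.0,
                   het_site_rate=0.02, error_rate=0.0, n_rate_3prime=0.0,
                   short_read_fraction=0.0, reads_per_gene_mean=4000.0)
        truth = generate_universe(cfg)
        rs = simulate_reads(truth, cfg)
        gid = truth.gene_ids[0]
        site = next(iter(truth.het_sites["acc2"][gid]))
        n_alt = n_tot = 0
        for read in rs.reads_by_accession["acc2"]:
            o = rs.provenance[read.id]
            if o.start <= site < o.end:
                n_tot += 1
                n_alt += o.haplotype
        assert n_tot >= 1000
        assert abs(n_alt - n_tot / 2) <= 3 * math.sqrt(n_tot * 0.25)

    def test_ns_skew_to_three_prime_half(self):
        cfg = _cfg(n_rate_3prime=0.05, reads_per_gene_mean=30.0)
        truth = generate_universe(cfg)
        rs = simulate_reads(truth, cfg)
        last_half = total = 0
        for reads in rs.reads_by_accession.values():
            for read in reads:
                seq = read.sequence
                o = rs.provenance[read.id]
                s = seq if o.strand == 1 else revcomp(seq)
                half = len(s) // 2
                total += s.count("N")
                last_half += s[half:].count("N")
        assert total > 100
        assert last_half / total > 0.90

    def test_short_read_tail_exists(self):
        cfg = _cfg(short_read_fraction=0.1, reads_per_gene_mean=30.0)
        truth = generate_universe(cfg)
        rs = simulate_reads(truth, cfg)
        lengths = [len(r) for r in rs.reads_by_accession["acc1"]]
        assert any(l <= 45 for l in lengths)

    def test_coverage_calibration_helper(self):
        cfg = _cfg(short_read_fraction=0.0)
        rpg = mean_reads_per_gene_for_coverage(cfg, 25.0)
        cfg2 = _cfg(short_read_fraction=0.0, reads_per_gene_mean=rpg)
        truth = generate_universe(cfg2)
        rs = simulate_reads(truth, cfg2)
        read_nt = sum(len(r) for reads in rs.reads_by_accession.values() for r in reads)
        gene_nt = sum(len(s) for s in truth.focal_genes.values())
        realized = read_nt / (2 * gene_nt)  # per accession
        assert realized == pytest.approx(25.0, rel=0.15)


class TestSpikeContaminants:
    def test_zero_fractions_leave_reads_unchanged(self):
        cfg = _cfg(contaminant_fractions={})
        truth = generate_universe(cfg)
        rs = simulate_reads(truth, cfg)
        n_before = {a: len(r) for a, r in rs.reads_by_accession.items()}
        rs = spike_contaminants(rs, truth, cfg)
        assert {a: len(r) for a, r in rs.reads_by_accession.items()} == n_before
        assert all(l == "transcript" for l in rs.labels().values())

    def test_binomial_spike_count(self):
        cfg = _cfg(n_genes=100, reads_per_gene_mean=50.0,
                   contaminant_fractions={"repeat": 0.01})
        truth = generate_universe(cfg)
        rs = spike_contaminants(simulate_reads(truth, cfg), truth, cfg)
        labels = rs.labels()
        n_transcript = sum(1 for l in labels.values() if l == "transcript")
        n_repeat = sum(1 for l in labels.values() if l == "repeat")
        mean = 0.01 * n_transcript
        assert abs(n_repeat - mean) <= 3 * math.sqrt(mean)

    def test_labels_partition_the_read_set(self):
        cfg = _cfg()
        truth = generate_universe(cfg)
        rs = spike_contaminants(simulate_reads(truth, cfg), truth, cfg)
        labels = rs.labels()
        for acc, reads in rs.reads_by_accession.items():
            assert {r.id for r in reads} <= set(labels)
        assert set(labels.values()) <= {"transcript", "repeat", "organelle", "human"}

    def test_unrealistic_fractions_rejected(self):
        cfg = _cfg(contaminant_fractions={"repeat": 0.3, "organelle": 0.3})
        truth = generate_universe(cfg)
        rs = simulate_reads(truth, cfg)
        with pytest.raises(ValueError):
            spike_contaminants(rs, truth, cfg)


class TestDerivedArtifacts:
    def test_pseudo_assembly_matches_acc1_consensus(self):
        cfg = _cfg()
        truth = generate_universe(cfg)
        contigs = pseudo_assembly(truth)
        assert [c.id for c in contigs] == truth.gene_ids
        for c in contigs:
            assert c.sequence == truth.haplotypes["acc1"][c.id][0]

    def test_read_counts_cover_all_transcribed_genes(self):
        cfg = _cfg(reads_per_gene_mean=30.0)
        truth = generate_universe(cfg)
        rs = simulate_reads(truth, cfg)
        counts = read_counts(rs)
        assert sum(counts.values()) == sum(len(r) for r in rs.reads_by_accession.values())

    def test_genetic_map_mirrors_planted_assignment(self):
        cfg = _cfg()
        truth = generate_universe(cfg)
        entries = {e.gene_id: e for e in synthetic_genetic_map(truth, species=2)}
        for gid, ref_id in truth.ortholog_of[2].items():
            chrom, cm = truth.map_assignment[gid]
            assert entries[ref_id].chromosome == chrom
            assert entries[ref_id].position_cM == cm

    def test_annotations_deterministic(self):
        cfg = _cfg(n_genes=100, nbarc_gene_fraction=0.2)
        truth = generate_universe(cfg)
        assert synthetic_annotations(truth, cfg) == synthetic_annotations(truth, cfg)
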