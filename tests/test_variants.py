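import math

import numpy as np
import pytest

from goatgrass.formats_io import SeqRecord
from goatgrass.synthetic_data import SimConfig, generate_universe, pseudo_assembly, simulate_reads
from goatgrass.variants import (
    GENOTYPES,
    CallerModel,
    PileupSet,
    build_pileups,
    call_snps,
    genotype_posteriors,
    snp_calls_to_gff,
    summarise_calls,
)

from conftest import random_dna


def manual_posterior(counts, eps, theta):
    """Independent direct evaluation of the stated genotype model."""
    logpost = []
    for a, b in GENOTYPES:
        p = [eps / 3.0] * 4
        if a == b:
            p[a] = 1 - eps
            prior = (1 - theta) / 4
        else:
            p[a] = p[b] = (1 - eps) / 2 + eps / 6
            prior = theta / 6
        ll = math.log(prior) + sum(n * math.log(pb) for n, pb in zip(counts, p))
        logpost.append(ll)
    m = max(logpost)
    w = [math.exp(x - m) for x in logpost]
    return [x / sum(w) for x in w]


def make_pileups(cols1, cols2, length=None):
    """PileupSet over one reference sequence from explicit column counts."""
    length = length or max(max(cols1), max(cols2)) + 1
    c1 = np.zeros((length, 4), dtype=np.int32)
    c2 = np.zeros((length, 4), dtype=np.int32)
    for pos, counts in cols1.items():
        c1[pos] = counts
    for pos, counts in cols2.items():
        c2[pos] = counts
    return PileupSet(
        reference_ids=["ref"],
        counts={"acc1": {"ref": c1}, "acc2": {"ref": c2}},
        n_counts={"acc1": {"ref": np.zeros(length, np.int32)},
                  "acc2": {"ref": np.zeros(length, np.int32)}},
    )


class TestGenotypePosteriors:
    def test_thirty_clean_reads_give_confident_homozygote(self):
        model = CallerModel(error_rate=0.01)
        post = genotype_posteriors(np.array([30, 0, 0, 0]), model)
        assert GENOTYPES[int(np.argmax(post))] == (0, 0)
        assert post[0] > 0.999
        expected = manual_posterior([30, 0, 0, 0], 0.01, 0.001)
        np.testing.assert_allclose(post, expected, rtol=1e-9)

    def test_balanced_counts_give_heterozygote(self):
        model = CallerModel(error_rate=0.01)
        post = genotype_posteriors(np.array([15, 0, 15, 0]), model)
        assert GENOTYPES[int(np.argmax(post))] == (0, 2)  # A/G
        expected = manual_posterior([15, 0, 15, 0], 0.01, 0.001)
        np.testing.assert_allclose(post, expected, rtol=1e-9)

    def test_single_read_small_error_dominated_by_homozygote(self):
        model = CallerModel(error_rate=1e-6)
        post = genotype_posteriors(np.array([1, 0, 0, 0]), model)
        assert GENOTYPES[int(np.argmax(post))] == (0, 0)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            genotype_posteriors(np.zeros(4), CallerModel())


class TestCallSnps:
    A = np.array([20, 0, 0, 0])   # A:20
    G = np.array([0, 0, 20, 0])   # G:20

    def test_clean_fixed_difference_called(self):
        pile = make_pileups({5: self.A}, {5: self.G}, length=10)
        calls, _ = call_snps(pile)
        assert len(calls) == 1
        c = calls[0]
        assert (c.allele_acc1, c.allele_acc2) == ("A", "G")
        assert c.pos == 5 and c.posterior > 0.99

    def test_single_read_allele_not_called(self):
        # acc2 shows G once among 19 A reads: fails both the genotype model
        # and the 2-reads-per-allele floor
        pile = make_pileups({5: self.A}, {5: np.array([19, 0, 1, 0])}, length=10)
        calls, _ = call_snps(pile)
        assert calls == []

    def test_min_two_reads_is_bilateral(self):
        pile = make_pileups({5: np.array([1, 0, 0, 0])}, {5: self.G}, length=10)
        model = CallerModel(min_posterior=0.5)
        calls, tally = call_snps(pile, model)
        assert calls == []
        assert tally["low_allele_support"] == 1

    def test_heterozygous_accession_vs_homozygote_called(self):
        pile = make_pileups({5: self.A}, {5: np.array([12, 0, 13, 0])}, length=10)
        calls, _ = call_snps(pile)
        assert len(calls) == 1
        assert (calls[0].allele_acc1, calls[0].allele_acc2) == ("A", "G")

    def test_label_swap_symmetry(self):
        pile = make_pileups({3: self.A, 7: np.array([10, 0, 10, 0])},
                            {3: self.G, 7: self.A}, length=10)
        fwd, _ = call_snps(pile, accessions=("acc1", "acc2"))
        rev, _ = call_snps(pile, accessions=("acc2", "acc1"))
        assert [(c.pos, c.allele_acc1, c.allele_acc2) for c in fwd] == [
            (c.pos, c.allele_acc2, c.allele_acc1) for c in rev
        ]

    def test_multiallelic_site_skipped_and_counted(self):
        pile = make_pileups({5: np.array([10, 10, 0, 0])},
                            {5: np.array([0, 0, 10, 0])}, length=10)
        calls, tally = call_snps(pile, CallerModel(min_posterior=0.5))
        assert calls == []
        assert tally["multiallelic_skipped"] == 1

    def test_raising_min_posterior_never_adds_calls(self):
        rng = np.random.default_rng(9)
        cols1, cols2 = {}, {}
        for pos in range(40):
            c1 = np.zeros(4, int); c2 = np.zeros(4, int)
            c1[rng.integers(0, 4)] = rng.integers(2, 8)
            c2[rng.integers(0, 4)] = rng.integers(2, 8)
            cols1[pos], cols2[pos] = c1, c2
        pile = make_pileups(cols1, cols2, length=40)
        loose, _ = call_snps(pile, CallerModel(min_posterior=0.5))
        strict, _ = call_snps(pile, CallerModel(min_posterior=0.99))
        assert {(c.seq_id, c.pos) for c in strict} <= {(c.seq_id, c.pos) for c in loose}


class TestBuildPileups:
    def _universe(self, **kw):
        base = dict(seed=31, n_genes=6, n_species=2, gene_len_range=(600, 800),
                    paralog_family_rate=0.0, error_rate=0.0, n_rate_3prime=0.0,
                    short_read_fraction=0.0, snp_rate=0.004,
                    het_fraction_acc1=0.0, het_fraction_acc2=0.0,
                    contaminant_fractions={}, reads_per_gene_mean=40.0)
        base.update(kw)
        cfg = SimConfig(**base)
        truth = generate_universe(cfg)
        return cfg, truth, simulate_reads(truth, cfg)

    def test_error_free_single_haplotype_columns_unanimous(self):
        cfg, truth, rs = self._universe(snp_rate=0.0)
        pile = build_pileups({"acc1": rs.reads_by_accession["acc1"]},
                             pseudo_assembly(truth))
        for gid, counts in pile.counts["acc1"].items():
            covered = counts.sum(axis=1) > 0
            assert (counts[covered] > 0).sum(axis=1).max() == 1

    def test_planted_snp_columns_differ_exactly_there(self):
        cfg, truth, rs = self._universe()
        pile = build_pileups(rs.reads_by_accession, pseudo_assembly(truth))
        base_code = {"A": 0, "C": 1, "G": 2, "T": 3}
        for gid, sites in truth.snp_positions.items():
            c1 = pile.counts["acc1"][gid]
            c2 = pile.counts["acc2"][gid]
            for pos in range(c1.shape[0]):
                d1, d2 = c1[pos].sum(), c2[pos].sum()
                if d1 == 0 or d2 == 0:
                    continue
                maj1, maj2 = int(c1[pos].argmax()), int(c2[pos].argmax())
                if pos in sites:
                    al1, al2 = sites[pos]
                    assert maj1 == base_code[al1] and maj2 == base_code[al2]
                else:
                    assert maj1 == maj2

    def test_tie_mapped_read_dropped_and_counted(self, rng):
        seq = random_dna(rng, 500)
        ref = [SeqRecord("copyA", seq, source_label="contig"),
               SeqRecord("copyB", seq, source_label="contig")]
        read = SeqRecord("r1", seq[100:400])
        pile = build_pileups({"acc1": [read]}, ref)
        assert pile.dropped_ties["acc1"] == 1
        assert all(c.sum() == 0 for c in pile.counts["acc1"].values())

    def test_unalignable_read_dropped_and_counted(self, rng):
        ref = [SeqRecord("c1", random_dna(rng, 500), source_label="contig")]
        read = SeqRecord("r1", random_dna(rng, 300))
        pile = build_pileups({"acc1": [read]}, ref)
        assert pile.dropped_unaligned["acc1"] == 1

    def test_zero_error_high_coverage_calls_equal_planted_truth(self):
        """With no read errors and ~50x coverage, the call set equals the
        planted inter-accession differences exactly."""
        cfg, truth, rs = self._universe(reads_per_gene_mean=50.0)
        pile = build_pileups(rs.reads_by_accession, pseudo_assembly(truth))
        calls, _ = call_snps(pile, CallerModel(error_rate=0.001))
        planted = {(g, p): al for g, d in truth.snp_positions.items()
                   for p, al in d.items()}
        called = {(c.seq_id, c.pos): (c.allele_acc1, c.allele_acc2) for c in calls}
        assert called == planted


class TestExportAndSummary:
    def test_gff_records_shift_to_one_based(self):
        pile = make_pileups({41: np.array([20, 0, 0, 0])},
                            {41: np.array([0, 0, 20, 0])}, length=50)
        calls, _ = call_snps(pile)
        (rec,) = snp_calls_to_gff(calls)
        assert rec.start == 42

    def test_summary_counts_brbh_subset(self):
        pile = make_pileups({1: np.array([20, 0, 0, 0]), 8: np.array([0, 20, 0, 0])},
                            {1: np.array([0, 0, 20, 0]), 8: np.array([0, 0, 0, 20])},
                            length=10)
        calls, _ = call_snps(pile)
        out = summarise_calls(calls, brbh_query_ids={"ref"})
        assert out["total_snps"] == 2
        assert out["snp_bearing_sequences"] == 1
        assert out["snps_in_brbh"] == 2


def test_model_validation():
    with pytest.raises(ValueError):
        CallerModel(error_rate=0.7)
    with pytest.raises(ValueError):
        CallerModel(het_prior=0.0)
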