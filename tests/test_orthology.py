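import pytest

from goatgrass.formats_io import Hit, MapEntry
from goatgrass.orthology import (
    BrbhPair,
    best_hit,
    brbh,
    core_intersection,
    place_on_map,
    unique_hit_union,
)
from goatgrass.simalign import AlignParams, all_vs_all
from goatgrass.synthetic_data import SimConfig, generate_universe, pseudo_assembly, synthetic_genetic_map

from oracles import brbh_bruteforce, venn_regions_bruteforce


def _hit(q, s, e, bits=50.0):
    return Hit(q, s, 95.0, 100, 5, 0, 1, 100, 1, 100, e, bits)


class TestBestHit:
    def test_minimal_evalue_under_ceiling_wins(self):
        hits = [_hit("q", "a", 1e-20), _hit("q", "b", 1e-5)]
        assert best_hit(hits, 1e-10).subject_id == "a"

    def test_tie_breaks_to_lexicographic_subject(self):
        hits = [_hit("q", "gB", 1e-20), _hit("q", "gA", 1e-20)]
        assert best_hit(hits, 1e-10).subject_id == "gA"

    def test_bitscore_breaks_ties_before_subject(self):
        hits = [_hit("q", "gA", 1e-20, bits=40.0), _hit("q", "gB", 1e-20, bits=60.0)]
        assert best_hit(hits, 1e-10).subject_id == "gB"

    def test_empty_or_all_failing_gives_none(self):
        assert best_hit([], 1e-10) is None
        assert best_hit([_hit("q", "a", 1e-5)], 1e-10) is None

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            best_hit([_hit("q1", "a", 1e-20), _hit("q2", "a", 1e-20)], 1e-10)


class TestBrbh:
    def test_mutually_best_pair_reported(self):
        fwd = [_hit("q1", "s1", 1e-20)]
        rev = [_hit("s1", "q1", 1e-18)]
        pairs = brbh(fwd, rev)
        assert [(p.query_id, p.subject_id) for p in pairs] == [("q1", "s1")]

    def test_broken_reciprocity_yields_nothing(self):
        fwd = [_hit("q1", "s1", 1e-20)]
        rev = [_hit("s1", "q2", 1e-30), _hit("s1", "q1", 1e-18)]
        assert brbh(fwd, rev) == []

    def test_each_query_at_most_once(self):
        fwd = [_hit("q1", "s1", 1e-20), _hit("q1", "s2", 1e-15)]
        rev = [_hit("s1", "q1", 1e-20), _hit("s2", "q1", 1e-20)]
        assert len(brbh(fwd, rev)) == 1

    def test_matches_bruteforce_on_random_matrices(self, rng):
        """BRBH over dense random hit matrices equals exhaustive
        mutually-best enumeration."""
        for _ in range(30):
            nq, ns = int(rng.integers(3, 40)), int(rng.integers(3, 40))
            fwd, rev = [], []
            fwd_t, rev_t = [], []
            for i in range(nq):
                for j in range(ns):
                    if rng.random() < 0.3:
                        e = float(10.0 ** -rng.integers(5, 40))
                        b = float(rng.integers(20, 200))
                        fwd.append(_hit(f"q{i}", f"s{j}", e, b))
                        fwd_t.append((f"q{i}", f"s{j}", e, b))
                    if rng.random() < 0.3:
                        e = float(10.0 ** -rng.integers(5, 40))
                        b = float(rng.integers(20, 200))
                        rev.append(_hit(f"s{j}", f"q{i}", e, b))
                        rev_t.append((f"s{j}", f"q{i}", e, b))
            got = {(p.query_id, p.subject_id) for p in brbh(fwd, rev)}
            assert got == brbh_bruteforce(fwd_t, rev_t, 1e-10)

    def test_symmetry_under_role_exchange(self, rng):
        fwd, rev = [], []
        for i in range(20):
            for j in range(20):
                if rng.random() < 0.4:
                    fwd.append(_hit(f"q{i}", f"s{j}", float(10.0 ** -rng.integers(5, 40))))
                if rng.random() < 0.4:
                    rev.append(_hit(f"s{j}", f"q{i}", float(10.0 ** -rng.integers(5, 40))))
        ab = {(p.query_id, p.subject_id) for p in brbh(fwd, rev)}
        ba = {(p.subject_id, p.query_id) for p in brbh(rev, fwd)}
        assert ab == ba

    def test_relaxing_ceiling_never_removes_pairs(self, rng):
        fwd = [_hit(f"q{i}", f"s{i}", float(10.0 ** -rng.integers(5, 20))) for i in range(20)]
        rev = [_hit(f"s{i}", f"q{i}", float(10.0 ** -rng.integers(5, 20))) for i in range(20)]
        strict = {(p.query_id, p.subject_id) for p in brbh(fwd, rev, 1e-15)}
        loose = {(p.query_id, p.subject_id) for p in brbh(fwd, rev, 1e-5)}
        assert strict <= loose

    def test_size_bound(self, rng):
        fwd = [_hit(f"q{i}", f"s{i % 5}", 1e-20) for i in range(30)]
        rev = [_hit(f"s{j}", f"q{j}", 1e-20) for j in range(5)]
        assert len(brbh(fwd, rev)) <= 5


def _pairs(name, ids):
    return [BrbhPair(q, f"{name}_{q}", name, 1e-20, 1e-20) for q in ids]


class TestSetAlgebra:
    def test_union_example(self):
        sets = {"a": _pairs("a", ["q1", "q2"]), "b": _pairs("b", ["q2", "q3"])}
        assert unique_hit_union(sets) == {"q1", "q2", "q3"}

    def test_union_single_set(self):
        sets = {"a": _pairs("a", [f"q{i}" for i in range(17)])}
        assert len(unique_hit_union(sets)) == 17

    def test_core_identical_sets(self):
        ids = [f"q{i}" for i in range(9)]
        sets = {n: _pairs(n, ids) for n in "abcd"}
        report = core_intersection(sets)
        assert report.core_count == 9
        assert report.union_count == 9
        assert all(v == 0 for k, v in report.region_counts.items() if len(k) < 4)

    def test_core_disjoint_sets(self):
        sets = {n: _pairs(n, [f"{n}{i}" for i in range(4)]) for n in "abcd"}
        report = core_intersection(sets)
        assert report.core_count == 0
        assert report.union_count == 16

    def test_regions_match_direct_set_algebra(self, rng):
        universe = [f"q{i}" for i in range(200)]
        memberships = {
            n: {q for q in universe if rng.random() < p}
            for n, p in zip("abcd", (0.5, 0.4, 0.6, 0.3))
        }
        sets = {n: _pairs(n, sorted(ids)) for n, ids in memberships.items()}
        report = core_intersection(sets)
        expected = venn_regions_bruteforce(memberships)
        got = {k: v for k, v in report.region_counts.items() if v}
        assert got == expected

    def test_requires_exactly_four_sets(self):
        with pytest.raises(ValueError):
            core_intersection({"a": [], "b": [], "c": []})

    def test_core_bounded_by_smallest_set(self, rng):
        sets = {
            n: _pairs(n, [f"q{i}" for i in rng.choice(50, size=s, replace=False)])
            for n, s in zip("abcd", (40, 10, 30, 20))
        }
        assert core_intersection(sets).core_count <= 10


class TestPlaceOnMap:
    MAP = [MapEntry("gene1", "1H", 10.5), MapEntry("gene2", "3H", 42.0)]

    def test_bin_index_floor(self):
        pairs = [BrbhPair("q1", "gene1", "ref", 1e-20, 1e-20)]
        placements, skipped = place_on_map(pairs, self.MAP, bin_width_cM=5.0)
        assert placements[0].bin_index == 2
        assert placements[0].chromosome == "1H"
        assert skipped == 0

    def test_partner_absent_from_map_is_skipped_and_counted(self):
        pairs = [BrbhPair("q1", "unknown_gene", "ref", 1e-20, 1e-20)]
        with pytest.warns(UserWarning):
            placements, skipped = place_on_map(pairs, self.MAP)
        assert placements == [] and skipped == 1

    def test_synthetic_universe_recovers_planted_chromosomes(self):
        cfg = SimConfig(seed=23, n_genes=50, n_species=2, gene_len_range=(600, 1000),
                        paralog_family_rate=0.0, ortholog_divergence=0.05,
                        reads_per_gene_mean=1.0)
        truth = generate_universe(cfg)
        contigs = pseudo_assembly(truth)
        refs = truth.reference_set(2)
        params = AlignParams(max_evalue=1e-10)
        pairs = brbh(all_vs_all(contigs, refs, params),
                     all_vs_all(refs, contigs, params), 1e-10, "sp2")
        placements, _ = place_on_map(pairs, synthetic_genetic_map(truth), 5.0)
        assert len(placements) >= 0.95 * 50
        correct = sum(
            1 for p in placements
            if truth.map_assignment[p.query_id][0] == p.chromosome
        )
        assert correct >= 0.95 * len(placements)
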