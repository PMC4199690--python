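import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_cds
from cubscan.codon_core import count_codons
from cubscan.cub_entropy import (
    CUBConfig,
    codon_entropy,
    differential_entropy,
    gene_seed,
    lz76_complexity,
    rank_genes,
    score_genes,
    synonymous_randomize,
)
from cubscan.seq_io import CodingSequence
from oracles import (
    degenerate_positions,
    exact_null_entropy,
    shannon_entropy_codons,
    translate,
)


class TestCodonEntropy:
    def test_single_codon_type_is_zero(self):
        assert codon_entropy("ATGATGATG") == 0.0

    def test_two_distinct_codons_once_each(self):
        assert codon_entropy("GCTGCC") == pytest.approx(1.0)

    def test_two_one_split(self):
        # AAA x2, AAG x1: -(2/3 log2 2/3 + 1/3 log2 1/3)
        assert codon_entropy("AAAAAGAAA") == pytest.approx(0.9182958, abs=1e-6)

    def test_matches_independent_counter_based_entropy(self, rng):
        for _ in range(10):
            seq = random_cds(rng, int(rng.integers(5, 60)))
            codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            assert codon_entropy(seq) == pytest.approx(
                shannon_entropy_codons(codons), abs=1e-12
            )

    def test_stops_and_n_codons_excluded(self):
        assert codon_entropy("ATGTAAATGNNN") == 0.0  # only the two ATG remain

    def test_no_usable_codons_rejected(self):
        with pytest.raises(ValueError):
            codon_entropy("TAATAG")


class TestLZ76:
    def test_deterministic(self):
        s = "ACGTACGTAAGG"
        assert lz76_complexity(s) == lz76_complexity(s)

    def test_homopolymer_less_complex_than_random(self, rng):
        n = 12
        rand_vals = [
            lz76_complexity("".join(rng.choice(list("ACGT"), size=n)))
            for _ in range(100)
        ]
        assert lz76_complexity("A" * n) < np.median(rand_vals)

    def test_repeats_less_complex_than_shuffle(self, rng):
        k = 50
        s = "ACGT" * k
        shuffled_vals = []
        for _ in range(50)        :
            arr = np.array(list(s))
            rng.shuffle(arr)
            shuffled_vals.append(lz76_complexity("".join(arr)))
        assert lz76_complexity(s) < np.mean(shuffled_vals)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            lz76_complexity("ACG")


class TestSynonymousRandomize:
    def test_uniform_draw_frequencies_binomial(self, rng):
        # Lys codon AAA -> {AAA, AAG} each with prob 1/2
        n = 10_000
        hits = sum(synonymous_randomize("AAA", rng) == "AAA" for _ in range(n))
        sd = np.sqrt(n * 0.25)
        assert abs(hits - n / 2) < 3 * sd

    def test_no_synonym_input_unchanged(self, rng):
        assert synonymous_randomize("ATGTGGATG", rng) == "ATGTGGATG"

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 40))
    def test_translation_preserved(self, seed, n_codons):
        rng = np.random.default_rng(seed)
        seq = random_cds(rng, n_codons)
        out = synonymous_randomize(seq, rng)
        assert translate(out) == translate(seq)

    def test_genome_frequency_null_respects_weights(self, rng):
        # a table where Lys is overwhelmingly AAG should draw AAG
        table = count_codons(["AAG" * 1000 + "AAA"])
        n = 2000
        hits = sum(
            synonymous_randomize("AAA", rng, "genome_frequency", table) == "AAG"
            for _ in range(n)
        )
        assert hits > 0.95 * n


class TestDifferentialEntropy:
    def test_no_synonymous_freedom_gives_exact_zero(self):
        r = differential_entropy("ATGATGATG", CUBConfig(master_seed=7))
        assert r.d == 0.0
        assert r.h_null_sd == 0.0

    def test_d_is_h_obs_minus_null_mean_exactly(self, rng):
        seq = random_cds(rng, 40)
        r = differential_entropy(seq, CUBConfig(master_seed=3))
        assert r.d == r.h_obs - r.h_null_mean

    def test_exact_enumeration_lysine_gene(self):
        # AAA x3: the 8 equiprobable synonymous variants have mean entropy
        # 6/8 * 0.9183 = 0.6887, so exact D = -0.6887
        exact = exact_null_entropy("AAAAAAAAA")
        assert exact == pytest.approx(0.688722, abs=1e-5)
        r = differential_entropy("AAAAAAAAA", CUBConfig(n_random=10_000, master_seed=11))
        se = r.h_null_sd / np.sqrt(10_000)
        assert abs(r.d - (-exact)) < 3 * se

    def test_monte_carlo_matches_enumeration_on_small_genes(self, rng):
        checked = 0
        while checked < 5:
            seq = random_cds(rng, int(rng.integers(3, 8)))
            if degenerate_positions(seq) > 10:
                continue
            exact = exact_null_entropy(seq)
            r = differential_entropy(
                CodingSequence(f"gene{checked}", "t", seq),
                CUBConfig(n_random=10_000, master_seed=21),
            )
            se = max(r.h_null_sd / np.sqrt(10_000), 1e-12)
            assert abs(r.h_null_mean - exact) < 3 * se
            checked += 1

    def test_reproducible_and_gene_order_independent(self, small_gene_set):
        config = CUBConfig(master_seed=99)
        res1, _ = score_genes(small_gene_set, config)
        res2, _ = score_genes(list(reversed(small_gene_set)), config)
        by_id_1 = {r.gene_id: r for r in res1}
        by_id_2 = {r.gene_id: r for r in res2}
        assert by_id_1.keys() == by_id_2.keys()
        for gid in by_id_1:
            assert by_id_1[gid].d == by_id_2[gid].d
            assert by_id_1[gid].h_null_mean == by_id_2[gid].h_null_mean

    def test_different_master_seed_changes_null(self, rng):
        seq = random_cds(rng, 50)
        r1 = differential_entropy(seq, CUBConfig(master_seed=1))
        r2 = differential_entropy(seq, CUBConfig(master_seed=2))
        assert r1.h_null_mean != r2.h_null_mean
        assert r1.h_obs == r2.h_obs

    def test_gene_seed_below_2_31(self):
        assert 0 <= gene_seed(123456789, "some_gene") < 2**31

    def test_lz76_estimator_runs(self, rng):
        seq = random_cds(rng, 30)
        r = differential_entropy(seq, CUBConfig(estimator="lz76", master_seed=5))
        assert r.estimator == "lz76"
        assert np.isfinite(r.d)


class TestRankGenes:
    def _mk(self, gene_id, d):
        from cubscan.cub_entropy import CUBResult

        return CUBResult(
            gene_id=gene_id, h_obs=0, h_null_mean=-d, h_null_sd=0, d=d,
            n_codons=10, estimator="codon_shannon", seed=0,
        )

    def test_most_negative_first(self):
        ranked = rank_genes([self._mk("a", -2), self._mk("b", 0), self._mk("c", -5)])
        assert [r.gene_id for r in ranked] == ["c", "a", "b"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_ties_broken_by_gene_id_and_flagged(self):
        ranked = rank_genes([self._mk("b", -1), self._mk("a", -1)])
        assert [r.gene_id for r in ranked] == ["a", "b"]
        assert all(r.tied for r in ranked)

    def test_duplicate_gene_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rank_genes([self._mk("a", -1), self._mk("a", 0)])

    def test_empty_input(self):
        assert rank_genes([]) == []
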