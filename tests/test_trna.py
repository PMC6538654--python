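"""tRNA clustering, signatures, location shuffling and the permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from censcape.genome_io import Genome, Interval
from censcape.trna import (
    ClusterPermutationTest,
    TrnaGene,
    bh_qvalues,
    centromere_frequency_matrix,
    cluster_permutation_test,
    cluster_signature,
    cluster_trna_genes,
    shuffle_gene_locations,
)

from oracles import mc_two_gene_cluster_prob


def gene(chrom, start, strand="+", aa="D", anticodon="GTC", length=70):
    return TrnaGene(Interval(chrom, start, start + length, strand), aa, anticodon)


class TestClustering:
    def test_gap_999_joins(self):
        genes = [gene("c", 0), gene("c", 70 + 999)]
        (cl,) = cluster_trna_genes(genes)
        assert len(cl) == 2

    def test_gap_1000_splits(self):
        genes = [gene("c", 0), gene("c", 70 + 1000)]
        assert [len(c) for c in cluster_trna_genes(genes)] == [1, 1]

    def test_singleton(self):
        (cl,) = cluster_trna_genes([gene("c", 5)])
        assert len(cl) == 1 and cl.span.start == 5

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            cluster_trna_genes([gene("c", 0), gene("c", 30)])

    def test_chromosome_breaks_cluster(self):
        genes = [gene("c1", 0), gene("c2", 100)]
        assert len(cluster_trna_genes(genes)) == 2

    def test_order_invariant_and_idempotent(self):
        genes = [gene("c", 0), gene("c", 500), gene("c", 5000), gene("c", 5400)]
        a = cluster_trna_genes(genes)
        b = cluster_trna_genes(list(reversed(genes)))
        assert [c.signature for c in a] == [c.signature for c in b]
        assert [c.span for c in a] == [c.span for c in b]


class TestSignatures:
    def test_orientation_flip_shares_signature(self):
        fwd = [gene("c", 0, "+", "D"), gene("c", 200, "+", "V")]
        rev = [gene("c", 0, "-", "V"), gene("c", 200, "-", "D")]
        assert cluster_signature(fwd) == cluster_signature(rev)

    def test_singleton_strands_collapse(self):
        assert cluster_signature([gene("c", 0, "+", "E")]) == cluster_signature(
            [gene("c", 0, "-", "E")]
        )

    def test_three_gene_mirror(self):
        fwd = [gene("c", 0, "+", "A"), gene("c", 100, "+", "I"),
               gene("c", 200, "+", "R")]
        rev = [gene("c", 0, "-", "R"), gene("c", 100, "-", "I"),
               gene("c", 200, "-", "A")]
        assert cluster_signature(fwd) == cluster_signature(rev)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.sampled_from("ADVRKLE"), st.sampled_from("+-")),
            min_size=1,
            max_size=6,
        )
    )
    def test_flip_invariance_property(self, pairs):
        genes_fwd = [
            gene("c", 200 * i, s, aa) for i, (aa, s) in enumerate(pairs)
        ]
        flip = {"+": "-", "-": "+"}
        genes_rev = [
            gene("c", 200 * i, flip[s], aa)
            for i, (aa, s) in enumerate(reversed(pairs))
        ]
        assert cluster_signature(genes_fwd) == cluster_signature(genes_rev)


class TestShuffleLocations:
    def test_identity_multiset_preserved(self):
        g = Genome({"c1": "A" * 5000, "c2": "A" * 3000})
        genes = [gene("c1", 0, "+", "D"), gene("c1", 500, "-", "V", "AAC"),
                 gene("c2", 10, "+", "A", "AGC", length=120)]
        placed = shuffle_gene_locations(g, genes, seed=0)
        assert len(placed) == 3
        assert sorted((p.amino_acid, p.interval.strand, p.interval.length)
                      for p in placed) == sorted(
            (x.amino_acid, x.interval.strand, x.interval.length) for x in genes
        )
        for p in placed:
            assert 0 <= p.interval.start and p.interval.end <= g.lengths[p.interval.chrom]

    def test_reproducible(self):
        g = Genome({"c1": "A" * 5000})
        genes = [gene("c1", 0), gene("c1", 1000)]
        a = shuffle_gene_locations(g, genes, seed=7)
        b = shuffle_gene_locations(g, genes, seed=7)
        assert [x.interval for x in a] == [x.interval for x in b]

    def test_uniform_start_distribution(self):
        # a single 70 bp gene on a 1 kb chromosome: start ~ Uniform{0..930}
        g = Genome({"c": "A" * 1000})
        genes = [gene("c", 0)]
        starts = np.array(
            [shuffle_gene_locations(g, genes, seed=i)[0].interval.start
             for i in range(10_000)]
        )
        assert starts.min() >= 0 and starts.max() <= 930
        se = 931 / np.sqrt(12 * 10_000)
        assert abs(starts.mean() - 465.0) < 3 * se

    def test_impossible_placement_errors(self):
        g = Genome({"c": "A" * 100})
        genes = [gene("c", 0, length=60), gene("c", 0, length=60)]
        with pytest.raises((RuntimeError, ValueError)):
            shuffle_gene_locations(g, genes, seed=0)


class TestPermutationTest:
    def test_toy_pvalue_matches_placement_oracle(self):
        # two identical genes planted adjacent on a 10 kb chromosome: any
        # chance pairing reproduces the observed signature, so p should
        # approach the probability that two uniformly placed genes land
        # within 1 kb of each other
        g = Genome({"c": "A" * 10_000})
        genes = [gene("c", 0, "+", "D"), gene("c", 200, "+", "D")]
        n_perm = 4000
        (res,) = cluster_permutation_test(g, genes, n_perm=n_perm, seed=3)
        assert res.observed_count == 1
        p_oracle = mc_two_gene_cluster_prob(10_000, 70, 1000, 1_000_000, seed=9)
        se = np.sqrt(p_oracle * (1 - p_oracle) / n_perm)
        assert abs(res.p - p_oracle) <= 3 * se

    def test_unobserved_signature_p_is_one(self):
        g = Genome({"c": "A" * 10_000})
        genes = [gene("c", 0, "+", "D"), gene("c", 5000, "+", "V")]
        results = cluster_permutation_test(
            g, genes, n_perm=50, seed=1, extra_signatures=["D+V+"]
        )
        by_sig = {r.signature: r for r in results}
        assert by_sig["D+V+"].observed_count == 0
        assert by_sig["D+V+"].p == 1.0
        assert not by_sig["D+V+"].below_resolution

    def test_below_resolution_flag(self, small_synth):
        genome, truth, ann = small_synth
        results = cluster_permutation_test(genome, ann.trna_genes,
                                           n_perm=200, seed=2)
        planted = [r for r in results if r.observed_count >= 2]
        assert planted and all(r.below_resolution == (r.p == 0.0) for r in planted)

    def test_estimator_wrapper(self):
        g = Genome({"c": "A" * 10_000})
        genes = [gene("c", 0, "+", "D"), gene("c", 200, "+", "V")]
        est = ClusterPermutationTest(n_perm=100, random_state=5).fit(genes, g)
        assert est.signatures_.shape == (1,)
        df = est.summary()
        assert set(df.columns) == {"signature", "observed", "p",
                                   "below_resolution", "q"}


class TestBhQvalues:
    def test_single_p(self):
        assert bh_qvalues([0.2])[0] == pytest.approx(0.2)

    def test_stepup_example(self):
        np.testing.assert_allclose(
            bh_qvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.2])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_monotone_in_p(self, ps):
        qs = bh_qvalues(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(qs)[order]) >= -1e-12)
        assert np.all((0 <= qs) & (qs <= 1))


class TestFrequencyMatrix:
    def test_overall_fraction(self):
        genes = [gene("c", 0, "+", "D"), gene("c", 5000, "+", "V", "AAC"),
                 gene("c", 8000, "-", "V", "AAC")]
        cen = [Interval("c", 0, 100)]
        df = centromere_frequency_matrix(genes, cen)
        assert df.loc[("ALL", "ALL"), "centromeric_fraction"] == pytest.approx(1 / 3)
        assert df.loc[("ALL", "ALL"), "total"] == 3

    def test_no_centromeres(self):
        genes = [gene("c", 0, "+", "D")]
        df = centromere_frequency_matrix(genes, [])
        assert df.loc[("D", "GTC"), "non_centromeric"] == 1
        assert df.loc[("D", "GTC"), "centromeric"] == 0

    def test_per_anticodon_counts(self):
        genes = [
            gene("c", 0, "+", "D", "GTC"),
            gene("c", 200, "+", "D", "GTC"),
            gene("c", 5000, "+", "V", "AAC"),
        ]
        cen = [Interval("c", 0, 300)]
        df = centromere_frequency_matrix(genes, cen)
        assert df.loc[("D", "GTC"), "centromeric"] == 2
        assert df.loc[("V", "AAC"), "non_centromeric"] == 1
        assert df.drop(("ALL", "ALL"))["total"].sum() == 3
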