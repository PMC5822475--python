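import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tssprofiler.genomic_io import CoverageTrack, GenomicInterval
from tssprofiler.startseq_core import TSSCluster
from tssprofiler.tss_catalog import TSSRecord
from tssprofiler.chromatin_class import (
    MARKS,
    ClusterSolution,
    cluster_nutss,
    elongation_test,
    label_clusters,
    permutation_overlap_test,
    presence_metaplot,
    ptm_enrichment,
)


def record(summit, strand="+", chrom="chrA"):
    cluster = TSSCluster(chrom, strand, np.array([summit]), np.array([20.0]))
    return TSSRecord(cluster, "nuTSS")


def flat_tracks(genome, value=2.0):
    chip = {}
    for m in MARKS:
        t = CoverageTrack(genome)
        for c in genome:
            t.array(c)[:] = value
        chip[m] = t
    inp = CoverageTrack(genome)
    for c in genome:
        inp.array(c)[:] = value
    return chip, inp


class TestPtmEnrichment:
    def test_chip_equal_input_gives_log2_zero(self, small_genome):
        chip, inp = flat_tracks(small_genome)
        table = ptm_enrichment([record(5000)], chip, inp)
        assert np.allclose(table.to_numpy(), 0.0)

    def test_ratio_without_pseudocount(self, small_genome):
        chip, inp = flat_tracks(small_genome, value=0.0)
        chip["H3K4me3"].array("chrA")[4800:5200] = 0.1  # 40 reads over the window
        inp.array("chrA")[4800:5200] = 0.025  # 10 reads
        table = ptm_enrichment([record(5000)], chip, inp, pseudocount=0.0)
        assert table.loc[0, "H3K4me3"] == pytest.approx(np.log2(4.0))

    def test_window_sums_match_brute_force(self, small_genome):
        rng = np.random.default_rng(0)
        chip, inp = flat_tracks(small_genome)
        chip["H3K27ac"].array("chrA")[:] = rng.random(10_000)
        r = record(5000)
        table = ptm_enrichment([r], chip, inp, window=150, pseudocount=1.0)
        c = chip["H3K27ac"].array("chrA")[4850:5150].sum()
        i = inp.array("chrA")[4850:5150].sum()
        assert table.loc[0, "H3K27ac"] == pytest.approx(np.log2((c + 1) / (i + 1)))

    def test_missing_mark_rejected(self, small_genome):
        chip, inp = flat_tracks(small_genome)
        del chip["H3K36me3"]
        with pytest.raises(KeyError, match="H3K36me3"):
            ptm_enrichment([record(5000)], chip, inp)


def planted_profiles(rng, n_per_class=30, scale=8.0, sd=1.0):
    """Four PTM classes with centroid separation >= 4 sd."""
    centroids = {
        "TSS-like": np.array([0, scale, 0, 0]),
        "Coding": np.array([0, 0, 0, scale]),
        "Enhancer-like": np.array([scale, 0, scale, 0]),
        "Featureless": np.zeros(4),
    }
    rows, truth = [], []
    for name, mu in centroids.items():
        rows.append(rng.normal(mu, sd, size=(n_per_class, 4)))
        truth += [name] * n_per_class
    X = pd.DataFrame(np.vstack(rows), columns=list(MARKS))
    return X, truth


class TestClustering:
    def test_elbow_selects_planted_class_count_and_recovers_members(self):
        rng = np.random.default_rng(1)
        X, truth = planted_profiles(rng)
        sol = cluster_nutss(X, range(2, 16))
        assert sol.k == 4
        assert adjusted_rand_score(truth, sol.labels) >= 0.95

    def test_duplicated_dataset_gives_same_k_and_labels(self):
        rng = np.random.default_rng(2)
        X, _ = planted_profiles(rng, n_per_class=12)
        sol = cluster_nutss(X, range(2, 9))
        dup = pd.concat([X, X], ignore_index=True)
        sol2 = cluster_nutss(dup, range(2, 9))
        assert sol2.k == sol.k
        # the doubled rows land in the same partition structure
        assert adjusted_rand_score(
            np.concatenate([sol.labels, sol.labels]), sol2.labels
        ) == 1.0

    def test_k_range_validation(self):
        X = pd.DataFrame(np.eye(4), columns=list(MARKS))
        with pytest.raises(ValueError):
            cluster_nutss(X, range(2, 16))

    def test_fixed_k_overrides_elbow(self):
        rng = np.random.default_rng(3)
        X, _ = planted_profiles(rng, n_per_class=10)
        sol = cluster_nutss(X, range(2, 9), k=2)
        assert sol.k == 2 and len(np.unique(sol.labels)) == 2


class TestLabelClusters:
    def _solution(self, centroids):
        cent = pd.DataFrame(centroids, columns=list(MARKS))
        cent.index = np.arange(1, len(cent) + 1)
        return ClusterSolution(k=len(cent), labels=np.arange(1, len(cent) + 1),
                               centroids=cent, wss={})

    def test_rule_table_reproduces_named_categories(self):
        # rows: K4me1, K4me3, K27ac, K36me3
        sol = self._solution([
            [0.0, 3.0, 0.0, 0.0],   # TSS-like
            [0.0, 0.0, 0.0, 3.0],   # Coding
            [2.0, 0.0, 2.0, 0.0],   # Enhancer-like
            [0.0, 0.0, 0.0, 0.0],   # Featureless
        ])
        labels = label_clusters(sol)
        assert list(labels.values()) == [
            "TSS-like", "Coding", "Enhancer-like", "Featureless"
        ]

    def test_k4me3_dominates_other_marks(self):
        sol = self._solution([
            [2.0, 3.0, 2.0, 3.0],  # everything high -> TSS-like wins
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ])
        assert label_clusters(sol)[1] == "TSS-like"


class TestElongation:
    def _rna(self, genome, entries):
        t = CoverageTrack(genome, stranded=True)
        for chrom, pos, strand, v in entries:
            t.array(chrom, strand)[pos] += v
        return t

    def test_balanced_counts_not_significant(self, small_genome):
        rna = self._rna(small_genome, [("chrA", 4950, "+", 50.0), ("chrA", 5050, "+", 50.0)])
        table = elongation_test([record(5000)], rna)
        assert table.adj_pvalue.iloc[0] > 0.9

    def test_extreme_downstream_excess_significant(self, small_genome):
        rna = self._rna(small_genome, [("chrA", 5050, "+", 100.0)])
        table = elongation_test([record(5000)], rna)
        assert table.adj_pvalue.iloc[0] < 1e-20
        assert table.signed_significance.iloc[0] > 0

    def test_minus_strand_downstream_is_leftward(self, small_genome):
        rna = self._rna(small_genome, [("chrA", 4950, "-", 100.0)])
        table = elongation_test([record(5000, strand="-")], rna)
        assert table.downstream.iloc[0] == 100.0
        assert table.signed_significance.iloc[0] > 0

    def test_zero_reads_flagged_untested(self, small_genome):
        rna = CoverageTrack(small_genome, stranded=True)
        table = elongation_test([record(5000)], rna)
        assert not table.tested.iloc[0]
        assert np.isnan(table.adj_pvalue.iloc[0])

    def test_bh_adjustment_matches_hand_step_up(self, small_genome):
        rng = np.random.default_rng(4)
        entries = []
        recs = []
        for i in range(12):
            pos = 300 + 700 * i
            recs.append(record(pos))
            entries.append(("chrA", pos - 50, "+", float(rng.integers(5, 40))))
            entries.append(("chrA", pos + 50, "+", float(rng.integers(5, 40))))
        table = elongation_test(recs, self._rna(small_genome, entries))
        p = table.pvalue.to_numpy()
        m = len(p)
        order = np.argsort(p)
        hand = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            hand[order[rank]] = running
        np.testing.assert_allclose(table.adj_pvalue.to_numpy(), hand, atol=1e-12)


class TestPermutationOverlap:
    def test_full_genome_targets_give_p_one(self, small_genome):
        targets = [GenomicInterval(c, 0, n) for c, n in small_genome.items()]
        features = [record(100), record(2000)]
        t = permutation_overlap_test(features, targets, small_genome, n=50, seed=0)
        assert t.observed == 2
        assert t.pvalue == 1.0
        assert np.all(t.null_counts == 2)

    def test_planted_features_in_sparse_targets_significant(self, small_genome):
        # targets cover 1% of the genome; all features planted inside
        targets = [GenomicInterval("chrA", 1000, 1080), GenomicInterval("chrB", 500, 580)]
        features = [record(1000 + 5 * i) for i in range(10)]
        t = permutation_overlap_test(features, targets, small_genome, n=999, seed=1)
        assert t.pvalue <= 0.001

    def test_small_case_matches_exhaustive_enumeration(self):
        # one chromosome of 4 bases, target covers half: each of 2 features
        # lands inside with probability 1/2 independently
        genome = {"c": 4, "d": 4}
        targets = [GenomicInterval("c", 0, 4)]
        features = [("c", 0), ("c", 1)]
        n = 2000
        t = permutation_overlap_test(features, targets, genome, n=n, seed=2)
        assert t.observed == 2
        # enumeration: P(null == 2) = 1/4; p = (1 + Binom(n, 1/4)) / (n + 1)
        frac = (t.null_counts == 2).mean()
        assert frac == pytest.approx(0.25, abs=0.04)
        expected_p = (1 + (t.null_counts >= 2).sum()) / (n + 1)
        assert t.pvalue == expected_p

    def test_empty_inputs_rejected(self, small_genome):
        with pytest.raises(ValueError):
            permutation_overlap_test([], [GenomicInterval("chrA", 0, 10)], small_genome)
        with pytest.raises(ValueError):
            permutation_overlap_test([record(5)], [], small_genome)

    def test_reproducible_per_seed(self, small_genome):
        targets = [GenomicInterval("chrA", 0, 500)]
        features = [record(100), record(5000)]
        a = permutation_overlap_test(features, targets, small_genome, n=100, seed=7)
        b = permutation_overlap_test(features, targets, small_genome, n=100, seed=7)
        np.testing.assert_array_equal(a.null_counts, b.null_counts)


class TestPresenceMetaplot:
    def test_signal_everywhere_gives_flat_unit_profile(self, small_genome):
        track = CoverageTrack(small_genome, stranded=True)
        track.array("chrA", "+")[:] = 1.0
        prof = presence_metaplot({"g": [("chrA", 5000)]}, track, flank=2000, bin_size=10)
        assert prof.shape[0] == 400  # 2 * flank / bin
        assert np.allclose(prof["g"], 1.0)

    def test_zero_track_uses_degenerate_median_rule(self, small_genome):
        track = CoverageTrack(small_genome, stranded=True)
        prof = presence_metaplot({"g": [("chrA", 5000)]}, track, flank=500, bin_size=10)
        assert np.allclose(prof["g"], 0.0)  # 0 / pseudocount median

    def test_empty_group_omitted(self, small_genome):
        track = CoverageTrack(small_genome, stranded=True)
        prof = presence_metaplot({"a": [("chrA", 5000)], "b": []}, track,
                                 flank=500, bin_size=10)
        assert list(prof.columns) == ["a"]
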