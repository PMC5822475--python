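import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from tssprofiler.genomic_io import CoverageTrack
from tssprofiler.startseq_core import (
    NormFactors,
    SpikeInCounts,
    TSSCluster,
    call_clusters,
    cluster_positions,
    compute_spikein_factors,
    derive_fdr_threshold,
    normalize_counts,
    subsample_counts,
    sum_tracks,
)


def oracle_components(positions, chain_dist):
    """O(n^2) connected components of the |pi - pj| <= chain_dist graph."""
    positions = np.sort(np.asarray(positions))
    n = len(positions)
    if n == 0:
        return []
    ii, jj = np.nonzero(np.abs(positions[:, None] - positions[None, :]) <= chain_dist)
    graph = coo_matrix((np.ones_like(ii), (ii, jj)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return [np.sort(positions[labels == lab]) for lab in np.unique(labels)]


class TestSpikeinFactors:
    def test_identical_replicates_give_unit_scores(self):
        R = SpikeInCounts(pd.DataFrame({"rep1": [10, 40, 7], "rep2": [10, 40, 7]}))
        S = compute_spikein_factors(R).S
        np.testing.assert_allclose(S, [1.0, 1.0])

    def test_single_transcript_hand_arithmetic(self):
        # geomean(4, 16) = 8 -> N = (0.5, 2.0) -> S = N
        R = SpikeInCounts(pd.DataFrame({"a": [4.0], "b": [16.0]}))
        f = compute_spikein_factors(R)
        np.testing.assert_allclose(f.N.iloc[0], [0.5, 2.0])
        np.testing.assert_allclose(f.S, [0.5, 2.0])

    def test_scaling_one_column_scales_its_score(self):
        rng = np.random.default_rng(0)
        R = pd.DataFrame(rng.integers(1, 1000, size=(20, 3)).astype(float),
                         columns=["r1", "r2", "r3"])
        base = compute_spikein_factors(SpikeInCounts(R)).S
        scaled = R.copy()
        scaled["r2"] *= 4.0
        S = compute_spikein_factors(SpikeInCounts(scaled)).S
        # the scaled replicate's score rises by c^(1 - 1/n); the others fall
        # by c^(1/n); the product stays 1
        np.testing.assert_allclose(S["r2"] / base["r2"], 4.0 ** (2 / 3))
        np.testing.assert_allclose(np.prod(S), 1.0)

    def test_zero_rows_excluded_and_all_zero_rejected(self):
        R = SpikeInCounts(pd.DataFrame({"a": [0.0, 5.0], "b": [3.0, 5.0]}))
        f = compute_spikein_factors(R)
        assert len(f.N) == 1
        bad = SpikeInCounts(pd.DataFrame({"a": [0.0], "b": [3.0]}))
        with pytest.raises(ValueError, match="no usable spike-ins"):
            compute_spikein_factors(bad)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        arrays(
            np.float64, (8, 3),
            elements=st.floats(min_value=1.0, max_value=1e5),
        )
    )
    def test_geometric_mean_invariants(self, R):
        f = compute_spikein_factors(
            SpikeInCounts(pd.DataFrame(R, columns=["a", "b", "c"]))
        )
        np.testing.assert_allclose(
            np.exp(np.log(f.N).mean(axis=1)), 1.0, atol=1e-9
        )
        np.testing.assert_allclose(np.prod(f.S), 1.0, atol=1e-9)


class TestNormalizeCounts:
    def _track(self, genome, value):
        t = CoverageTrack(genome, stranded=True)
        t.array("chrA", "+")[100] = value
        return t

    def test_unit_factors_are_identity_and_division_applies(self, small_genome):
        tracks = {"rep1": self._track(small_genome, 18.0)}
        f = NormFactors(N=pd.DataFrame(), S=pd.Series({"rep1": 2.0}))
        out = normalize_counts(tracks, f)
        assert out["rep1"].array("chrA", "+")[100] == 9.0
        f1 = NormFactors(N=pd.DataFrame(), S=pd.Series({"rep1": 1.0}))
        same = normalize_counts(tracks, f1)
        np.testing.assert_array_equal(
            same["rep1"].array("chrA", "+"), tracks["rep1"].array("chrA", "+")
        )

    def test_missing_replicate_factor_rejected(self, small_genome):
        tracks = {"repX": self._track(small_genome, 1.0)}
        f = NormFactors(N=pd.DataFrame(), S=pd.Series({"rep1": 1.0}))
        with pytest.raises(KeyError, match="repX"):
            normalize_counts(tracks, f)


class TestFdrThreshold:
    def test_override_returns_operating_point(self, small_genome):
        assert derive_fdr_threshold({}, override=9) == 9.0

    def test_poisson_tail_oracle(self):
        genome = {"c1": 500_000, "c2": 500_000}
        rng = np.random.default_rng(5)
        track = CoverageTrack(genome)
        lam = 0.001
        for c in genome:
            track.array(c)[:] = rng.poisson(lam, genome[c])
        values = np.concatenate([track.array(c) for c in genome])
        size = int((values > 0).sum())
        rate = values.sum() / size
        expected = next(
            c for c in range(1, 100)
            if size * stats.poisson.sf(c - 1, rate)
            / max(1, int((values >= c).sum())) <= 0.05
        )
        got = derive_fdr_threshold({"r": track}, target_fdr=0.05, override=None)
        assert got == expected

    def test_all_zero_track_rejected(self, small_genome):
        with pytest.raises(ValueError, match="no signal"):
            derive_fdr_threshold(
                {"r": CoverageTrack(small_genome)}, override=None
            )


class TestCallClusters:
    def _tracks(self, small_genome, rep_values):
        """rep_values: list of dicts position -> count on chrA '+'."""
        tracks = []
        for values in rep_values:
            t = CoverageTrack(small_genome, stranded=True)
            for pos, v in values.items():
                t.array("chrA", "+")[pos] = v
            tracks.append(t)
        return tracks

    def test_chaining_example(self, small_genome):
        values = {10: 12.0, 12: 20.0, 14: 12.0, 25: 15.0}
        clusters = call_clusters(self._tracks(small_genome, [values]), 9.0, 5)
        assert [list(c.positions) for c in clusters] == [[10, 12, 14], [25]]

    def test_single_nucleotide_cluster(self, small_genome):
        (c,) = call_clusters(self._tracks(small_genome, [{50: 30.0}]), 9.0, 5)
        assert (c.width, c.summit, c.summit_prop) == (1, 50, 1.0)

    def test_every_replicate_rule(self, small_genome):
        # position 20 passes in rep1 only -> excluded
        tracks = self._tracks(small_genome, [{10: 12.0, 20: 12.0}, {10: 10.0, 20: 3.0}])
        (c,) = call_clusters(tracks, 9.0, 5)
        assert list(c.positions) == [10]

    def test_cluster_signal_is_replicate_sum(self, small_genome):
        tracks = self._tracks(small_genome, [{10: 12.0}, {10: 10.0}])
        (c,) = call_clusters(tracks, 9.0, 5)
        assert c.total_signal == 22.0

    def test_summit_tie_broken_leftmost(self):
        c = TSSCluster("c", "+", np.array([5, 6, 7]), np.array([4.0, 4.0, 1.0]))
        assert c.summit == 5
        assert c.secondary == 6

    def test_summit_prop_window(self):
        c = TSSCluster("c", "+", np.arange(10, 20), np.array([1.0] * 5 + [10.0] + [1.0] * 4))
        inside = c.signal[np.abs(c.positions - 15) <= 2].sum()
        assert c.summit_prop == pytest.approx(inside / c.total_signal)

    @pytest.mark.parametrize("chain_dist", [1, 5, 10, 25])
    def test_matches_connected_components_oracle(self, chain_dist):
        rng = np.random.default_rng(chain_dist)
        for _ in range(20):
            n = int(rng.integers(0, 400))
            positions = np.unique(rng.integers(0, 5000, size=n))
            got = cluster_positions(positions, chain_dist)
            expected = sorted(oracle_components(positions, chain_dist),
                              key=lambda a: a[0])
            assert len(got) == len(expected)
            for g, e in zip(got, expected):
                np.testing.assert_array_equal(g, e)

    def test_monotonicity_in_chain_dist_and_threshold(self, small_genome):
        rng = np.random.default_rng(9)
        values = {int(p): float(v) for p, v in
                  zip(rng.integers(0, 2000, 300), rng.integers(1, 40, 300))}
        tracks = self._tracks(small_genome, [values])
        counts = [len(call_clusters(tracks, 9.0, d)) for d in (1, 2, 5, 10, 25)]
        assert counts == sorted(counts, reverse=True)
        qual = [sum(len(c.positions) for c in call_clusters(tracks, thr, 5))
                for thr in (1.0, 5.0, 9.0, 20.0)]
        assert qual == sorted(qual, reverse=True)

    def test_partition_property(self, small_genome):
        rng = np.random.default_rng(3)
        values = {int(p): 15.0 for p in rng.integers(0, 3000, 200)}
        tracks = self._tracks(small_genome, [values])
        clusters = call_clusters(tracks, 9.0, 5)
        members = np.concatenate([c.positions for c in clusters])
        assert len(members) == len(np.unique(members)) == len(values)
        starts = sorted((c.positions[0], c.positions[-1]) for c in clusters)
        for (s1, e1), (s2, e2) in zip(starts, starts[1:]):
            assert s2 - e1 > 5  # inter-cluster gap exceeds chain distance


class TestSubsample:
    def _int_track(self, small_genome):
        t = CoverageTrack(small_genome, stranded=True)
        t.array("chrA", "+")[:100] = np.arange(100, dtype=float)
        t.array("chrB", "-")[10] = 500.0
        return t

    def test_full_draw_is_identity_and_zero_draw_empty(self, small_genome):
        t = self._int_track(small_genome)
        total = int(t.total())
        full = subsample_counts(t, total, seed=0)
        np.testing.assert_array_equal(full.array("chrA", "+"), t.array("chrA", "+"))
        assert subsample_counts(t, 0, seed=0).total() == 0.0

    def test_overdraw_rejected_and_deterministic(self, small_genome):
        t = self._int_track(small_genome)
        with pytest.raises(ValueError, match="cannot draw"):
            subsample_counts(t, int(t.total()) + 1, seed=0)
        a = subsample_counts(t, 1000, seed=4)
        b = subsample_counts(t, 1000, seed=4)
        np.testing.assert_array_equal(a.array("chrA", "+"), b.array("chrA", "+"))

    def test_marginal_means_match_sampling_theory(self, small_genome):
        # mean over draws at each position ~ n * p within 3 SE
        t = CoverageTrack(small_genome, stranded=True)
        counts = np.array([100.0, 300.0, 600.0])
        t.array("chrA", "+")[:3] = counts
        n = 200
        draws = np.stack([
            subsample_counts(t, n, seed=s).array("chrA", "+")[:3]
            for s in range(300)
        ])
        p = counts / counts.sum()
        expected = n * p
        se = np.sqrt(n * p * (1 - p) / 300)
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se)
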