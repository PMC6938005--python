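"""Partition indices against a brute-force oracle; clustering, bootstrap
cluster-number statistics and per-cluster stability."""

import itertools

import numpy as np
import pytest

from tnwclust import (agglomerate, bootstrap_index_stats, cluster_stability,
                      compare_partitions, similarity_matrix, to_distance)
from tnwclust.align import DistanceMatrix
from tnwclust.validate import INDEX_NAMES


def brute_force_indices(p, q):
    """O(N^2) pair counting, independent of the package's contingency
    shortcut, with the same degenerate-denominator conventions."""
    n = len(p)
    a = b = c = d = 0
    for i, j in itertools.combinations(range(n), 2):
        same_p, same_q = p[i] == p[j], q[i] == q[j]
        if same_p and same_q:
            a += 1
        elif same_p:
            b += 1
        elif same_q:
            c += 1
        else:
            d += 1
    total = a + b + c + d
    identical = b == 0 and c == 0
    P, Q = a + b, a + c
    expected = P * Q / total
    ar_den = 0.5 * (P + Q) - expected
    return {
        "Rand": (a + d) / total,
        "AR": (a - expected) / ar_den if ar_den else (1.0 if identical else 0.0),
        "FM": a / np.sqrt(P * Q) if P * Q else 0.0,
        "Jaccard": a / (a + b + c) if a + b + c else 0.0,
        "AW": ((a / P - Q / total) / (1 - Q / total)) if P and total != Q
        else (1.0 if identical else 0.0),
    }


def two_block_distance(n1, n2, within=1.0, between=10.0, jitter=0.0, rng=None):
    n = n1 + n2
    labels = np.array([0] * n1 + [1] * n2)
    D = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if jitter and rng is not None:
        noise = rng.uniform(0, jitter, size=(n, n))
        noise = (noise + noise.T) / 2
        D = D + noise
    np.fill_diagonal(D, 0.0)
    ids = tuple(f"s{i}" for i in range(n))
    return DistanceMatrix(ids, D, 0.0), labels


class TestCompareParticians:
    def test_identical_partitions_all_one(self):
        res = compare_partitions([1, 1, 2, 2], [5, 5, 9, 9])
        assert all(res[name] == pytest.approx(1.0) for name in INDEX_NAMES)

    def test_crossed_partitions_worked_example(self):
        res = compare_partitions([1, 1, 2, 2], [1, 2, 1, 2])
        assert res["Rand"] == pytest.approx(1 / 3)
        assert res["Jaccard"] == 0.0
        assert res["FM"] == 0.0
        assert res["AR"] == pytest.approx(-0.5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            p = rng.integers(0, rng.integers(1, 5) + 1, size=n)
            q = rng.integers(0, rng.integers(1, 5) + 1, size=n)
            res = compare_partitions(p, q)
            exp = brute_force_indices(p.tolist(), q.tolist())
            for name in INDEX_NAMES:
                assert res[name] == pytest.approx(exp[name], abs=1e-12), name

    def test_symmetric_except_adjusted_wallace(self, rng):
        p = rng.integers(0, 3, size=20)
        q = rng.integers(0, 4, size=20)
        fwd, bwd = compare_partitions(p, q), compare_partitions(q, p)
        for name in ("Rand", "AR", "FM", "Jaccard"):
            assert fwd[name] == pytest.approx(bwd[name])

    def test_adjusted_rand_is_centred_on_chance(self, rng):
        """Mean AR of independent random partitions ~ 0 (the point of the
        chance correction), unlike the raw Rand index."""
        ars = []
        for _ in range(1000):
            p = rng.integers(0, 3, size=12)
            q = rng.integers(0, 3, size=12)
            ars.append(compare_partitions(p, q)["AR"])
        assert abs(np.mean(ars)) < 0.05

    def test_bounded_ranges(self, rng):
        for _ in range(100):
            p = rng.integers(0, 4, size=10)
            q = rng.integers(0, 4, size=10)
            res = compare_partitions(p, q)
            for name in ("Rand", "FM", "Jaccard"):
                assert 0.0 <= res[name] <= 1.0
            for name in ("AR", "AW"):
                assert -1.0 <= res[name] <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_partitions([1, 2], [1, 2, 3])


class TestAgglomerate:
    def test_two_leaves_merge_at_their_distance(self):
        D = DistanceMatrix(("a", "b"), np.array([[0.0, 3.5], [3.5, 0.0]]), 0.0)
        Z = agglomerate(D, "single")
        assert Z.merges.shape == (1, 4)
        assert Z.merges[0, 2] == pytest.approx(3.5)

    def test_hand_executed_single_linkage(self):
        D = DistanceMatrix(
            ("a", "b", "c"),
            np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]]),
            0.0,
        )
        Z = agglomerate(D, "single")
        assert set(Z.merges[0, :2].astype(int)) == {0, 1}
        assert Z.merges[0, 2] == pytest.approx(1.0)
        assert Z.merges[1, 2] == pytest.approx(10.0)
        labels = Z.cut(2)
        assert labels[0] == labels[1] != labels[2]

    def test_cut_boundaries(self):
        D, _ = two_block_distance(3, 3)
        Z = agglomerate(D, "average")
        assert len(set(Z.cut(1))) == 1
        assert len(set(Z.cut(6))) == 6
        for q in range(1, 7):
            assert len(set(Z.cut(q))) == q

    def test_cut_out_of_range(self):
        D, _ = two_block_distance(2, 2)
        Z = agglomerate(D, "ward")
        with pytest.raises(ValueError):
            Z.cut(0)
        with pytest.raises(ValueError):
            Z.cut(5)

    def test_unknown_linkage(self):
        D, _ = two_block_distance(2, 2)
        with pytest.raises(ValueError):
            agglomerate(D, "median")

    @pytest.mark.parametrize("linkage", ["single", "complete", "average",
                                         "centroid", "ward"])
    def test_two_block_structure_recovered_by_all_linkages(self, linkage, rng):
        """All within-block distances below all between-block distances:
        the 2-cut must recover the blocks exactly."""
        D, labels = two_block_distance(6, 9, within=1.0, between=10.0,
                                       jitter=0.5, rng=rng)
        Z = agglomerate(D, linkage)
        res = compare_partitions(Z.cut(2), labels)
        assert res["AR"] == pytest.approx(1.0)


class TestBootstrapIndexStats:
    def test_separated_blocks_give_ar_one_at_two(self, rng):
        D, _ = two_block_distance(8, 8, jitter=0.5, rng=rng)
        stats = bootstrap_index_stats(D, M=40, linkage="ward", k_min=2, k_max=4,
                                      seed=11)
        means = stats.mean_table()
        assert means.loc[2, "AR"] == pytest.approx(1.0)
        # the supported q wins
        assert means.loc[2, "AR"] >= means.loc[3, "AR"]

    def test_all_values_within_index_ranges(self, rng):
        n = 12
        noise = rng.uniform(1, 5, size=(n, n))
        Dm = (noise + noise.T) / 2
        np.fill_diagonal(Dm, 0.0)
        D = DistanceMatrix(tuple(map(str, range(n))), Dm, 0.0)
        stats = bootstrap_index_stats(D, M=25, k_min=2, k_max=5, seed=2)
        v = stats.values
        assert (v >= -1 - 1e-12).all() and (v <= 1 + 1e-12).all()
        ii = list(INDEX_NAMES)
        for name in ("Rand", "FM", "Jaccard"):
            assert (v[:, ii.index(name)] >= -1e-12).all()

    def test_reproducible_under_seed(self):
        D, _ = two_block_distance(5, 5)
        s1 = bootstrap_index_stats(D, M=10, k_min=2, k_max=3, seed=7)
        s2 = bootstrap_index_stats(D, M=10, k_min=2, k_max=3, seed=7)
        assert np.array_equal(s1.values, s2.values)

    def test_statistics_come_from_m_replicates(self):
        D, _ = two_block_distance(4, 4)
        stats = bootstrap_index_stats(D, M=13, k_min=2, k_max=3, seed=0)
        assert stats.n_replicates == 13

    def test_invalid_k_range(self):
        D, _ = two_block_distance(3, 3)
        with pytest.raises(ValueError):
            bootstrap_index_stats(D, M=2, k_min=1, k_max=3)
        with pytest.raises(ValueError):
            bootstrap_index_stats(D, M=2, k_min=4, k_max=2)


class TestClusterStability:
    def test_separated_blocks_recover(self, rng):
        """Two clear blocks: every bootstrap replicate finds both, so the
        recovery rate stays near 1."""
        D, labels = two_block_distance(8, 8, jitter=0.5, rng=rng)
        rep = cluster_stability(D, labels, "ward", M=200, seed=5)
        assert rep.gamma.mean(axis=1).min() >= 0.9
        assert rep.sizes == (8, 8)

    def test_measures_bounded(self, rng):
        n = 10
        noise = rng.uniform(1, 4, size=(n, n))
        Dm = (noise + noise.T) / 2
        np.fill_diagonal(Dm, 0.0)
        labels = rng.integers(0, 3, size=n)
        labels[:3] = [0, 1, 2]  # ensure k >= 2
        rep = cluster_stability(Dm, labels, "average", M=30, seed=9)
        for arr in (rep.tau, rep.gamma, rep.eta):
            assert (arr >= 0).all() and (arr <= 1 + 1e-12).all()

    def test_dice_at_least_jaccard(self, rng):
        """Textbook Dice >= Jaccard pointwise for the best-match cluster."""
        D, labels = two_block_distance(6, 6, jitter=1.0, rng=rng)
        rep = cluster_stability(D, labels, "ward", M=50, seed=1)
        assert (rep.eta >= rep.tau - 1e-12).all()

    def test_requires_two_clusters(self):
        D, _ = two_block_distance(3, 3)
        with pytest.raises(ValueError):
            cluster_stability(D, np.zeros(6, dtype=int), M=2)

    def test_reproducible_under_seed(self):
        D, labels = two_block_distance(5, 5)
        r1 = cluster_stability(D, labels, M=8, seed=3)
        r2 = cluster_stability(D, labels, M=8, seed=3)
        assert np.array_equal(r1.tau, r2.tau)
        assert np.array_equal(r1.gamma, r2.gamma)

    def test_summary_shape_and_csv(self, tmp_path):
        D, labels = two_block_distance(5, 5)
        rep = cluster_stability(D, labels, M=8, seed=3)
        df = rep.summary()
        assert list(df["cluster"]) == [0, 1]
        assert {"tau_median", "eta_average", "gamma_std"} <= set(df.columns)
        rep.to_csv(tmp_path / "stab.csv")
        assert (tmp_path / "stab.csv").read_text().startswith("cluster,")
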