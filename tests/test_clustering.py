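import numpy as np
import pytest

from hapfm import (GenotypePanel, KNNSpectralClustering, XMeans,
                   build_design_matrix, cluster_haplotypes,
                   enumerate_haplotypes, make_design,
                   simulate_block_haplotypes)
from hapfm.clustering import _weighted_bic, _weighted_kmeans
from hapfm.partition import BlockPartition


def _panel_from_hap(hap):
    hap = np.asarray(hap, dtype=np.uint8)
    p = hap.shape[1]
    return GenotypePanel(
        sample_ids=[f"S{i}" for i in range(hap.shape[0] // 2)],
        chrom=np.full(p, "1", dtype=object),
        pos=np.arange(1, p + 1) * 100,
        ref=np.full(p, "A", dtype=object),
        alt=np.full(p, "T", dtype=object),
        haplotypes=hap,
    )


class TestEnumerateHaplotypes:
    def test_degenerate_single_haplotype(self):
        hap = np.tile(np.array([1, 0, 1], dtype=np.uint8), (8, 1))
        bh = enumerate_haplotypes(_panel_from_hap(hap), ("1", 0, 3))
        assert bh.h == 1 and bh.counts.tolist() == [8]

    def test_hand_enumeration_counts(self):
        # phased rows 00,00,01,11,01,00 -> uniques 00 x3, 01 x2, 11 x1
        hap = np.array([[0, 0], [0, 0], [0, 1], [1, 1], [0, 1], [0, 0]],
                       dtype=np.uint8)
        bh = enumerate_haplotypes(_panel_from_hap(hap), ("1", 0, 2))
        assert bh.h == 3
        assert bh.counts.tolist() == [3, 2, 1]
        np.testing.assert_array_equal(bh.Z, [[0, 0], [0, 1], [1, 1]])
        np.testing.assert_array_equal(bh.Z[bh.assignment], hap)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(3)
        hap = rng.integers(0, 2, size=(20, 4)).astype(np.uint8)
        bh = enumerate_haplotypes(_panel_from_hap(hap), ("1", 0, 4))
        perm = rng.permutation(10)
        hap2 = hap.reshape(10, 2, 4)[perm].reshape(20, 4)
        bh2 = enumerate_haplotypes(_panel_from_hap(hap2), ("1", 0, 4))
        np.testing.assert_array_equal(bh.Z, bh2.Z)
        np.testing.assert_array_equal(bh.counts, bh2.counts)


class TestXMeans:
    def test_two_rows_forced_minimum_k(self):
        X = np.array([[0, 0, 0, 0], [0, 0, 0, 1]], dtype=float)
        est = XMeans(k_max=10, random_state=0).fit(X)
        assert est.n_clusters_ == 2

    def test_matches_exhaustive_bic_search(self):
        # three well-separated groups: recursive splitting must find the
        # same k as brute-force search over k of the same BIC objective
        rng = np.random.default_rng(5)
        centers = np.array([[0] * 12, [1] * 12,
                            [0, 1] * 6], dtype=float)
        X = np.vstack([c + rng.normal(0, 0.05, size=(6, 12))
                       for c in centers])
        w = np.ones(len(X))
        est = XMeans(k_max=10, random_state=1).fit(X, sample_weight=w)
        bics = []
        for k in range(1, 8):
            labels, cents = _weighted_kmeans(X, w, k, seed=1)
            bics.append(_weighted_bic(X, w, labels, cents))
        assert est.n_clusters_ == int(np.argmax(bics)) + 1 == 3

    def test_k_max_caps_clusters(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 2, size=(40, 16)).astype(float)
        est = XMeans(k_max=2, random_state=0).fit(X)
        assert est.n_clusters_ <= 2

    def test_founder_recovery_on_simulated_haplotypes(self):
        # 15 unique haplotypes from three founders: labels should agree
        # with founder identity in >= 90% of seeded replicates
        agree = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            Z, founders = simulate_block_haplotypes(40, 3, 5, 0.02, rng)
            est = XMeans(k_max=10, random_state=seed).fit(Z.astype(float))
            ok = est.n_clusters_ == 3
            if ok:
                # founder groups must map to distinct clusters
                mapping = {}
                consistent = True
                for lab, f in zip(est.labels_, founders):
                    if f in mapping and mapping[f] != lab:
                        consistent = False
                    mapping[f] = lab
                ok = consistent and len(set(mapping.values())) == 3
            agree.append(ok)
        assert np.mean(agree) >= 0.9


class TestKNNSpectral:
    def test_two_components_become_two_clusters(self):
        X = np.vstack([np.zeros((5, 10)), np.ones((5, 10))])
        X[1, 0] = 1  # minor within-group variation
        est = KNNSpectralClustering(n_neighbors=3, k_max=10,
                                    random_state=0).fit(X)
        assert est.n_clusters_ == 2
        assert len(set(est.labels_[:5])) == 1
        assert len(set(est.labels_[5:])) == 1

    def test_founder_recovery(self):
        agree = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            Z, founders = simulate_block_haplotypes(40, 3, 5, 0.02, rng)
            est = KNNSpectralClustering(n_neighbors=4, k_max=10,
                                        random_state=seed).fit(Z.astype(float))
            same = [est.labels_[i] == est.labels_[j]
                    for i in range(len(Z)) for j in range(i + 1, len(Z))
                    if founders[i] == founders[j]]
            agree.append(np.mean(same))
        assert np.mean(agree) >= 0.85

    def test_agrees_with_xmeans_on_separated_groups(self):
        rng = np.random.default_rng(9)
        Z, founders = simulate_block_haplotypes(30, 3, 4, 0.01, rng)
        X = Z.astype(float)
        a = XMeans(k_max=10, random_state=0).fit(X).labels_
        b = KNNSpectralClustering(n_neighbors=len(X) - 1, k_max=10,
                                  random_state=0).fit(X).labels_
        # same partition up to relabeling
        pairs_a = {(i, j): a[i] == a[j] for i in range(len(X))
                   for j in range(i + 1, len(X))}
        pairs_b = {(i, j): b[i] == b[j] for i in range(len(X))
                   for j in range(i + 1, len(X))}
        assert pairs_a == pairs_b


class TestClusterHaplotypes:
    def _bh(self, h, s, seed=0):
        rng = np.random.default_rng(seed)
        rows = np.unique(rng.integers(0, 2, size=(4 * h, s)), axis=0)[:h]
        from hapfm.clustering import BlockHaplotypes
        counts = np.arange(h, 0, -1)
        assignment = np.repeat(np.arange(h), counts)[: 2 * counts.sum() // 2]
        return BlockHaplotypes(Z=rows.astype(np.uint8), counts=counts,
                               assignment=assignment)

    def test_identity_below_threshold(self):
        bh = self._bh(7, 8)
        labels = cluster_haplotypes(bh, threshold=10)
        np.testing.assert_array_equal(labels, np.arange(7))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            cluster_haplotypes(self._bh(5, 8), method="umap")

    @pytest.mark.parametrize("method", ["xmeans", "knn_spectral"])
    def test_two_tight_groups_perfectly_separated(self, method):
        from hapfm.clustering import BlockHaplotypes
        # 16 unique haplotypes in two maximally separated groups: 8 around
        # all-zeros and 8 around all-ones (one distinguishing bit each)
        Z = np.zeros((16, 20), dtype=np.uint8)
        Z[8:] = 1
        for i in range(8):
            Z[i, i] = 1
            Z[8 + i, i] = 0
        bh = BlockHaplotypes(Z=Z, counts=np.full(16, 2),
                             assignment=np.repeat(np.arange(16), 2))
        labels = cluster_haplotypes(bh, method=method, threshold=10,
                                    random_state=0)
        assert len(np.unique(labels)) == 2
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1


class TestDesignMatrix:
    def test_row_sums_are_two_per_block(self, sim_pipeline):
        panel, _, part, design = sim_pipeline
        for k in range(part.n_blocks):
            cols = design.block_columns(k)
            np.testing.assert_array_equal(
                design.H[:, cols].sum(axis=1), 2.0)

    def test_homozygous_and_heterozygous_entries(self):
        hap = np.array([[0, 0], [0, 0], [0, 1], [1, 1]], dtype=np.uint8)
        panel = _panel_from_hap(hap)
        part = BlockPartition(blocks=[("1", 0, 2)])
        design = make_design(panel, part, threshold=10)
        # sample 0 homozygous for haplotype 00 -> single entry 2
        assert sorted(design.H[0].tolist()) == [0, 0, 2]
        # sample 1 heterozygous across clusters -> two entries of 1
        assert sorted(design.H[1].tolist()) == [0, 1, 1]

    def test_identity_limit_counts_unique_haplotypes(self, sim_pipeline):
        panel, _, part, _ = sim_pipeline
        design = make_design(panel, part, threshold=10 ** 9)
        assert design.m == sum(bh.h for bh in design.block_haplotypes)

    def test_merging_clusters_sums_columns(self, sim_pipeline):
        panel, _, part, design = sim_pipeline
        rng = np.random.default_rng(0)
        k = int(rng.integers(part.n_blocks))
        cols = design.block_columns(k)
        if len(cols) < 2:
            k = int(np.argmax(np.bincount(design.block_of)))
            cols = design.block_columns(k)
        a, b = cols[0], cols[1]
        labels = [lab.copy() for lab in design.labels]
        la = labels[k]
        la[la == 1] = 0
        la[la > 1] -= 1
        merged = build_design_matrix(panel, part, design.block_haplotypes,
                                     labels)
        ca = merged.block_columns(k)[0]
        np.testing.assert_array_equal(merged.H[:, ca],
                                      design.H[:, a] + design.H[:, b])
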