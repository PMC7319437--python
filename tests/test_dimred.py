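import numpy as np
import pytest

from schic import (CellMatrix, EmbeddingMatrix, GenomeBinning, SCoolContainer,
                   SchicError, compartment_features, exact_jaccard, exact_knn,
                   flatten_cells, minhash_knn, obs_exp, pca_reduce,
                   svl_features)
import schic.dimred as dimred
from .conftest import make_cell


class TestFlatten:
    def test_shape_and_identical_rows(self, toy_binning):
        # 4 bins -> 10 upper-triangle features (order bins^2)
        cells = [make_cell("a", [(0, 1, 2)]), make_cell("b", [(0, 1, 2)])]
        emb = flatten_cells(SCoolContainer(toy_binning, cells))
        assert emb.features.shape == (2, 10)
        X = emb.dense()
        assert np.array_equal(X[0], X[1])

    def test_pixel_ordering_is_row_major_upper_triangle(self, toy_binning):
        emb = flatten_cells(SCoolContainer(
            toy_binning, [make_cell("a", [(0, 0, 1), (0, 3, 2), (1, 1, 3)])]))
        row = emb.dense()[0]
        assert row[0] == 1 and row[3] == 2 and row[4] == 3

    def test_feature_count_is_order_bins_squared(self):
        # a 2702-bin genome yields ~3.7 million upper-triangle features,
        # i.e. the millions-of-dimensions regime raw clustering faces
        b = GenomeBinning(("c",), (2702,), 1)
        n = b.n_bins * (b.n_bins + 1) // 2
        assert 3.6e6 < n < 3.7e6


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self, toy_binning):
        t = np.arange(5, dtype=float)
        cells = [make_cell(f"c{i}", [(0, 1, 1 + 2 * i), (1, 2, 2 + 4 * i)],
                           "normalized") for i in range(5)]
        emb = pca_reduce(flatten_cells(SCoolContainer(toy_binning, cells)), 2)
        ev = emb.params["explained_variance"]
        assert ev[0] / ev.sum() > 0.999

    def test_full_rank_preserves_pairwise_distances(self, sim_three_clusters):
        container, _ = sim_three_clusters
        sub = container.with_cells(container.cells[:8])
        raw = flatten_cells(sub)
        X = raw.dense()
        emb = pca_reduce(raw, n_components=7)  # n_cells - 1
        from sklearn.metrics import pairwise_distances
        D_raw = pairwise_distances(X - X.mean(0))
        D_pca = pairwise_distances(emb.dense())
        assert np.abs(D_raw - D_pca).max() < 1e-8

    def test_duplicated_cells_map_identically(self, toy_binning):
        cells = [make_cell("a", [(0, 1, 5)]), make_cell("b", [(0, 2, 3)]),
                 make_cell("a2", [(0, 1, 5)])]
        emb = pca_reduce(flatten_cells(SCoolContainer(toy_binning, cells)), 2)
        X = emb.dense()
        assert np.allclose(X[0], X[2])

    def test_component_count_validation(self, toy_binning):
        raw = flatten_cells(SCoolContainer(toy_binning,
                                           [make_cell("a", [(0, 1, 1)])]))
        with pytest.raises(SchicError):
            pca_reduce(raw, 0)
        with pytest.raises(SchicError):
            pca_reduce(raw, 5)


class TestExactKNN:
    def test_tie_broken_by_lowest_index(self):
        # cell 0 is exactly equidistant (distance 5) from cells 1 and 2,
        # whose own nearest neighbor is cell 3; with k=1 the tie must go to
        # the lower index, so edge (0,1) exists and (0,2) does not
        X = np.array([[0., 0.], [4., 3.], [4., -3.], [7., 0.]])
        emb = EmbeddingMatrix(["a", "b", "c", "d"], X, "pca")
        g = exact_knn(emb, k=1)
        assert g.weights[0, 1] > 0
        assert g.weights[0, 2] == 0
        assert g.weights[1, 3] > 0 and g.weights[2, 3] > 0

    def test_two_far_groups_have_no_cross_edges(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.01, (5, 3)),
                       rng.normal(100, 0.01, (5, 3))])
        g = exact_knn(EmbeddingMatrix([f"c{i}" for i in range(10)], X, "pca"),
                      k=4)
        assert np.all(g.weights[:5, 5:] == 0)

    def test_full_k_gives_complete_graph(self):
        X = np.arange(8, dtype=float).reshape(4, 2)
        g = exact_knn(EmbeddingMatrix(list("abcd"), X, "pca"), k=3)
        off = ~np.eye(4, dtype=bool)
        assert np.all(g.weights[off] > 0)
        assert np.all(np.diag(g.weights) == 0)

    def test_k_must_be_less_than_n(self):
        emb = EmbeddingMatrix(["a", "b"], np.zeros((2, 1)), "pca")
        with pytest.raises(SchicError):
            exact_knn(emb, 2)


class TestMinHash:
    def _container_from_sets(self, sets, n_bins=60):
        # place each set on distinct diagonal-adjacent pixels of one chrom
        b = GenomeBinning(("c",), (n_bins,), 1)
        i, j = np.triu_indices(n_bins)
        cells = [CellMatrix(f"s{k}", i[list(s)], j[list(s)],
                            np.ones(len(s), dtype=np.int64))
                 for k, s in enumerate(sets)]
        return SCoolContainer(b, [c.sorted() for c in cells])

    def test_identical_cells_have_similarity_one(self):
        c = self._container_from_sets([{1, 5, 9}, {1, 5, 9}, {2, 3, 4}])
        g = minhash_knn(c, k=1, num_hashes=50, seed=0)
        assert g.weights[0, 1] == 1.0

    def test_disjoint_sets_near_zero(self):
        c = self._container_from_sets([set(range(100)), set(range(200, 300))],
                                      n_bins=100)
        g = minhash_knn(c, k=1, num_hashes=400, seed=0)
        assert g.weights[0, 1] < 0.05

    def test_estimate_close_to_exact_jaccard(self):
        # sets {1,2,3} vs {2,3,4}: exact Jaccard 0.5
        c = self._container_from_sets([{1, 2, 3}, {2, 3, 4}])
        g = minhash_knn(c, k=1, num_hashes=2000, seed=11)
        assert abs(g.weights[0, 1] - 0.5) <= 0.05

    def test_error_decreases_with_more_hashes(self, sim_three_clusters):
        container, _ = sim_three_clusters
        sub = container.with_cells(container.cells[::2])
        J = exact_jaccard(sub)
        sets, universe = dimred._nonzero_sets(sub)
        iu = np.triu_indices(sub.n_cells, 1)
        maes = []
        for h in (100, 1000):
            sigs = dimred.minhash_signatures(sets, h, 21, universe)
            est = (sigs[:, None, :] == sigs[None, :, :]).mean(2)
            maes.append(np.abs(est[iu] - J[iu]).mean())
        assert maes[1] < maes[0]

    def test_empty_cell_rejected(self, toy_binning):
        c = SCoolContainer(toy_binning, [make_cell("a", np.empty((0, 3))),
                                         make_cell("b", [(0, 1, 1)])])
        with pytest.raises(SchicError, match="QC"):
            minhash_knn(c, k=1)

    def test_deterministic_given_seed(self, sim_three_clusters):
        container, _ = sim_three_clusters
        sub = container.with_cells(container.cells[:6])
        g1 = minhash_knn(sub, k=3, num_hashes=64, seed=5)
        g2 = minhash_knn(sub, k=3, num_hashes=64, seed=5)
        assert np.array_equal(g1.weights, g2.weights)


class TestSVL:
    def test_hand_computed_ratio(self, toy_binning):
        # 4 bins of 1 Mb, threshold 2 Mb: (0,1) is short, (0,3) is long
        c = SCoolContainer(toy_binning, [make_cell("a", [(0, 1, 4), (0, 3, 2)])])
        emb = svl_features(c, distance_threshold=2_000_000)
        assert emb.dense()[0, 0] == 2.0

    def test_scale_invariance(self, sim_three_clusters):
        container, _ = sim_three_clusters
        sub = container.with_cells(container.cells[:4])
        from schic import normalize_scale
        scaled = sub.with_cells([normalize_scale(c, 10.0) for c in sub.cells])
        f1 = svl_features(sub).dense()
        f2 = svl_features(scaled).dense()
        assert np.allclose(f1, f2)

    def test_no_long_range_contacts_gets_sentinel(self, toy_binning):
        c = SCoolContainer(toy_binning, [make_cell("a", [(0, 1, 4)])])
        emb = svl_features(c, distance_threshold=2_000_000)
        assert emb.dense()[0, 0] == emb.params["sentinel"]
        assert ("a", "chr1") in emb.params["sentinel_cells"]

    def test_short_chromosome_flagged_degenerate(self, two_chrom_binning):
        c = SCoolContainer(two_chrom_binning, [make_cell("a", [(0, 3, 1)])])
        with pytest.warns(UserWarning, match="chr2"):
            emb = svl_features(c, distance_threshold=2_000_000)
        assert "chr2" in emb.params["degenerate_chroms"]

    def test_threshold_below_bin_size_rejected(self, toy_binning):
        c = SCoolContainer(toy_binning, [make_cell("a", [(0, 1, 1)])])
        with pytest.raises(SchicError):
            svl_features(c, distance_threshold=10)


class TestObsExp:
    def test_constant_diagonals_give_all_ones(self, toy_binning):
        pixels = [(i, j, 3 * (j - i) + 1) for i in range(4)
                  for j in range(i, 4)]
        m = make_cell("a", pixels)
        oe = obs_exp(m, "chr1", toy_binning)
        assert np.allclose(oe, 1.0)

    def test_hand_computed_three_bins(self):
        b = GenomeBinning(("c",), (3,), 1)
        m = make_cell("a", [(0, 0, 4), (1, 1, 4), (2, 2, 4),
                            (0, 1, 2), (1, 2, 6)])
        oe = obs_exp(m, "c", b)
        assert np.allclose(np.diag(oe), 1.0)        # expected(0) = 4
        assert oe[0, 1] == 0.5 and oe[1, 2] == 1.5  # expected(1) = 4
        assert oe[0, 2] == 0.0                      # zero diagonal d=2

    def test_zero_diagonal_stays_zero(self, toy_binning):
        m = make_cell("a", [(0, 0, 5), (1, 1, 5)])
        oe = obs_exp(m, "chr1", toy_binning)
        assert np.all(oe[np.triu_indices(4, 1)] == 0)


class TestCompartments:
    def _checkerboard(self, n, block, lo=1, hi=9, phase=0):
        side = ((np.arange(n) + phase) // block) % 2
        A = np.where(side[:, None] == side[None, :], hi, lo).astype(float)
        return A

    def test_cell_identical_to_reference_reproduces_track(self):
        b = GenomeBinning(("c",), (12,), 1)
        A = self._checkerboard(12, 3)
        cell = CellMatrix.from_symmetric("a", A, "normalized")
        c = SCoolContainer(b, [cell])
        emb = compartment_features(c, reference=cell)
        ref_track = dimred._compartment_track(cell, "c", b)[0]
        assert np.allclose(emb.dense()[0], ref_track)

    def test_checkerboard_sign_pattern_constant_within_blocks(self):
        b = GenomeBinning(("c",), (12,), 1)
        A = self._checkerboard(12, 3)
        track, ok = dimred._compartment_track(
            CellMatrix.from_symmetric("a", A, "normalized"), "c", b)
        assert ok
        side = (np.arange(12) // 3) % 2
        signs = np.sign(track)
        assert len(set(signs[side == 0])) == 1
        assert len(set(signs[side == 1])) == 1
        assert signs[0] != signs[3]

    def test_inverted_checkerboard_recovered_up_to_sign(self):
        # same-side depleted instead of enriched: the two column-profile
        # groups are unchanged, so the track recovers the same block
        # structure (up to sign, which orientation then fixes)
        b = GenomeBinning(("c",), (12,), 1)
        ref = CellMatrix.from_symmetric(
            "r", self._checkerboard(12, 3), "normalized")
        inverted = CellMatrix.from_symmetric(
            "f", self._checkerboard(12, 3, lo=9, hi=1), "normalized")
        t_ref = dimred._compartment_track(ref, "c", b)[0]
        emb = compartment_features(SCoolContainer(b, [inverted]),
                                   reference=ref)
        r = np.corrcoef(t_ref, emb.dense()[0])[0, 1]
        assert abs(r) > 0.999

    def test_orientation_dot_product_non_negative(self, sim_three_clusters):
        # tracks of simulated compartmented cells all point the same way
        # as the pooled-bulk reference track on every chromosome
        container, _ = sim_three_clusters
        sub = container.with_cells(container.cells[::6])
        emb = compartment_features(sub)
        from schic import pool_to_bulk
        bulk = pool_to_bulk(sub)
        for chrom in container.binning.chrom_names:
            lo, hi = container.binning.chrom_bin_range(chrom)
            ref_track = dimred._compartment_track(
                bulk, chrom, container.binning)[0]
            dots = emb.dense()[:, lo:hi] @ ref_track
            assert np.all(dots >= -1e-12)

    def test_too_few_unmasked_bins_zero_filled_and_flagged(self):
        b = GenomeBinning(("c", "d"), (12, 2), 1)
        A = self._checkerboard(12, 3)
        cell = CellMatrix.from_symmetric("a", A, "normalized")  # chrom d empty
        c = SCoolContainer(b, [cell])
        emb = compartment_features(c, reference=cell)
        assert np.all(emb.dense()[0, 12:] == 0)
        assert ("a", "d") in emb.params["flagged"]
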