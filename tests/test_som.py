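import networkx as nx
import numpy as np
import pytest

from seascapes.som import (HexSOM, TrainConfig, assign_labels, build_hex_lattice,
                           init_weights, input_weight_planes, link_distance_matrix,
                           neighbor_weight_distances, train_batch)


class TestHexLattice:
    def test_single_row_is_a_path(self):
        lat = build_hex_lattice(1, 9)
        assert lat.k == 9
        assert len(lat.edges) == 8
        d = link_distance_matrix(lat)
        assert d[0, 8] == 8

    def test_single_neuron(self):
        lat = build_hex_lattice(1, 1)
        assert lat.edges == ()
        assert link_distance_matrix(lat).item() == 0

    def test_interior_degree_is_six(self):
        lat = build_hex_lattice(4, 5)
        deg = np.zeros(lat.k, int)
        for i, j in lat.edges:
            deg[i] += 1
            deg[j] += 1
        interior = 1 * 5 + 2  # row 1..2, col 1..3 -> e.g. neuron (1,2), (2,2)
        assert deg[1 * 5 + 2] == 6
        assert deg[2 * 5 + 2] == 6
        assert deg[0] < 6  # corner

    def test_positions_offset_layout(self):
        lat = build_hex_lattice(2, 3)
        # odd rows shifted half a cell right
        assert lat.positions[3, 0] == pytest.approx(0.5)
        assert lat.positions[0, 0] == pytest.approx(0.0)

    def test_invalid_dims(self):
        with pytest.raises(ValueError):
            build_hex_lattice(0, 3)


class TestLinkDistance:
    @pytest.mark.parametrize("X,Y", [(1, 4), (2, 3), (3, 3), (4, 6), (6, 6), (5, 5)])
    def test_matches_bfs_oracle(self, X, Y):
        lat = build_hex_lattice(X, Y)
        d = link_distance_matrix(lat)
        G = nx.Graph(list(lat.edges))
        G.add_nodes_from(range(lat.k))
        oracle = dict(nx.all_pairs_shortest_path_length(G))
        for i in range(lat.k):
            for j in range(lat.k):
                assert d[i, j] == oracle[i][j]

    def test_self_zero_adjacent_one(self):
        lat = build_hex_lattice(3, 4)
        d = link_distance_matrix(lat)
        assert (np.diag(d) == 0).all()
        for i, j in lat.edges:
            assert d[i, j] == 1

    def test_symmetric_triangle_inequality(self):
        d = link_distance_matrix(build_hex_lattice(4, 5))
        np.testing.assert_array_equal(d, d.T)
        k = d.shape[0]
        assert (d[:, :, None] + d[None, :, :] >= d[:, None, :]).all()


class TestInitWeights:
    def test_pca_plane_deterministic(self, rng):
        X = rng.normal(size=(100, 6))
        lat = build_hex_lattice(3, 4)
        np.testing.assert_array_equal(init_weights(X, lat), init_weights(X, lat))

    def test_random_within_data_box(self, rng):
        X = rng.normal(size=(50, 6)) * 3 + 1
        lat = build_hex_lattice(2, 5)
        W = init_weights(X, lat, method="random", seed=1)
        assert (W >= X.min(axis=0)).all() and (W <= X.max(axis=0)).all()

    def test_1d_data_gives_monotone_weights_on_path(self):
        X = np.column_stack([np.linspace(0, 1, 30), np.zeros(30)])
        W = init_weights(X, build_hex_lattice(1, 3))
        diffs = np.diff(W[:, 0])
        assert (diffs > 0).all() or (diffs < 0).all()
        np.testing.assert_allclose(W[:, 1], 0.0, atol=1e-12)


class TestTrainBatch:
    def test_single_neuron_converges_to_data_mean(self, rng):
        X = rng.normal(size=(200, 6))
        model = train_batch(X, build_hex_lattice(1, 1), TrainConfig(steps=100))
        np.testing.assert_allclose(model.weights[0], X.mean(axis=0), atol=1e-12)

    def test_two_blobs_two_neurons(self, two_blobs):
        X, labels = two_blobs
        model = train_batch(X, build_hex_lattice(1, 2), TrainConfig())
        means = np.array([X[labels == c].mean(axis=0) for c in (0, 1)])
        d = np.linalg.norm(model.weights[:, None] - means[None], axis=2)
        # each neuron within 0.01 of one blob mean, both blobs covered
        assert d.min(axis=1).max() < 0.01
        assert set(d.argmin(axis=1)) == {0, 1}

    def test_bitwise_deterministic(self, rng):
        X = rng.normal(size=(300, 6))
        cfg = TrainConfig(steps=200, seed=5, init="random")
        a = train_batch(X, build_hex_lattice(2, 3), cfg)
        b = train_batch(X, build_hex_lattice(2, 3), cfg)
        assert a.weights.tobytes() == b.weights.tobytes()

    def test_radius_zero_equals_lloyds_kmeans(self, rng):
        """With the neighborhood disabled the batch step is exactly Lloyd's
        iteration (empty clusters keep their centroid)."""
        X = rng.normal(size=(150, 4))
        lat = build_hex_lattice(1, 6)
        W0 = init_weights(X, lat)

        C = W0.copy()
        for _ in range(5):  # independent Lloyd oracle
            d2 = ((X[:, None] - C[None]) ** 2).sum(-1)
            a = d2.argmin(1)
            for j in range(len(C)):
                if (a == j).any():
                    C[j] = X[a == j].mean(axis=0)

        model = train_batch(X, lat, TrainConfig(steps=5, init_radius=0, tol=0.0))
        np.testing.assert_allclose(model.weights, C, atol=1e-12)

    def test_path_on_line_gives_monotone_weights(self):
        """Topology preservation: a 1x9 map on noiseless collinear points
        orders its weights along the line."""
        t = np.linspace(0, 1, 400)
        X = np.column_stack([t, 2 * t, -t, 0.5 * t, t, t])  # line in 6-D
        model = train_batch(X, build_hex_lattice(1, 9), TrainConfig())
        proj = model.weights @ np.array([1, 2, -1, 0.5, 1, 1.0])
        diffs = np.diff(proj)
        assert (diffs > 0).all() or (diffs < 0).all()

    def test_final_partition_is_voronoi(self, planted):
        X = planted["std"].values
        model = train_batch(X, build_hex_lattice(2, 3), TrainConfig())
        labels = assign_labels(model, X)
        d = np.linalg.norm(X[:, None] - model.weights[None], axis=2)
        np.testing.assert_allclose(d[np.arange(len(X)), labels], d.min(axis=1),
                                   atol=1e-12)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            train_batch(np.empty((0, 6)), build_hex_lattice(1, 2), TrainConfig())

    def test_fewer_rows_than_neurons_warns(self, rng):
        with pytest.warns(UserWarning, match="fewer rows"):
            train_batch(rng.normal(size=(3, 2)), build_hex_lattice(2, 3),
                        TrainConfig(steps=10))


class TestAssignAndDiagnostics:
    def test_row_equal_to_weight_gets_that_neuron(self, rng):
        X = rng.normal(size=(50, 3))
        model = train_batch(X, build_hex_lattice(1, 4), TrainConfig(steps=50))
        lab = assign_labels(model, model.weights)
        np.testing.assert_array_equal(lab, np.arange(4))

    def test_labels_match_bruteforce_argmin(self, rng):
        X = rng.normal(size=(100, 5))
        model = train_batch(X, build_hex_lattice(2, 4), TrainConfig(steps=100))
        lab = assign_labels(model, X)
        oracle = np.array([np.argmin([np.linalg.norm(x - w) for w in model.weights])
                           for x in X])
        np.testing.assert_array_equal(lab, oracle)
        assert len(lab) == len(X)

    def test_column_mismatch_raises(self, rng):
        model = train_batch(rng.normal(size=(30, 4)), build_hex_lattice(1, 2),
                            TrainConfig(steps=10))
        with pytest.raises(ValueError):
            assign_labels(model, rng.normal(size=(5, 3)))

    def test_neighbor_distances_match_norms(self, rng):
        X = rng.normal(size=(80, 4))
        model = train_batch(X, build_hex_lattice(2, 3), TrainConfig(steps=50))
        for i, j, d in neighbor_weight_distances(model):
            assert d == pytest.approx(np.linalg.norm(model.weights[i] - model.weights[j]))
        assert len(neighbor_weight_distances(model)) == len(model.lattice.edges)

    def test_identical_weights_zero_distances(self):
        model = train_batch(np.tile([[0.5, 0.5]], (20, 1)),
                            build_hex_lattice(1, 3), TrainConfig(steps=10))
        assert all(d == 0 for _, _, d in neighbor_weight_distances(model))

    def test_weight_planes_reassemble_matrix(self, rng):
        X = rng.uniform(size=(100, 6))
        model = train_batch(X, build_hex_lattice(1, 5), TrainConfig(steps=100))
        planes = input_weight_planes(model)
        reassembled = np.column_stack([planes[c] for c in planes])
        np.testing.assert_array_equal(reassembled, model.weights)
        assert all(((p >= 0) & (p <= 1)).all() for p in planes.values())


class TestHexSOMEstimator:
    def test_sklearn_contract(self, two_blobs):
        X, _ = two_blobs
        est = HexSOM(x=1, y=2, steps=100)
        assert est.get_params()["y"] == 2
        est.fit(X)
        assert est.weights_.shape == (2, 2)
        assert len(est.labels_) == len(X)
        np.testing.assert_array_equal(est.predict(X), est.labels_)
        assert est.transform(X).shape == (len(X), 2)

    def test_model_json_round_trip(self, two_blobs, tmp_path):
        X, _ = two_blobs
        est = HexSOM(x=1, y=2, steps=100).fit(X)
        p = tmp_path / "model.json"
        est.model_.to_json(p)
        from seascapes.som import SOMModel
        back = SOMModel.from_json(p)
        np.testing.assert_allclose(back.weights, est.weights_, atol=1e-15)
        np.testing.assert_array_equal(back.link_dist, est.model_.link_dist)
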