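"""Graph convolution, readout, checkpointing, and gradient correctness."""

import numpy as np
import pytest

import polysize as ps
from polysize.nn import GCNEncoder, MLP, _sigmoid

from conftest import random_graph


def message_passing_oracle(H, A_hat, W, b):
    """Per-node view of the convolution: each node sums A_hat-weighted
    neighbour-plus-self features, then applies the affine map and ReLU."""
    n, d_out = H.shape[0], W.shape[1]
    out = np.zeros((n, d_out))
    for i in range(n):
        msg = np.zeros(H.shape[1])
        for j in range(n):
            msg += A_hat[i, j] * H[j]
        out[i] = np.maximum(msg @ W + b, 0.0)
    return out


def hop_distances(graph, source):
    """BFS hop distances from one node (inf where unreachable)."""
    dist = np.full(graph.n_nodes, np.inf)
    dist[source] = 0
    frontier = [source]
    adj = {i: [] for i in range(graph.n_nodes)}
    for a, b in graph.edges:
        adj[a].append(b)
        adj[b].append(a)
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if dist[v] == np.inf:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


class TestGCNLayer:
    def test_two_node_path_closed_form(self):
        A_hat = np.array([[0.5, 0.5], [0.5, 0.5]])
        params = ps.GCNLayerParams(
            W=np.eye(2), b=np.zeros(2), activation="identity", dropout=0.0
        )
        out = ps.gcn_layer(np.eye(2), A_hat, params)
        np.testing.assert_allclose(out, [[0.5, 0.5], [0.5, 0.5]])

    def test_zero_weights_yield_bias(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, n_max=9)
        A_hat = ps.normalized_adjacency(g)
        c = np.array([1.5, -2.0, 0.25])
        params = ps.GCNLayerParams(
            W=np.zeros((g.H0.shape[1], 3)), b=c, activation="identity", dropout=0.0
        )
        out = ps.gcn_layer(g.H0, A_hat, params)
        np.testing.assert_allclose(out, np.tile(c, (g.n_nodes, 1)))

    def test_matrix_form_matches_message_passing_oracle(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            g = random_graph(rng, n_max=12, dim=6)
            A_hat = ps.normalized_adjacency(g)
            W = rng.normal(size=(6, 4))
            b = rng.normal(size=4)
            params = ps.GCNLayerParams(W=W, b=b, activation="relu", dropout=0.0)
            got = ps.gcn_layer(g.H0, A_hat, params)
            want = message_passing_oracle(g.H0, A_hat, W, b)
            worst = max(worst, np.abs(got - want).max())
        assert worst < 1e-6

    def test_shape_mismatch_names_shapes(self):
        params = ps.GCNLayerParams(W=np.eye(3), b=np.zeros(3), dropout=0.0)
        with pytest.raises(ps.ShapeError, match=r"\(2, 2\)"):
            ps.gcn_layer(np.zeros((2, 2)), np.eye(2), params)

    def test_dropout_disabled_in_evaluation(self):
        rng = np.random.default_rng(1)
        g = random_graph(rng, n_max=6)
        A_hat = ps.normalized_adjacency(g)
        params = ps.GCNLayerParams(
            W=rng.normal(size=(g.H0.shape[1], 3)), b=np.zeros(3), dropout=0.5
        )
        a = ps.gcn_layer(g.H0, A_hat, params)
        b = ps.gcn_layer(g.H0, A_hat, params)
        np.testing.assert_array_equal(a, b)


class TestStackAndLocality:
    def test_zero_layers_return_input(self, cyclic_mma):
        out = ps.stack_convolutions(cyclic_mma, [])
        np.testing.assert_array_equal(out, cyclic_mma.H0)

    def test_perturbation_cannot_leak_past_awareness_range(self, cyclic_mma):
        rng = np.random.default_rng(5)
        n_layers = 3
        dims = [cyclic_mma.H0.shape[1], 8, 8, 8]
        layers = [
            ps.GCNLayerParams(
                W=rng.normal(size=(dims[i], dims[i + 1])),
                b=rng.normal(size=dims[i + 1]),
                dropout=0.0,
            )
            for i in range(n_layers)
        ]
        base = ps.stack_convolutions(cyclic_mma, layers)
        perturbed = cyclic_mma.H0.copy()
        perturbed[0] += 10.0
        g2 = ps.MolecularGraph(
            n_nodes=cyclic_mma.n_nodes,
            edges=cyclic_mma.edges,
            H0=perturbed,
            unit_index=cyclic_mma.unit_index,
            atom_index=cyclic_mma.atom_index,
            n_units=cyclic_mma.n_units,
            unit_size=cyclic_mma.unit_size,
            cyclic=True,
        )
        after = ps.stack_convolutions(g2, layers)
        dist = hop_distances(cyclic_mma, 0)
        far = dist > n_layers
        assert far.any()
        assert np.array_equal(base[far], after[far])  # bit-identical
        assert np.abs(base[~far] - after[~far]).max() > 0

    def test_cyclic_symmetry_propagates_through_convolutions(self, cyclic_mma):
        rng = np.random.default_rng(9)
        dims = [cyclic_mma.H0.shape[1], 16, 16, 16, 16]
        layers = [
            ps.GCNLayerParams(
                W=rng.normal(size=(dims[i], dims[i + 1])),
                b=rng.normal(size=dims[i + 1]),
                dropout=0.0,
            )
            for i in range(4)
        ]
        H = ps.stack_convolutions(cyclic_mma, layers).reshape(10, 7, -1)
        assert np.abs(H - H[0]).max() < 1e-6


class TestReadout:
    def test_single_node_graph(self):
        row = np.array([[1.0, -2.0, 3.0]])
        w = np.array([0.5, 0.5, 0.5])
        fp = ps.pool_readout(row, w, 0.0)
        gate = _sigmoid(np.array([row[0] @ w]))[0]
        np.testing.assert_allclose(fp[:3], row[0])
        np.testing.assert_allclose(fp[3:], gate * row[0])

    def test_permutation_invariance_exact(self):
        rng = np.random.default_rng(2)
        H = rng.normal(size=(9, 4))
        w = rng.normal(size=4)
        perm = rng.permutation(9)
        a = ps.pool_readout(H, w, 0.3)
        b = ps.pool_readout(H[perm], w, 0.3)
        np.testing.assert_array_equal(a, b)

    def test_disjoint_duplication_doubles_sum_half(self):
        rng = np.random.default_rng(3)
        H = rng.normal(size=(6, 4))
        w = rng.normal(size=4)
        fp1 = ps.pool_readout(H, w, -0.2)
        fp2 = ps.pool_readout(np.vstack([H, H]), w, -0.2)
        np.testing.assert_allclose(fp2[:4], fp1[:4])  # max unchanged
        np.testing.assert_allclose(fp2[4:], 2 * fp1[4:])  # sum doubled

    def test_empty_graph_rejected(self):
        with pytest.raises(ps.ValidationError):
            ps.pool_readout(np.empty((0, 3)), np.zeros(3), 0.0)

    def test_plain_sum_mode(self):
        H = np.array([[1.0, 2.0], [3.0, 4.0]])
        fp = ps.pool_readout(H, None, None, sum_mode="plain")
        np.testing.assert_allclose(fp, [3.0, 4.0, 4.0, 6.0])


class TestFingerprintDistance:
    def test_identical_is_zero(self):
        v = np.arange(5.0)
        assert ps.fingerprint_distance(v, v) == 0.0

    def test_three_four_five(self):
        assert ps.fingerprint_distance([0.0, 0.0], [3.0, 4.0]) == 5.0

    def test_length_mismatch(self):
        with pytest.raises(ps.ShapeError):
            ps.fingerprint_distance([1.0], [1.0, 2.0])


class TestFCLayer:
    def test_identity_map(self):
        params = ps.FCLayerParams(
            W=np.eye(4), b=np.zeros(4), activation="identity", dropout=0.0
        )
        v = np.array([1.0, -2.0, 3.0, 0.5])
        np.testing.assert_array_equal(ps.fc_layer(v, params), v)

    def test_zero_input_gives_bias(self):
        rng = np.random.default_rng(0)
        params = ps.FCLayerParams(
            W=rng.normal(size=(3, 2)),
            b=np.array([0.7, -0.1]),
            activation="identity",
            dropout=0.0,
        )
        np.testing.assert_allclose(ps.fc_layer(np.zeros(3), params), [0.7, -0.1])

    def test_per_neuron_oracle(self):
        rng = np.random.default_rng(4)
        l, W, b = rng.normal(size=7), rng.normal(size=(7, 5)), rng.normal(size=5)
        params = ps.FCLayerParams(W=W, b=b, activation="identity", dropout=0.0)
        got = ps.fc_layer(l, params)
        want = np.array(
            [sum(l[i] * W[i, j] for i in range(7)) + b[j] for j in range(5)]
        )
        assert np.abs(got - want).max() < 1e-9


class TestEncoderGradients:
    def test_backward_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        g = random_graph(rng, n_max=7, dim=5)
        A_hat = ps.normalized_adjacency(g)
        enc = GCNEncoder(5, (6, 4), dropout=0.0, rng=rng)
        target = rng.normal(size=enc.fingerprint_dim)

        def loss():
            fp, _ = enc.forward(g.H0, A_hat)
            return 0.5 * np.sum((fp - target) ** 2)

        fp, cache = enc.forward(g.H0, A_hat)
        grads = enc.backward(cache, fp - target)
        eps = 1e-6
        for key in ["conv0.W", "conv1.b", "gate.w", "gate.b"]:
            arr = enc.params[key]
            it = np.nditer(arr, flags=["multi_index"])
            for _ in range(min(arr.size, 5)):
                idx = it.multi_index
                old = arr[idx]
                arr[idx] = old + eps
                lp = loss()
                arr[idx] = old - eps
                lm = loss()
                arr[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - grads[key][idx]) < 1e-4 * max(1.0, abs(num))
                it.iternext()

    def test_mlp_backward_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        mlp = MLP(6, (8, 4), dropout=0.0, rng=rng)
        X = rng.normal(size=(5, 6))
        y = rng.uniform(50, 200, size=5)

        def loss():
            y_hat, _ = mlp.forward(X)
            return np.mean(np.abs(y_hat - y) / y)

        y_hat, caches = mlp.forward(X)
        dy = np.sign(y_hat - y) / (y * len(y))
        grads, _ = mlp.backward(caches, dy)
        eps = 1e-6
        for key in ["fc0.W", "fc1.b", "fc2.W"]:
            arr = mlp.params[key]
            it = np.nditer(arr, flags=["multi_index"])
            for _ in range(min(arr.size, 5)):
                idx = it.multi_index
                old = arr[idx]
                arr[idx] = old + eps
                lp = loss()
                arr[idx] = old - eps
                lm = loss()
                arr[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - grads[key][idx]) < 1e-5 * max(1.0, abs(num))
                it.iternext()


class TestCheckpoint:
    def test_encoder_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(10)
        enc = GCNEncoder(5, (8, 6), rng=rng)
        path = tmp_path / "enc.json"
        enc.save(path)
        loaded = GCNEncoder.load(path)
        for k, v in enc.params.items():
            assert np.array_equal(loaded.params[k], v)  # bit-exact
        assert loaded.config() == enc.config()

    def test_wrong_kind_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"kind": "something_else"}')
        with pytest.raises(ps.ValidationError):
            GCNEncoder.load(path)


class TestConvergence:
    def test_cyclic_matches_infinite_chain_viewpoint(self, mma_unit):
        table = ps.fingerprint_convergence(
            mma_unit, [1, 2, 4, 8, 16, 20], seed=0, hidden_dims=(16, 16, 16, 16)
        )
        d = table["distance"].to_numpy()
        assert (np.diff(d[2:]) <= 1e-12).all()  # non-increasing beyond small n
        assert table.loc[table["n"] >= 16, "rel_distance"].max() < 1e-5

    def test_whole_graph_mode_keeps_end_effect_floor(self, mma_unit):
        table = ps.fingerprint_convergence(
            mma_unit, [8, 16], seed=0, hidden_dims=(8, 8), mode="whole_graph"
        )
        assert (table["rel_distance"] > 1e-5).all()
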