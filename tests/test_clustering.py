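import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cytoclust.clustering import (
    _cdf_area,
    consensus_metacluster,
    elbow_data,
    flowsom_cluster,
    graph_cluster,
    kmeans_cluster,
    knn_jaccard_graph,
    train_som,
)
from cytoclust.core import Panel, SampleTable, build_experiment


def _exp_from_matrix(m):
    m = np.asarray(m, dtype=float)
    exp = build_experiment(
        m,
        ["S1"] * len(m),
        Panel.from_channels([f"m{i}" for i in range(m.shape[1])]),
        SampleTable(pd.DataFrame({"sample_id": ["S1"]})),
    )
    exp.transformed = m.copy()
    return exp


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def lloyd_kmeans(data, init_codes, iters=50):
    """Plain Lloyd iterations from a fixed init (empty clusters keep codes)."""
    codes = init_codes.copy()
    for _ in range(iters):
        d = ((data[:, None, :] - codes[None, :, :]) ** 2).sum(-1)
        assign = d.argmin(1)
        new = codes.copy()
        for j in range(len(codes)):
            if (assign == j).any():
                new[j] = data[assign == j].mean(0)
        if np.allclose(new, codes):
            break
        codes = new
    return codes, assign


def best_partition_by_enumeration(data, k):
    """Exhaustive search over all assignments of n points to k clusters."""
    n = len(data)
    best = None
    best_ss = np.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) != k:
            continue
        assign = np.array(assign)
        ss = 0.0
        for j in range(k):
            pts = data[assign == j]
            ss += ((pts - pts.mean(0)) ** 2).sum()
        if ss < best_ss - 1e-12:
            best_ss = ss
            best = assign
    return best, best_ss


# ---------------------------------------------------------------------------
# SOM
# ---------------------------------------------------------------------------

class TestSom:
    def test_fixed_point_zero_radius(self):
        """Data equal to the initial codes with radius 0 stays put."""
        rng = np.random.default_rng(0)
        data = rng.normal(size=(9, 2))
        model, node = train_som(
            data, x_dim=3, y_dim=3, rlen=3, seed=0, radius=0.0, mode="online"
        )
        # each cell is its own code up to tiny online drift toward itself
        q_err = np.linalg.norm(data - model.codes[node], axis=1)
        assert q_err.max() == pytest.approx(0.0, abs=1e-12)

    def test_batch_zero_radius_equals_lloyd(self):
        """1xK grid, zero neighborhood, batch mode == Lloyd from same init."""
        rng = np.random.default_rng(1)
        data = np.vstack(
            [rng.normal(i * 5, 0.3, size=(20, 2)) for i in range(3)]
        )
        model, node = train_som(
            data, x_dim=1, y_dim=3, rlen=60, seed=7, radius=0.0, mode="batch"
        )
        # oracle: same seeded init
        rng2 = np.random.default_rng(7)
        init = data[rng2.choice(len(data), size=3, replace=False)].copy()
        codes_ref, assign_ref = lloyd_kmeans(data, init)
        np.testing.assert_allclose(
            np.sort(model.codes, axis=0), np.sort(codes_ref, axis=0), atol=1e-8
        )
        assert adjusted_rand_score(node, assign_ref) == 1.0

    def test_same_seed_identical_codes(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(200, 4))
        m1, n1 = train_som(data, 4, 4, rlen=4, seed=5)
        m2, n2 = train_som(data, 4, 4, rlen=4, seed=5)
        np.testing.assert_array_equal(m1.codes, m2.codes)
        np.testing.assert_array_equal(n1, n2)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            train_som(np.array([[np.nan, 1.0]]), 1, 1)

    def test_small_n_warns(self):
        with pytest.warns(UserWarning, match="fewer cells"):
            train_som(np.random.default_rng(0).normal(size=(5, 2)), 3, 3, rlen=1)


# ---------------------------------------------------------------------------
# consensus metaclustering
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def separated_codes():
    rng = np.random.default_rng(3)
    return np.vstack([rng.normal(i * 20, 0.1, size=(3, 2)) for i in range(3)])


@pytest.fixture(scope="module")
def separated_codes_large():
    """3 groups x 10 codes with within-group spread (stable K>3 splits)."""
    rng = np.random.default_rng(8)
    return np.vstack([rng.normal(i * 20, 0.5, size=(10, 2)) for i in range(3)])


class TestConsensus:
    def test_three_group_recovery(self, separated_codes):
        cr = consensus_metacluster(separated_codes, maxK=5, reps=30, seed=0)
        truth = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        assert adjusted_rand_score(truth, cr.labels_by_k[3]) == 1.0
        C = cr.consensus[3]
        for block in (slice(0, 3), slice(3, 6), slice(6, 9)):
            np.testing.assert_allclose(C[block, block], 1.0)

    def test_matrix_invariants(self, separated_codes):
        cr = consensus_metacluster(separated_codes, maxK=4, reps=10, seed=1)
        for C in cr.consensus.values():
            assert (C >= 0).all() and (C <= 1).all()
            np.testing.assert_allclose(np.diag(C), 1.0)
            np.testing.assert_allclose(C, C.T)

    def test_never_cosampled_flagged(self):
        rng = np.random.default_rng(0)
        codes = rng.normal(size=(10, 2))
        with pytest.warns(UserWarning, match="never"):
            cr = consensus_metacluster(codes, maxK=2, reps=1, p_item=0.5, seed=2)
        iu = np.triu_indices(10, 1)
        never = cr.co_sample_count[iu] == 0
        assert never.any()
        assert (cr.consensus[2][iu][never] == 0).all()

    def test_maxk_too_large(self, separated_codes):
        with pytest.raises(ValueError, match="maxK"):
            consensus_metacluster(separated_codes, maxK=9)

    def test_maxk_56_supported(self):
        rng = np.random.default_rng(4)
        codes = rng.normal(size=(100, 3))
        cr = consensus_metacluster(codes, maxK=56, reps=5, seed=0)
        assert cr.ks == list(range(2, 57))


class TestElbow:
    def test_delta_small_beyond_true_k(self, separated_codes_large):
        cr = consensus_metacluster(separated_codes_large, maxK=5, reps=30, seed=0)
        df = elbow_data(cr).set_index("K")
        assert abs(df.loc[4, "delta_area"]) < 0.1
        assert abs(df.loc[5, "delta_area"]) < 0.1

    def test_area_nondecreasing(self, separated_codes):
        cr = consensus_metacluster(separated_codes, maxK=5, reps=30, seed=0)
        areas = elbow_data(cr)["area"].to_numpy()
        assert (np.diff(areas) >= -1e-12).all()

    def test_hand_integrated_toy_area(self):
        """Toy consensus values {0, 1} in equal measure: CDF is 1/2 on [0,1),
        jumping to 1 at 1, so the area under it is 1/2."""
        vals = np.array([0.0, 1.0])
        assert _cdf_area(vals) == pytest.approx(0.5)
        # and a 3/4-at-zero variant: area = 3/4
        assert _cdf_area(np.array([0.0, 0.0, 0.0, 1.0])) == pytest.approx(0.75)


# ---------------------------------------------------------------------------
# flowsom ensemble
# ---------------------------------------------------------------------------

class TestFlowsom:
    def test_recovery_on_mixture(self, sim_small):
        exp, truth = sim_small
        ca = flowsom_cluster(exp.copy(), maxK=10, reps=30, seed=1)
        ari = adjusted_rand_score(truth["cell_population"], ca.labels(8))
        assert ari >= 0.9

    def test_all_k_stored(self, sim_small):
        exp, _ = sim_small
        ca = flowsom_cluster(exp.copy(), maxK=6, reps=10, seed=0)
        assert ca.ks == [2, 3, 4, 5, 6]

    def test_identical_cells_single_metacluster(self):
        exp = _exp_from_matrix(np.ones((50, 3)))
        ca = flowsom_cluster(exp, x_dim=2, y_dim=2, maxK=3, reps=10, seed=0)
        for k in ca.ks:
            assert len(np.unique(ca.labels(k))) == 1

    def test_node_consistency(self, sim_small):
        exp, _ = sim_small
        ca = flowsom_cluster(exp.copy(), maxK=5, reps=10, seed=2)
        for k in ca.ks:
            labels = ca.labels(k)
            df = pd.DataFrame({"node": ca.node_of_cell, "lab": labels})
            assert (df.groupby("node")["lab"].nunique() == 1).all()


# ---------------------------------------------------------------------------
# graph community detection
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def two_blob_exp():
    rng = np.random.default_rng(0)
    dim = 16
    c1 = np.zeros(dim)
    c2 = np.zeros(dim)
    c2[:4] = 5.0
    m = np.vstack([rng.normal(c1, 0.3, (50, dim)), rng.normal(c2, 0.3, (50, dim))])
    return _exp_from_matrix(m)


class TestGraphCluster:
    def test_two_blob_recovery(self, two_blob_exp):
        ca = graph_cluster(two_blob_exp.copy(), k=10, seed=0)
        k_found = ca.ks[0]
        assert k_found == 2
        truth = [0] * 50 + [1] * 50
        assert adjusted_rand_score(truth, ca.labels(k_found)) == 1.0

    def test_jaccard_identity(self):
        """Two nodes with identical neighbor sets get weight 1."""
        # 4 points: a,b coincident; their k=2 neighbor sets are equal
        m = np.array([[0.0, 0], [0.001, 0], [5, 0], [5.002, 0]])
        edges, w = knn_jaccard_graph(m, 2)
        lut = dict(zip(edges, w))
        # neighbors of 0: {1, 2}; of 1: {0, 2} -> not identical.
        # use explicit symmetric construction instead:
        m = np.array([[0.0, 0], [1.0, 0], [0.5, 10.0], [0.5, -10.0]])
        edges, w = knn_jaccard_graph(m, 2)
        lut = dict(zip(edges, w))
        # 2 and 3 both have neighbor set {0, 1}
        assert lut[(2, 3)] == 1.0

    def test_modularity_beats_trivial(self, two_blob_exp):
        import igraph as ig

        exp = two_blob_exp.copy()
        ca = graph_cluster(exp, k=10, seed=0)
        edges, w = knn_jaccard_graph(exp.transformed, 10)
        g = ig.Graph(n=exp.n_cells, edges=edges)
        trivial = g.modularity([0] * exp.n_cells, weights=w)
        assert ca.params["modularity"] >= trivial

    def test_k_too_large(self, two_blob_exp):
        with pytest.raises(ValueError, match="k must be <"):
            graph_cluster(two_blob_exp.copy(), k=100)

    def test_seed_determinism(self, two_blob_exp):
        c1 = graph_cluster(two_blob_exp.copy(), k=10, seed=4)
        c2 = graph_cluster(two_blob_exp.copy(), k=10, seed=4)
        for k in c1.ks:
            np.testing.assert_array_equal(c1.labels(k), c2.labels(k))


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

class TestKmeans:
    def test_two_pair_toy(self):
        """Brute-force oracle over all partitions of {0, .1, 10, 10.1}."""
        data = np.array([[0.0], [0.1], [10.0], [10.1]])
        assign_ref, ss_ref = best_partition_by_enumeration(data, 2)
        exp = _exp_from_matrix(data)
        ca = kmeans_cluster(exp, k=2, seed=0, n_starts=10)
        labels = ca.labels(2)
        assert adjusted_rand_score(assign_ref, labels) == 1.0
        cent = np.sort(ca.params["centroids"].ravel())
        np.testing.assert_allclose(cent, [0.05, 10.05], atol=1e-12)

    def test_k1_is_global_mean(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(30, 3))
        exp = _exp_from_matrix(data)
        ca = kmeans_cluster(exp, k=1, seed=0)
        np.testing.assert_allclose(
            ca.params["centroids"][0], data.mean(0), atol=1e-9
        )

    def test_matches_exhaustive_optimum(self):
        rng = np.random.default_rng(6)
        for trial in range(5):
            n = int(rng.integers(5, 9))
            k = int(rng.integers(2, 4))
            data = rng.normal(size=(n, 2))
            _, ss_ref = best_partition_by_enumeration(data, k)
            exp = _exp_from_matrix(data)
            ca = kmeans_cluster(exp, k=k, seed=trial, n_starts=20)
            assert ca.params["inertia"] <= ss_ref + 1e-8

    def test_k_exceeds_cells(self):
        exp = _exp_from_matrix(np.zeros((3, 1)))
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster(exp, k=4)

    def test_labels_relabeled_by_size(self, sim_small):
        exp, _ = sim_small
        ca = kmeans_cluster(exp.copy(), k=4, seed=0)
        sizes = pd.Series(ca.labels(4)).value_counts()
        assert list(sizes.index) == sorted(sizes.index)  # 1 is largest
        assert (sizes.sort_index().diff().dropna() <= 0).all()
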