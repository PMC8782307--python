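import numpy as np
import pytest

from fcgrclust.fcgr import fcgr_vector
from fcgrclust.iic_core import (
    Hyperparameters,
    JointDistribution,
    assign_clusters,
    forward,
    iic_loss,
    init_network,
    input_scale,
    joint_distribution,
    perturb_parameters,
    train_single,
)
from fcgrclust.mimics import MimicParams, build_training_pairs


def direct_loss_oracle(P: np.ndarray, lam: float) -> float:
    """Independent direct-summation evaluation of -lam*H(marg) + H(cond)."""
    eps = 1e-12
    p = P.sum(axis=1)
    q = P.sum(axis=0)
    h_marg = -sum(pi * np.log(max(pi, eps)) for pi in p)
    h_cond = -sum(
        P[i, j] * (np.log(max(P[i, j], eps)) - np.log(max(q[j], eps)))
        for i in range(P.shape[0])
        for j in range(P.shape[1])
    )
    return -lam * h_marg + h_cond


def as_joint(P: np.ndarray) -> JointDistribution:
    return JointDistribution(P=P, row_marginal=P.sum(1), col_marginal=P.sum(0))


class TestInitNetwork:
    def test_deterministic(self):
        a = init_network(5, 4096, seed=3)
        b = init_network(5, 4096, seed=3)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_layer_shapes(self):
        net = init_network(5, 4096, seed=0)
        assert [w.shape for w in net.weights] == [(4096, 512), (512, 64), (64, 5)]
        assert all((b == 0).all() for b in net.biases)

    def test_kaiming_scale_first_layer(self):
        net = init_network(5, 4096, seed=1)
        std = net.weights[0].std()
        assert abs(std - np.sqrt(2 / 4096)) < 0.05 * np.sqrt(2 / 4096)


class TestForward:
    def test_rows_on_simplex(self, rng):
        net = init_network(4, 64, seed=0)
        probs = forward(net, rng.dirichlet(np.ones(64), 10))
        assert probs.shape == (10, 4)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_final_layer_gives_uniform(self, rng):
        net = init_network(4, 32, seed=0)
        net.weights[2][:] = 0
        probs = forward(net, rng.random((5, 32)))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_train_mode_reproducible(self, rng):
        net = init_network(3, 32, seed=0)
        x = rng.random((8, 32))
        a = forward(net, x, train_mode=True, rng=np.random.default_rng(5))
        b = forward(net, x, train_mode=True, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_dimension_mismatch(self, rng):
        net = init_network(3, 32, seed=0)
        with pytest.raises(ValueError, match="dim"):
            forward(net, rng.random((4, 33)))


class TestJointDistribution:
    def test_single_one_hot_pair(self):
        e1 = np.eye(3)[[0]]
        joint = joint_distribution(e1, e1)
        assert joint.P[0, 0] == 1.0 and joint.P.sum() == 1.0

    def test_crossed_pairs_symmetrize(self):
        px = np.eye(2)[[0, 1]]
        pxt = np.eye(2)[[1, 0]]
        joint = joint_distribution(px, pxt)
        np.testing.assert_allclose(joint.P, [[0, 0.5], [0.5, 0]])

    def test_random_batches_sum_to_one(self, rng):
        for _ in range(20):
            px = rng.dirichlet(np.ones(5), 16)
            pxt = rng.dirichlet(np.ones(5), 16)
            joint = joint_distribution(px, pxt)
            assert abs(joint.P.sum() - 1.0) < 1e-9
            np.testing.assert_allclose(joint.P, joint.P.T, atol=1e-15)


class TestIicLoss:
    def test_diagonal_uniform_closed_form(self):
        P = np.eye(5) / 5
        out = iic_loss(as_joint(P), 2.5)
        assert abs(out.marginal_entropy - np.log(5)) < 1e-9
        assert abs(out.conditional_entropy) < 1e-9
        assert abs(out.loss - (-2.5 * np.log(5))) < 1e-9

    def test_all_uniform_closed_form(self):
        P = np.full((5, 5), 1 / 25)
        out = iic_loss(as_joint(P), 2.5)
        assert abs(out.loss - (-1.5 * np.log(5))) < 1e-9

    def test_degenerate_collapse_is_worse_than_diagonal(self):
        P = np.zeros((5, 5))
        P[0, 0] = 1.0
        out = iic_loss(as_joint(P), 2.5)
        assert abs(out.loss) < 1e-9  # H_marg = H_cond = 0
        assert out.loss > iic_loss(as_joint(np.eye(5) / 5), 2.5).loss

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(50):
            P = rng.dirichlet(np.ones(25)).reshape(5, 5)
            P = (P + P.T) / 2
            assert abs(iic_loss(as_joint(P), 2.5).loss - direct_loss_oracle(P, 2.5)) < 1e-9

    def test_permutation_invariance(self, rng):
        for _ in range(20):
            P = rng.dirichlet(np.ones(25)).reshape(5, 5)
            P = (P + P.T) / 2
            perm = rng.permutation(5)
            Pp = P[np.ix_(perm, perm)]
            assert abs(iic_loss(as_joint(P), 2.5).loss - iic_loss(as_joint(Pp), 2.5).loss) < 1e-9

    def test_loss_bounds_on_random_joints(self, rng):
        c, lam = 5, 2.5
        for _ in range(50):
            px = rng.dirichlet(np.ones(c), 32)
            pxt = rng.dirichlet(np.ones(c), 32)
            out = iic_loss(joint_distribution(px, pxt), lam)
            assert 0 <= out.marginal_entropy <= np.log(c) + 1e-12
            assert -lam * np.log(c) - 1e-9 <= out.loss <= np.log(c) + 1e-9


class TestPerturbParameters:
    def test_sigma_zero_identity(self):
        net = init_network(3, 64, seed=0)
        out = perturb_parameters(net, 0.0, np.random.default_rng(0))
        for a, b in zip(net.weights, out.weights):
            np.testing.assert_array_equal(a, b)

    def test_noise_scale(self):
        net = init_network(3, 256, seed=0)
        out = perturb_parameters(net, 0.01, np.random.default_rng(1))
        noise = out.weights[0] - net.weights[0]
        assert noise.size >= 1e4
        assert abs(noise.std() - 0.01) < 0.001

    def test_reproducible(self):
        net = init_network(3, 64, seed=0)
        a = perturb_parameters(net, 0.05, np.random.default_rng(7))
        b = perturb_parameters(net, 0.05, np.random.default_rng(7))
        np.testing.assert_array_equal(a.weights[1], b.weights[1])


@pytest.fixture(scope="module")
def small_pairs(small_two_cluster_dataset):
    ds, _spec = small_two_cluster_dataset
    pairs = build_training_pairs(ds.sequences, MimicParams(m=3, seed=7), k=4)
    fcgrs = np.stack([fcgr_vector(s, 4) for s in ds.sequences])
    return pairs, fcgrs, ds


class TestTrainSingle:
    def test_zero_epochs_returns_initial_network(self, small_pairs):
        pairs, _, _ = small_pairs
        hp = Hyperparameters(c=2, k=4, epochs=0, seed=1)
        net, history = train_single(pairs, hp, seed=1)
        assert history == []
        ref = train_single(pairs, hp, seed=1)[0]
        for a, b in zip(net.weights, ref.weights):
            np.testing.assert_array_equal(a, b)

    def test_empty_pairs_error(self):
        with pytest.raises(ValueError, match="empty"):
            train_single([], Hyperparameters(c=2, epochs=1), seed=0)

    def test_training_reduces_loss_on_separable_data(self, small_pairs):
        """Median over seeds of (final - first) epoch loss is negative."""
        pairs, _, _ = small_pairs
        deltas = []
        for seed in range(5):
            hp = Hyperparameters(c=2, k=4, epochs=60, batch_size=512, seed=seed)
            _, history = train_single(pairs, hp, seed=seed)
            deltas.append(history[-1].loss - history[0].loss)
        assert np.median(deltas) < 0

    def test_deterministic_given_seed(self, small_pairs):
        pairs, _, _ = small_pairs
        hp = Hyperparameters(c=2, k=4, epochs=3, seed=11)
        a, ha = train_single(pairs, hp, seed=11)
        b, hb = train_single(pairs, hp, seed=11)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)
        assert [h.loss for h in ha] == [h.loss for h in hb]


class TestAssignClusters:
    def test_exact_tie_goes_to_lowest_index(self):
        net = init_network(3, 8, seed=0)
        net.weights[2][:] = 0  # uniform output: a three-way tie on every row
        assignment = assign_clusters(net, np.full((4, 8), 1 / 8))
        assert assignment.probabilities.shape == (4, 3)
        np.testing.assert_array_equal(assignment.hard_labels, 0)

    def test_labels_match_argmax(self, small_pairs):
        pairs, fcgrs, _ = small_pairs
        net, _ = train_single(pairs, Hyperparameters(c=2, k=4, epochs=2, seed=0), seed=0)
        a = assign_clusters(net, fcgrs)
        np.testing.assert_array_equal(a.hard_labels, a.probabilities.argmax(axis=1))

    def test_input_scale_restores_order_one_entries(self):
        assert input_scale(256) == 256.0
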