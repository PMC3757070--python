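"""Spiking-network dynamics, plasticity rules and initialization checks."""

import numpy as np
import pytest

from sparsedev import sailnet as sn
from sparsedev.synthimg import PatchSampler


def scalar_lif_trace(drive, theta, eta, n_steps):
    """Independent hand-loop oracle of the single-neuron recurrence."""
    u, count = 0.0, 0
    for _ in range(n_steps):
        u = (1 - eta) * u + eta * drive
        if u > theta:
            count += 1
            u = 0.0
    return count


def two_neuron_lif_trace(drives, w, theta, eta, n_steps):
    """Hand loop for two neurons with mutual inhibition (one-step delay)."""
    u = [0.0, 0.0]
    y = [0, 0]
    counts = [0, 0]
    for _ in range(n_steps):
        new_u = [
            (1 - eta) * u[0] + eta * (drives[0] - w[0][1] * y[1]),
            (1 - eta) * u[1] + eta * (drives[1] - w[1][0] * y[0]),
        ]
        new_y = [0, 0]
        for i in (0, 1):
            if new_u[i] > theta[i]:
                counts[i] += 1
                new_u[i] = 0.0
                new_y[i] = 1
        u, y = new_u, new_y
    return counts


def single_neuron_state(q_value, theta, n_pixels=4, **rates):
    q = np.full((1, n_pixels), q_value)
    # SailnetState requires >= 1 neuron; W is 1x1 zero
    return sn.SailnetState(
        Q=q,
        W=np.zeros((1, 1)),
        theta=np.array([theta]),
        n_neurons=1,
        patch_edge=2,
        **{**dict(p=0.05, alpha=0.1, beta=0.01, gamma=0.1), **rates},
    )


class TestLifInference:
    @pytest.mark.parametrize(
        "drive,theta,eta,n_steps",
        [
            (0.3, 0.2, 0.1, 20),
            (0.3, 0.2, 1.0, 20),
            (1.7, 1.0, 0.1, 50),
            (0.3, 1.0, 1.0, 20),  # sub-threshold forever: zero spikes
            (-0.5, 0.4, 0.2, 30),  # negative drive never crosses
        ],
    )
    def test_single_neuron_matches_hand_trace(self, drive, theta, eta, n_steps):
        state = single_neuron_state(drive / 4.0, theta)
        patch = np.ones(4)  # Q . x = drive
        cfg = sn.LifDynamicsConfig(n_steps=n_steps, eta=eta)
        counts = sn.lif_inference(state, patch, cfg)
        assert counts[0] == scalar_lif_trace(drive, theta, eta, n_steps)

    def test_two_neurons_with_inhibition_match_hand_trace(self):
        w = np.array([[0.0, 0.8], [0.6, 0.0]])
        theta = np.array([0.3, 0.25])
        state = sn.SailnetState(
            Q=np.array([[0.9], [0.7]]),  # one pixel: drives are 0.9 and 0.7
            W=w,
            theta=theta,
            p=0.05,
            alpha=0.1,
            beta=0.01,
            gamma=0.1,
            n_neurons=2,
            patch_edge=1,
        )
        cfg = sn.LifDynamicsConfig(n_steps=40, eta=0.2)
        counts = sn.lif_inference(state, np.array([1.0]), cfg)
        expected = two_neuron_lif_trace([0.9, 0.7], w, theta, 0.2, 40)
        assert list(counts) == expected

    def test_unattainable_threshold_silences(self, rng):
        state = single_neuron_state(0.5, theta=1e12)
        counts = sn.lif_inference(state, rng.standard_normal(4))
        assert counts[0] == 0

    def test_inhibition_reduces_total_firing(self):
        q = np.tile(np.array([[0.4, 0.4, 0.4, 0.4]]), (2, 1))
        theta = np.array([0.5, 0.5])
        common = dict(p=0.05, alpha=0.1, beta=0.01, gamma=0.1, n_neurons=2, patch_edge=2)
        free = sn.SailnetState(Q=q, W=np.zeros((2, 2)), theta=theta, **common)
        coupled = sn.SailnetState(
            Q=q, W=np.array([[0.0, 5.0], [5.0, 0.0]]), theta=theta, **common
        )
        patch = np.ones(4)
        n_free = sn.lif_inference(free, patch).sum()
        n_coupled = sn.lif_inference(coupled, patch).sum()
        assert n_coupled < n_free

    def test_batch_and_single_agree(self, rng):
        state = sn.init_dense_regime(5, 4, seed=0)
        patches = rng.standard_normal((3, 16))
        batch_counts = sn.lif_inference(state, patches)
        for k in range(3):
            np.testing.assert_array_equal(
                batch_counts[k], sn.lif_inference(state, patches[k])
            )

    def test_shape_mismatch_raises(self, rng):
        state = sn.init_dense_regime(5, 4, seed=0)
        with pytest.raises(ValueError):
            sn.lif_inference(state, rng.standard_normal(15))


class TestUpdateParameters:
    def test_silent_network_updates(self, rng):
        """n = 0 for all neurons: Q frozen, thresholds fall by gamma * p."""
        state = sn.init_sparse_regime(6, 4, seed=1)
        patch = rng.standard_normal(16)
        counts = np.zeros(6, dtype=int)
        new = sn.update_parameters(state, patch, counts)
        np.testing.assert_array_equal(new.Q, state.Q)
        np.testing.assert_allclose(new.theta, state.theta - state.gamma * state.p)
        # W decrement alpha * (0 - p^2), rectified at zero
        expected_w = np.clip(state.W - state.alpha * state.p**2, 0.0, None)
        np.fill_diagonal(expected_w, 0.0)
        np.testing.assert_allclose(new.W, expected_w)

    def test_at_target_rate_thresholds_and_w_fixed(self, rng):
        """n_i = p exactly (p = 1) leaves theta and W unchanged."""
        state = sn.init_sparse_regime(4, 4, seed=2, p=1.0)
        patch = rng.standard_normal(16)
        counts = np.ones(4, dtype=int)
        new = sn.update_parameters(state, patch, counts)
        np.testing.assert_allclose(new.theta, state.theta)
        np.testing.assert_allclose(new.W, state.W)

    def test_q_rule_direct_substitution(self, rng):
        state = sn.init_dense_regime(3, 4, seed=3)
        patch = rng.standard_normal(16)
        counts = np.array([2, 0, 1])
        new = sn.update_parameters(state, patch, counts)
        for i, n_i in enumerate(counts):
            expected = state.Q[i] + state.beta * n_i * (patch - n_i * state.Q[i])
            np.testing.assert_allclose(new.Q[i], expected)

    def test_rectification_always_holds(self, rng):
        state = sn.init_dense_regime(8, 4, seed=4)
        for _ in range(5):
            patch = rng.standard_normal(16)
            counts = rng.integers(0, 4, size=8)
            state = sn.update_parameters(state, patch, counts)
            assert np.all(state.W >= 0)
            assert np.all(np.diag(state.W) == 0)

    def test_batch_update_averages(self, rng):
        state = sn.init_dense_regime(3, 4, seed=5)
        patches = rng.standard_normal((2, 16))
        counts = np.array([[1, 0, 2], [0, 1, 0]])
        new = sn.update_parameters(state, patches, counts)
        # average of the two single-patch updates applied jointly
        dq = np.zeros_like(state.Q)
        for b in range(2):
            n = counts[b][:, None].astype(float)
            dq += state.beta * n * (patches[b][None, :] - n * state.Q) / 2
        np.testing.assert_allclose(new.Q, state.Q + dq)


class TestInitRegimes:
    def test_lognormal_w_moments(self):
        """-log W over off-diagonal entries is N(0, 1) to sampling accuracy."""
        state = sn.init_sparse_regime(350, 4, seed=0)
        off = ~np.eye(350, dtype=bool)
        z = -np.log(state.W[off])
        assert abs(z.mean()) < 0.02
        assert abs(z.std() - 1.0) < 0.02

    def test_theta_within_interval_and_regime_ordering(self):
        sparse = sn.init_sparse_regime(40, 4, seed=1)
        dense = sn.init_dense_regime(40, 4, seed=1)
        assert sparse.theta.min() >= 2.0 and sparse.theta.max() <= 8.0
        assert dense.theta.mean() < sparse.theta.mean()

    def test_dense_w_rectified_nonnegative(self):
        state = sn.init_dense_regime(30, 4, seed=2)
        assert state.W.min() >= 0 and np.all(np.diag(state.W) == 0)

    def test_seeded_determinism(self):
        a = sn.init_sparse_regime(10, 4, seed=7)
        b = sn.init_sparse_regime(10, 4, seed=7)
        np.testing.assert_array_equal(a.Q, b.Q)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_q_rows_unit_drive_scale(self):
        state = sn.init_sparse_regime(50, 8, seed=3)
        l2 = np.linalg.norm(state.Q, axis=1)
        assert np.all(np.abs(l2 - 1.0) < 0.35)  # L1-normalized rows, L2 near 1

    def test_too_few_neurons_raises(self):
        with pytest.raises(ValueError):
            sn.init_sparse_regime(1, 4, seed=0)


class TestTrain:
    def test_frozen_network_is_stationary_and_length_correct(self):
        sampler = PatchSampler(4, seed=0, n_images=4, image_edge=32)
        state = sn.init_dense_regime(16, 4, seed=0, alpha=0.0, beta=0.0, gamma=0.0)
        state, traj = sn.train(
            state,
            sampler,
            n_batches=40,
            batch_size=10,
            measure_every=10,
            metrics_cfg=sn.MetricsConfig(measure_size=50),
            debug_checks=True,
        )
        assert len(traj) == 4
        for col in ("SA_mu", "SP_mu", "SL_mu", "mean_rate"):
            assert traj[col].nunique() == 1  # frozen network, fixed measurement batch

    def test_checkpoint_zero_measures_initial_state(self):
        sampler = PatchSampler(4, seed=0, n_images=4, image_edge=32)
        state = sn.init_dense_regime(16, 4, seed=0)
        _, traj = sn.train(
            state,
            sampler,
            n_batches=5,
            batch_size=5,
            checkpoints=[0, 5],
            metrics_cfg=sn.MetricsConfig(measure_size=30),
        )
        assert list(traj["batch"]) == [0, 5]

    def test_invalid_checkpoints_raise(self):
        sampler = PatchSampler(4, seed=0, n_images=4, image_edge=32)
        state = sn.init_dense_regime(4, 4, seed=0)
        with pytest.raises(ValueError):
            sn.train(state, sampler, n_batches=5, checkpoints=[2, 9])


def test_state_hdf5_roundtrip(tmp_path):
    state = sn.init_sparse_regime(6, 4, seed=0)
    path = tmp_path / "state.h5"
    sn.save_state(path, state)
    loaded = sn.load_state(path)
    np.testing.assert_array_equal(loaded.Q, state.Q)
    np.testing.assert_array_equal(loaded.W, state.W)
    np.testing.assert_array_equal(loaded.theta, state.theta)
    assert loaded.p == state.p and loaded.patch_edge == state.patch_edge
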