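"""Unit and property tests for the RBM core: initialization, sampling,
the constrained CD-1 update, and reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgrbm import (
    RBMState,
    cd1_update,
    init_rbm,
    reconstruct,
    sample_hidden,
    sample_visible,
)
from conftest import stub_gibbs

SIG1 = 0.7310585786300049  # logistic(1)


class TestInit:
    def test_base_variant(self, rng):
        s = init_rbm(200, 1000, "base", rng)
        assert s.W.shape == (200, 1000)
        assert np.all(s.mask == 1)
        assert np.all(s.cost == 0)
        assert np.all(s.epsilon == 0.1)

    def test_sparse_variant(self, rng):
        s = init_rbm(200, 1000, "sparse", rng)
        assert np.all(s.epsilon == 0.1)
        assert np.all(s.cost == 0.9)
        assert np.all(s.mask == 1)

    @pytest.mark.parametrize("variant", ["base", "sparse", "neuro", "neuro_sparse_conn"])
    def test_biases_start_at_zero(self, variant, rng):
        s = init_rbm(50, 30, variant, rng)
        assert np.all(s.a == 0) and np.all(s.b == 0)

    def test_neuro_parameters_track_age(self, rng):
        s = init_rbm(100, 500, "neuro", rng)
        assert np.all((s.age >= -1) & (s.age <= 1))
        assert np.all((s.epsilon >= 0.1) & (s.epsilon <= 0.3))
        assert np.all((s.cost >= 0) & (s.cost <= 0.9))
        # plasticity and inhibition move in opposite directions with age
        order = np.argsort(s.age)
        assert np.all(np.diff(s.epsilon[order]) <= 1e-12)
        assert np.all(np.diff(s.cost[order]) >= -1e-12)

    def test_sparse_connectivity_masks_young_units(self, rng):
        s = init_rbm(200, 500, "neuro_sparse_conn", rng)
        frac = s.mask.mean(axis=0)
        young = s.age < -0.5
        mature = s.age > 0.5
        assert frac[young].mean() < frac[mature].mean()
        assert np.all(s.W[s.mask == 0] == 0)

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            init_rbm(0, 10, "base", rng)
        with pytest.raises(ValueError):
            init_rbm(10, 10, "does_not_exist", rng)


class TestSampling:
    def test_zero_weights_give_half_probability(self, make_state, rng):
        s = make_state(4, 3)
        s.W[:] = 0
        v = np.array([[1.0, 0.0, 1.0, 1.0]])
        probs, samples = sample_hidden(s, v, rng)
        assert np.allclose(probs, 0.5)
        assert set(np.unique(samples)) <= {0.0, 1.0}
        probs_v, _ = sample_visible(s, np.array([[1.0, 0.0, 0.0]]), rng)
        assert np.allclose(probs_v, 0.5)

    def test_single_unit_closed_forms(self, rng, schedule):
        s = RBMState(
            W=np.array([[2.0]]), a=np.array([1.0]), b=np.array([-1.0]),
            mask=np.ones((1, 1), dtype=np.int8), age=np.array([1.0]),
            epsilon=np.array([0.1]), decay=np.zeros(1), cost=np.zeros(1),
        )
        probs, _ = sample_hidden(s, np.array([[1.0]]), rng)
        assert probs[0, 0] == pytest.approx(SIG1, abs=1e-12)  # sigma(-1 + 2)
        s.W[0, 0] = -2.0
        probs_v, _ = sample_visible(s, np.array([[1.0]]), rng)
        assert probs_v[0, 0] == pytest.approx(1 - SIG1, abs=1e-12)  # sigma(1 - 2)

    def test_saturation(self, make_state, rng):
        s = make_state(4, 3)
        s.b[:] = 100.0
        s.W[:] = np.abs(s.W)
        probs, samples = sample_hidden(s, np.ones((1, 4)), rng)
        assert np.allclose(probs, 1.0)
        assert np.all(samples == 1.0)

    def test_hidden_drive_ignores_masked_weights(self, make_state, rng):
        s = make_state(4, 3)
        s.mask[:, 0] = 0
        s.W *= s.mask
        probs, _ = sample_hidden(s, np.ones((1, 4)), rng)
        assert probs[0, 0] == pytest.approx(0.5)

    def test_shape_and_binary_validation(self, make_state, rng):
        s = make_state(4, 3)
        with pytest.raises(ValueError):
            sample_hidden(s, np.ones((1, 5)), rng)
        with pytest.raises(ValueError):
            sample_hidden(s, np.full((1, 4), 0.5), rng)


class TestCD1:
    def test_no_learning_terms_means_no_change(self, make_state, rng):
        s = make_state(4, 3)
        s.epsilon[:] = 0
        s.decay[:] = 0
        s.cost[:] = 0
        W0, a0, b0 = s.W.copy(), s.a.copy(), s.b.copy()
        cd1_update(s, np.array([[1.0, 0.0, 1.0, 0.0]]), rng)
        assert np.array_equal(s.W, W0)
        assert np.array_equal(s.a, a0)
        assert np.array_equal(s.b, b0)

    def test_clamped_states_leave_only_sparsity_term(self, make_state, rng, monkeypatch):
        # identical data-driven and reconstructed states cancel the Hebbian terms
        s = make_state(3, 2, variant="sparse")
        s.decay[:] = 0
        v = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        h = np.array([[1.0, 0.0], [1.0, 1.0]])
        stub_gibbs(monkeypatch, h_probs=h, h_samples=h, v_probs=v, v_samples=v)
        W0 = s.W.copy()
        cd1_update(s, v, rng, stats="sample")
        q = h.mean(axis=0)
        expected = -s.cost * (q - s.p_target)
        assert np.allclose(s.W - W0, np.tile(expected, (3, 1)))

    @pytest.mark.parametrize("stats", ["sample", "prob"])
    def test_matches_brute_force_oracle(self, stats, rng, monkeypatch, cd1_brute_force):
        # 3 visible x 2 hidden toy with the Gibbs pass pinned to fixed states
        s = RBMState(
            W=np.array([[0.2, -0.1], [0.0, 0.3], [-0.4, 0.1]]),
            a=np.array([0.05, -0.02, 0.0]), b=np.array([0.1, -0.3]),
            mask=np.array([[1, 1], [1, 0], [1, 1]], dtype=np.int8),
            age=np.zeros(2), epsilon=np.array([0.1, 0.25]),
            decay=np.array([0.0, 0.02]), cost=np.array([0.0, 0.9]),
            p_target=0.05,
        )
        s.W *= s.mask
        v = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        hp = np.array([[0.9, 0.2], [0.6, 0.7]])
        h = np.array([[1.0, 0.0], [1.0, 1.0]])
        vp = np.array([[0.8, 0.1, 0.9], [0.3, 0.9, 0.5]])
        vr = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        hp2 = np.array([[0.5, 0.4], [0.2, 0.8]])
        hr = np.array([[0.0, 1.0], [0.0, 1.0]])
        stub_gibbs(monkeypatch, h_probs=hp, h_samples=h, v_probs=vp, v_samples=vr,
                   h_probs2=hp2, h_samples2=hr)
        hd, hrr = (hp, hp2) if stats == "prob" else (h, hr)
        expW, expA, expB = cd1_brute_force(
            s.W, s.a, s.b, s.mask, s.epsilon, s.decay, s.cost, s.p_target,
            v, hd, vr, hrr,
        )
        cd1_update(s, v, rng, stats=stats)
        assert np.allclose(s.W, expW, atol=1e-12)
        assert np.allclose(s.a, expA, atol=1e-12)
        assert np.allclose(s.b, expB, atol=1e-12)

    def test_batch_hebbian_decomposes_over_patterns(self, make_state, monkeypatch, cd1_brute_force):
        # the batch update equals the mean of per-pattern Hebbian statistics
        v = np.array([[1.0, 0.0], [1.0, 1.0]])
        h = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        vr = np.array([[0.0, 1.0], [1.0, 0.0]])
        hr = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        s = make_state(2, 3)
        s.decay[:] = 0
        s.cost[:] = 0
        stub_gibbs(monkeypatch, h_probs=h, h_samples=h, v_probs=vr, v_samples=vr,
                   h_probs2=hr, h_samples2=hr)
        W0 = s.W.copy()
        cd1_update(s, v, np.random.default_rng(0), stats="sample")
        per_pattern = np.mean(
            [np.outer(v[k], h[k]) - np.outer(vr[k], hr[k]) for k in range(2)], axis=0
        )
        assert np.allclose(s.W - W0, s.epsilon * per_pattern)

    def test_longer_gibbs_chains_also_respect_the_mask(self, rng):
        s = init_rbm(20, 10, "sparse", rng)
        s.mask = (rng.random((20, 10)) < 0.5).astype(np.int8)
        s.W *= s.mask
        v = (rng.random((5, 20)) < 0.1).astype(float)
        cd1_update(s, v, rng, k=3)
        assert np.max(np.abs(s.W[s.mask == 0])) == 0.0
        with pytest.raises(ValueError):
            cd1_update(s, v, rng, k=0)

    def test_mask_conserved_under_training(self, rng):
        s = init_rbm(30, 20, "base", rng)
        s.mask = (rng.random((30, 20)) < 0.5).astype(np.int8)
        s.W *= s.mask
        for _ in range(200):
            v = (rng.random((5, 30)) < 0.1).astype(float)
            cd1_update(s, v, rng)
        assert np.max(np.abs(s.W[s.mask == 0])) == 0.0

    def test_sparsity_pressure_monotonically_lowers_hidden_bias(
        self, make_state, rng, monkeypatch
    ):
        # with clamped Gibbs states and q > p the penalty strictly lowers b
        s = make_state(3, 2, variant="sparse")
        s.decay[:] = 0
        v = np.array([[1.0, 0.0, 1.0]])
        h = np.array([[1.0, 1.0]])  # q = 1 > p
        stub_gibbs(monkeypatch, h_probs=h, h_samples=h, v_probs=v, v_samples=v)
        prev = s.b.copy()
        for _ in range(5):
            cd1_update(s, v, rng, stats="sample")
            assert np.all(s.b < prev)
            prev = s.b.copy()


class TestReconstruct:
    def _autoassociator(self):
        # one hidden unit copies the stored pattern via saturated weights
        pattern = np.array([1.0, 0.0, 1.0, 0.0])
        W = np.where(pattern[:, None] == 1, 50.0, -50.0)
        return RBMState(
            W=W, a=np.full(4, -25.0), b=np.array([0.0]),
            mask=np.ones((4, 1), dtype=np.int8), age=np.zeros(1),
            epsilon=np.array([0.1]), decay=np.zeros(1), cost=np.zeros(1),
        ), pattern

    def test_stored_pattern_is_reconstructed(self, rng):
        s, pattern = self._autoassociator()
        assert np.array_equal(reconstruct(s, pattern), pattern)
        assert np.array_equal(reconstruct(s, pattern, mode="stochastic", rng=rng), pattern)

    def test_zero_state_mean_field_ties_reconstruct_as_one(self, make_state):
        s = make_state(4, 3)
        s.W[:] = 0
        out = reconstruct(s, np.array([1.0, 0.0, 0.0, 1.0]))
        assert np.all(out == 1.0)  # every probability is exactly 0.5

    def test_mean_field_is_deterministic(self, make_state):
        s = make_state(6, 4, seed=3)
        v = np.array([1.0, 0.0, 0.0, 1.0, 1.0, 0.0])
        assert np.array_equal(reconstruct(s, v), reconstruct(s, v))

    def test_unknown_mode(self, make_state):
        with pytest.raises(ValueError):
            reconstruct(make_state(), np.zeros(4), mode="nope")


@settings(derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000))
def test_checkpoint_roundtrip(tmp_path_factory, seed):
    """Saving and reloading a state preserves every array and scalar."""
    s = init_rbm(10, 8, "neuro_sparse_conn", np.random.default_rng(seed))
    path = tmp_path_factory.mktemp("ckpt") / "state.npz"
    s.save(path)
    s2 = RBMState.load(path)
    for name in ("W", "a", "b", "mask", "age", "epsilon", "decay", "cost"):
        assert np.array_equal(getattr(s, name), getattr(s2, name)), name
    assert (s2.p_target, s2.sigma_init, s2.variant, s2.sparse_connectivity) == (
        s.p_target, s.sigma_init, s.variant, s.sparse_connectivity
    )
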