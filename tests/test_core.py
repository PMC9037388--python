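"""Unit and property tests for the particle-filter attention mechanism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spafilter.core import (
    AttentionVector,
    ConfigurationError,
    ContractError,
    DegenerateInputError,
    FeatureTensor,
    ReturnObservation,
    SPAConfig,
    apply_attention,
    attention_to_csv,
    bottom_up_probs,
    ensemble_attention,
    ensemble_to_csv,
    init_ensemble,
    load_ensemble,
    movement_step,
    particle_attention,
    particle_errors,
    resample,
    resampling_weights,
    save_ensemble,
    update_attention,
)

from conftest import make_ensemble
from oracles import (
    bottom_up_probs_naive,
    ensemble_attention_naive,
    particle_attention_naive,
    resampling_weights_naive,
)


class TestConfig:
    def test_table_defaults(self):
        mc = SPAConfig.multiple_choice(K=512)
        assert (mc.N, mc.tau_bu, mc.tau_td, mc.c_max, mc.t_max) == (250, 10, 10, 1, 1)
        oc = SPAConfig.object_collection(K=512)
        assert (oc.N, oc.tau_bu, oc.tau_td, oc.c_max, oc.t_max) == (250, 1, 10, 1000, 10)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"K": 0},
            {"K": 4, "N": 0},
            {"K": 4, "phi": 1.5},
            {"K": 4, "tau_td": -1.0},
            {"K": 4, "c_max": 0},
            {"K": 4, "obs_buffer": 0},
            {"K": 4, "zero_particle_fallback": "explode"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SPAConfig(**kwargs)


class TestEnsembleInit:
    def test_seed_determinism(self):
        cfg = SPAConfig(K=3, N=4, seed=42)
        assert np.array_equal(init_ensemble(cfg).states, init_ensemble(cfg).states)

    def test_forced_all_ones(self):
        cfg = SPAConfig(K=5, N=8, seed=0, p_init=1.0)
        assert init_ensemble(cfg).states.all()

    def test_default_scale_shape(self):
        cfg = SPAConfig(K=512, N=250, seed=0)
        ens = init_ensemble(cfg)
        assert ens.states.shape == (250, 512)
        assert np.isin(ens.states, (0, 1)).all()


class TestBottomUp:
    def test_hand_instance(self):
        p = bottom_up_probs(np.array([2.0, 1.0, 1.0, 0.0]), 10.0)
        np.testing.assert_allclose(
            p, [1.0, 0.0820849986, 0.0820849986, 0.0067379470], atol=1e-9
        )

    def test_uniform_means_give_ones(self):
        assert np.allclose(bottom_up_probs(np.full(6, 3.3), 10.0), 1.0)

    def test_zero_strength_gives_ones(self):
        assert np.allclose(bottom_up_probs(np.array([5.0, 1.0, 0.1]), 0.0), 1.0)

    def test_all_zero_means_rejected(self):
        with pytest.raises(DegenerateInputError):
            bottom_up_probs(np.zeros(4), 10.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        means=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=8),
        tau=st.floats(0.0, 50.0),
    )
    def test_matches_naive_and_argmax_is_one(self, means, tau):
        p = bottom_up_probs(np.array(means), tau)
        np.testing.assert_allclose(p, bottom_up_probs_naive(means, tau), atol=1e-12)
        assert p[int(np.argmax(means))] == 1.0
        assert ((p > 0) & (p <= 1)).all()
        # monotone nondecreasing in the channel mean
        order = np.argsort(means)
        assert (np.diff(p[order]) >= -1e-12).all()


class TestMovement:
    def test_zero_phi_is_identity(self, small_ensemble):
        before = small_ensemble.states.copy()
        after = movement_step(small_ensemble, np.full(4, 0.5), 0.0)
        assert np.array_equal(after.states, before)

    def test_full_refresh_forced(self):
        ens = make_ensemble(np.zeros((10, 2)))
        after = movement_step(ens, np.array([1.0, 0.0]), 1.0)
        assert np.array_equal(after.states, np.tile([1, 0], (10, 1)))

    def test_refresh_fraction_binomial(self):
        n = 10000
        ens = make_ensemble(np.zeros((n, 3)), seed=5)
        after = movement_step(ens, np.ones(3), 0.5)
        frac = after.states.all(axis=1).mean()
        sigma = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * sigma

    def test_states_stay_binary(self, small_ensemble):
        after = movement_step(small_ensemble, np.full(4, 0.3), 0.7)
        assert np.isin(after.states, (0, 1)).all()

    def test_bad_probs_rejected(self, small_ensemble):
        with pytest.raises(ContractError):
            movement_step(small_ensemble, np.full(4, 1.5), 0.5)


class TestParticleAttention:
    @pytest.mark.parametrize(
        "state, expected",
        [
            ([1, 0, 1, 0], [0.5, 0.0, 0.5, 0.0]),
            ([0, 0, 0, 0], [0.25, 0.25, 0.25, 0.25]),
            ([1, 1, 1, 1], [0.25, 0.25, 0.25, 0.25]),
        ],
    )
    def test_normalisation_and_fallback(self, state, expected):
        np.testing.assert_allclose(particle_attention(state).weights, expected)
        np.testing.assert_allclose(
            particle_attention(state).weights, particle_attention_naive(state)
        )


class CountingValue:
    """Value function that records how many evaluations it performs."""

    def __init__(self, fn):
        self.fn = fn
        self.calls = 0

    def __call__(self, features, attention):
        self.calls += 1
        return self.fn(features, attention)


class TestParticleErrors:
    def test_perfect_prediction_gives_zero(self, vector_features):
        ens = make_ensemble([[1, 0, 0, 1], [0, 1, 1, 0]])
        obs = ReturnObservation(vector_features, 0.75)
        deltas = particle_errors(ens, obs, lambda f, a: 0.75)
        np.testing.assert_allclose(deltas, 0.0)

    def test_hand_arithmetic(self, vector_features):
        ens = make_ensemble([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]])
        preds = {0: 1.0, 1: 0.5, 2: 0.0}

        def value_fn(features, attention):
            return preds[int(np.argmax(attention.weights))]

        obs = ReturnObservation(vector_features, 1.0)
        np.testing.assert_allclose(
            particle_errors(ens, obs, value_fn), [0.0, 0.25, 1.0]
        )

    def test_identical_rows_single_evaluation(self, vector_features):
        ens = make_ensemble(np.tile([1, 0, 1, 0], (25, 1)))
        counting = CountingValue(lambda f, a: 0.0)
        particle_errors(ens, ReturnObservation(vector_features, 1.0), counting)
        assert counting.calls == 1

    def test_memoized_equals_naive(self, vector_features, rng):
        states = (rng.random((40, 4)) < 0.5).astype(np.uint8)
        ens = make_ensemble(states)

        def value_fn(features, attention):
            return float(attention.weights @ features.channel_means)

        obs = ReturnObservation(vector_features, 0.5)
        fast = particle_errors(ens, obs, value_fn)
        naive = [
            (0.5 - value_fn(vector_features, particle_attention(s))) ** 2
            for s in states
        ]
        np.testing.assert_allclose(fast, naive, atol=1e-15)


class TestResamplingWeights:
    def test_equal_errors_split_evenly(self):
        np.testing.assert_allclose(
            resampling_weights(np.array([0.3, 0.3]), 10.0), [0.5, 0.5]
        )

    def test_hand_instance(self):
        w = resampling_weights(np.array([0.0, 1.0]), 10.0)
        np.testing.assert_allclose(w, [0.9999546, 4.5398e-5], atol=1e-7)

    def test_zero_strength_uniform(self):
        w = resampling_weights(np.array([0.0, 5.0, 2.0, 0.1]), 0.0)
        np.testing.assert_allclose(w, 0.25)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        errors=st.lists(st.floats(0.0, 50.0), min_size=2, max_size=10),
        tau=st.floats(0.0, 100.0),
    )
    def test_matches_naive_and_order_reversed(self, errors, tau):
        w = resampling_weights(np.array(errors), tau)
        np.testing.assert_allclose(w, resampling_weights_naive(errors, tau), atol=1e-12)
        assert abs(w.sum() - 1.0) < 1e-12
        # weight ordering is the reverse of error ordering
        order = np.argsort(errors)
        assert (np.diff(w[order]) <= 1e-12).all()
        assert w[int(np.argmin(errors))] == w.max()


class TestResample:
    def test_degenerate_weight_copies_one_row(self, small_ensemble):
        w = np.zeros(6)
        w[0] = 1.0
        after = resample(small_ensemble, w)
        assert (after.states == small_ensemble.states[0]).all()

    def test_rejects_unnormalised(self, small_ensemble):
        with pytest.raises(ContractError):
            resample(small_ensemble, np.full(6, 0.3))

    def test_reproducible_under_seed(self, small_config):
        a = resample(init_ensemble(small_config), np.full(6, 1 / 6))
        b = resample(init_ensemble(small_config), np.full(6, 1 / 6))
        assert np.array_equal(a.states, b.states)


class TestEnsembleAttention:
    def test_hand_instance(self):
        ens = make_ensemble([[1, 0, 1], [1, 1, 0]])
        np.testing.assert_allclose(
            ensemble_attention(ens).weights, [0.5, 0.25, 0.25]
        )
        np.testing.assert_allclose(
            ensemble_attention(ens).weights,
            ensemble_attention_naive([[1, 0, 1], [1, 1, 0]]),
        )

    def test_consensus(self):
        ens = make_ensemble(np.tile([0, 1, 0], (5, 1)))
        np.testing.assert_allclose(ensemble_attention(ens).weights, [0, 1, 0])

    def test_all_zero_fallback(self):
        ens = make_ensemble(np.zeros((4, 3)))
        np.testing.assert_allclose(ensemble_attention(ens).weights, 1 / 3)


class TestUpdateAttention:
    def test_large_tau_td_collapses_to_argmin_particle(self, vector_features):
        cfg = SPAConfig(K=4, N=5, tau_bu=10.0, tau_td=1e6, phi=0.0, seed=3)
        states = np.array(
            [[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 0, 0], [0, 1, 1, 1], [1, 1, 1, 1]]
        )
        ens = make_ensemble(states, seed=3)

        def value_fn(features, attention):
            # unique argmin at particle [1, 1, 0, 0]
            return 1.0 if attention.weights[0] == 0.5 and attention.weights[1] == 0.5 else 0.0

        obs = ReturnObservation(vector_features, 1.0)
        _, att = update_attention(ens, vector_features, obs, value_fn, cfg)
        np.testing.assert_allclose(att.weights, [0.5, 0.5, 0.0, 0.0])

    def test_buffered_observations_average_errors(self, vector_features):
        cfg = SPAConfig(K=4, N=4, tau_bu=0.0, tau_td=5.0, phi=0.0, seed=9, obs_buffer=2)
        states = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]])

        def value_fn(features, attention):
            return float(attention.weights[0])

        obs_a = ReturnObservation(vector_features, 1.0)
        obs_b = ReturnObservation(vector_features, 0.0)
        ens_pair = make_ensemble(states, seed=9)
        _, att_pair = update_attention(
            ens_pair, vector_features, [obs_a, obs_b], value_fn, cfg
        )
        # manual average of the two squared-error vectors
        deltas = np.mean(
            [
                particle_errors(make_ensemble(states), o, value_fn)
                for o in (obs_a, obs_b)
            ],
            axis=0,
        )
        weights = resampling_weights(deltas, cfg.tau_td)
        manual_ens = make_ensemble(states, seed=9)
        manual_ens.rng.random(4)  # the movement-step selection mask draw
        manual = resample(manual_ens, weights)
        np.testing.assert_allclose(att_pair.weights, ensemble_attention(manual).weights)

    def test_binary_states_after_full_update(self, vector_features):
        cfg = SPAConfig(K=4, N=20, phi=0.5, seed=11)
        ens = init_ensemble(cfg)
        obs = ReturnObservation(vector_features, 1.0)
        ens2, att = update_attention(
            ens, vector_features, obs, lambda f, a: 0.5, cfg
        )
        assert np.isin(ens2.states, (0, 1)).all()
        assert abs(att.weights.sum() - 1.0) < 1e-9
        assert (att.weights >= 0).all()


class TestApplyAttention:
    def test_channel_masking(self):
        f = FeatureTensor(
            np.array([[[1.0, 2.0], [3.0, 4.0]], [[5.0, 5.0], [5.0, 5.0]]])
        )
        out = apply_attention(f, AttentionVector(np.array([1.0, 0.0])))
        np.testing.assert_allclose(out[0], [[1, 2], [3, 4]])
        np.testing.assert_allclose(out[1], 0.0)

    def test_uniform_scales_every_channel(self, vector_features):
        out = apply_attention(vector_features, AttentionVector.uniform(4))
        np.testing.assert_allclose(out, vector_features.values / 4)

    def test_channel_sum_identity(self, rng):
        f = FeatureTensor(rng.random((5, 3, 2)))
        a = AttentionVector.from_unnormalized(rng.random(5))
        out = apply_attention(f, a)
        np.testing.assert_allclose(
            out.mean(axis=(1, 2)).sum(), float(a.weights @ f.channel_means)
        )

    def test_shape_mismatch_rejected(self, vector_features):
        with pytest.raises(ContractError):
            apply_attention(vector_features, AttentionVector.uniform(3))


class TestTypes:
    def test_attention_invariants_enforced(self):
        with pytest.raises(ContractError):
            AttentionVector(np.array([0.5, 0.6]))
        with pytest.raises(ContractError):
            AttentionVector(np.array([1.5, -0.5]))
        np.testing.assert_allclose(
            AttentionVector.from_unnormalized(np.zeros(4)).weights, 0.25
        )

    def test_feature_tensor_channel_means(self, rng):
        v = rng.random((3, 2, 2))
        f = FeatureTensor(v)
        np.testing.assert_allclose(f.channel_means, v.mean(axis=(1, 2)))
        with pytest.raises(ContractError):
            FeatureTensor(-v)

    def test_ensemble_rejects_nonbinary(self):
        with pytest.raises(ContractError):
            make_ensemble([[0, 2], [1, 0]])


class TestSerialization:
    def test_ensemble_roundtrip_preserves_stream(self, small_ensemble, tmp_path):
        path = tmp_path / "ens.npz"
        save_ensemble(small_ensemble, path)
        loaded = load_ensemble(path)
        assert np.array_equal(loaded.states, small_ensemble.states)
        # the restored generator continues the same stream
        assert loaded.rng.random() == small_ensemble.rng.random()

    def test_csv_outputs(self, small_ensemble, tmp_path):
        import pandas as pd

        ensemble_to_csv(small_ensemble, tmp_path / "ens.csv")
        df = pd.read_csv(tmp_path / "ens.csv")
        assert df.shape == (6, 5)
        attention_to_csv(ensemble_attention(small_ensemble), tmp_path / "att.csv")
        att = pd.read_csv(tmp_path / "att.csv")
        assert abs(att["weight"].sum() - 1.0) < 1e-9
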