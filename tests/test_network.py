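"""Forward computation: masked trunk, decoders, fusion, disease head."""

import numpy as np
import pytest

from microkpnn_mt.network import (
    ModelConfig,
    decode_disease,
    decode_metadata,
    forward,
    fuse_metadata,
    init_state,
    load_checkpoint,
    masked_linear,
    predict,
    save_checkpoint,
    softmax,
)


def make_state(rng, n_species=6, n_hidden=5, n_disease=3, n_body_site=2, **kw):
    config = ModelConfig(n_species=n_species, n_hidden=n_hidden, n_disease=n_disease,
                         n_body_site=n_body_site, **kw)
    mask = (rng.random((n_species, n_hidden)) < 0.6).astype(float)
    mask[:, 0] = 1.0  # keep every species and node connected
    mask[0, :] = 1.0
    return init_state(config, mask, rng)


class TestMaskedLinear:
    def test_zero_input_zero_bias(self, rng):
        state = make_state(rng)
        state.params["b"][:] = 0.0
        assert np.all(masked_linear(np.zeros(6), state) == 0.0)

    def test_scalar_closed_form(self, rng):
        config = ModelConfig(n_species=1, n_hidden=1, n_disease=2)
        state = init_state(config, np.ones((1, 1)), rng)
        state.params["W"][:] = 2.0
        state.params["b"][:] = 0.0
        assert masked_linear(np.array([3.0]), state)[0, 0] == 6.0

    def test_equals_dense_layer_on_masked_weights(self, rng):
        """Oracle: relu(x @ (W*M) + b) computed independently."""
        state = make_state(rng)
        X = rng.normal(size=(7, 6))
        dense = np.maximum(X @ (state.params["W"] * state.mask) + state.params["b"], 0.0)
        np.testing.assert_allclose(masked_linear(X, state), dense, atol=1e-12)

    def test_masked_entries_have_no_effect(self, rng):
        state = make_state(rng)
        X = rng.normal(size=(4, 6))
        before = masked_linear(X, state)
        tampered = state.copy()
        tampered.params["W"] = state.params["W"] + 100.0 * (1.0 - state.mask)
        np.testing.assert_array_equal(masked_linear(X, tampered), before)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            masked_linear(np.zeros(5), make_state(rng))


class TestDecodeMetadata:
    def test_zero_weights_give_uniform(self, rng):
        state = make_state(rng)
        state.params["A_age"][:] = 0.0
        state.params["c_age"][:] = 0.0
        P = decode_metadata(rng.normal(size=(3, 5)), state, "age")
        np.testing.assert_allclose(P, 1.0 / 6.0)

    def test_gender_zero_logit_is_half(self, rng):
        state = make_state(rng)
        state.params["A_gender"][:] = 0.0
        state.params["c_gender"][:] = 0.0
        P = decode_metadata(rng.normal(size=(2, 5)), state, "gender")
        np.testing.assert_allclose(P, 0.5)

    def test_hand_computed_softmax(self, rng):
        state = make_state(rng)
        state.params["A_bmi"][:] = 0.0
        state.params["A_bmi"][0, :] = [1.0, 2.0, 0.0, -1.0]
        state.params["c_bmi"][:] = 0.0
        h = np.zeros((1, 5))
        h[0, 0] = 1.0
        P = decode_metadata(h, state, "bmi")
        expect = np.exp([1.0, 2.0, 0.0, -1.0])
        np.testing.assert_allclose(P[0], expect / expect.sum(), atol=1e-12)

    def test_unknown_task(self, rng):
        with pytest.raises(ValueError):
            decode_metadata(np.zeros(5), make_state(rng), "height")

    def test_probabilities_normalized(self, rng):
        state = make_state(rng)
        h = rng.normal(size=(10, 5))
        for task in ("age", "bmi", "body_site"):
            np.testing.assert_allclose(decode_metadata(h, state, task).sum(axis=1), 1.0, atol=1e-9)


class TestFuseMetadata:
    def test_observed_becomes_one_hot(self, rng):
        state = make_state(rng)
        predicted = {t: decode_metadata(rng.normal(size=(1, 5)), state, t)
                     for t in state.config.metadata_tasks}
        fused = fuse_metadata(predicted, {"age": np.array([4])}, state.config)
        np.testing.assert_array_equal(fused["age"][0], [0, 0, 0, 0, 1, 0])

    def test_all_missing_passes_predictions_through(self, rng):
        state = make_state(rng)
        predicted = {t: decode_metadata(rng.normal(size=(2, 5)), state, t)
                     for t in state.config.metadata_tasks}
        fused = fuse_metadata(predicted, {}, state.config)
        for t in state.config.metadata_tasks:
            np.testing.assert_array_equal(fused[t], np.atleast_2d(predicted[t]))

    def test_per_sample_locality(self, rng):
        state = make_state(rng)
        h = rng.normal(size=(2, 5))
        predicted = {t: decode_metadata(h, state, t) for t in state.config.metadata_tasks}
        obs_mixed = {"age": np.array([2, -1])}
        fused = fuse_metadata(predicted, obs_mixed, state.config)
        # sample 1 (missing) is identical to the all-missing fusion
        fused_none = fuse_metadata(predicted, {}, state.config)
        np.testing.assert_array_equal(fused["age"][1], fused_none["age"][1])

    def test_gender_scalar_fusion(self, rng):
        state = make_state(rng)
        predicted = {t: decode_metadata(rng.normal(size=(1, 5)), state, t)
                     for t in state.config.metadata_tasks}
        fused = fuse_metadata(predicted, {"gender": np.array([1])}, state.config)
        assert fused["gender"][0, 0] == 1.0

    def test_invalid_index_rejected(self, rng):
        state = make_state(rng)
        predicted = {t: decode_metadata(rng.normal(size=(1, 5)), state, t)
                     for t in state.config.metadata_tasks}
        with pytest.raises(ValueError):
            fuse_metadata(predicted, {"age": np.array([6])}, state.config)


class TestDecodeDisease:
    def test_zero_weights_uniform(self, rng):
        state = make_state(rng, n_disease=26)
        state.params["B"][:] = 0.0
        state.params["d"][:] = 0.0
        bundle = forward(rng.normal(size=(3, 6)), state)
        np.testing.assert_allclose(bundle.disease_probs, 1.0 / 26.0)

    def test_depends_only_on_age_when_wired_so(self, rng):
        state = make_state(rng)
        state.params["B"][:] = 0.0
        H = state.config.n_hidden
        state.params["B"][H : H + 6, :] = rng.normal(size=(6, 3))  # only the age block
        h = rng.normal(size=(2, H))
        fused_a = {t: np.zeros((2, state.config.task_width(t))) for t in state.config.metadata_tasks}
        fused_a["age"] = np.array([[1, 0, 0, 0, 0, 0], [0, 0, 1, 0, 0, 0.0]])
        fused_b = {t: np.ones((2, state.config.task_width(t))) for t in state.config.metadata_tasks}
        fused_b["age"] = fused_a["age"]
        np.testing.assert_allclose(
            decode_disease(h, fused_a, state), decode_disease(np.zeros_like(h), fused_b, state),
            atol=1e-12,
        )

    def test_matches_dense_oracle(self, rng):
        state = make_state(rng)
        bundle = forward(rng.normal(size=(4, 6)), state)
        u = np.concatenate([bundle.h] + [bundle.fused[t] for t in state.config.metadata_tasks], axis=1)
        expect = softmax(u @ state.params["B"] + state.params["d"])
        np.testing.assert_allclose(bundle.disease_probs, expect, atol=1e-12)


class TestForward:
    def test_deterministic(self, rng):
        state = make_state(rng)
        X = rng.normal(size=(5, 6))
        obs = {"age": np.array([1, -1, 2, -1, 0])}
        a = forward(X, state, obs)
        b = forward(X, state, obs)
        np.testing.assert_array_equal(a.disease_probs, b.disease_probs)

    def test_observed_metadata_changes_disease_output(self, rng):
        state = make_state(rng)
        X = rng.normal(size=(1, 6))
        p0 = forward(X, state, {"age": np.array([0])}).disease_probs
        p1 = forward(X, state, {"age": np.array([5])}).disease_probs
        assert not np.allclose(p0, p1)

    def test_composition_equals_manual_pipeline(self, rng):
        state = make_state(rng)
        X = rng.normal(size=(3, 6))
        obs = {"gender": np.array([1, -1, 0])}
        bundle = forward(X, state, obs)
        h = masked_linear(X, state)
        probs = {t: decode_metadata(h, state, t) for t in state.config.metadata_tasks}
        full_obs = {t: np.full(3, -1) for t in state.config.metadata_tasks}
        full_obs.update(obs)
        fused = fuse_metadata(probs, full_obs, state.config)
        np.testing.assert_allclose(bundle.disease_probs, decode_disease(h, fused, state), atol=1e-12)

    def test_permutation_equivariance(self, rng):
        """Permuting species (and mask/weight rows) leaves outputs unchanged."""
        state = make_state(rng)
        X = rng.normal(size=(4, 6))
        perm = rng.permutation(6)
        permuted = state.copy()
        mask_p = np.array(state.mask)[perm]
        permuted.params["W"] = state.params["W"][perm]
        object.__setattr__(permuted, "mask", mask_p)
        np.testing.assert_allclose(
            forward(X, state).disease_probs, forward(X[:, perm], permuted).disease_probs, atol=1e-12
        )


class TestPredict:
    def test_tie_goes_to_lowest_index(self, rng):
        state = make_state(rng, n_disease=2)
        state.params["B"][:] = 0.0
        state.params["d"][:] = 0.0
        bundle = forward(rng.normal(size=(1, 6)), state)
        assert predict(bundle)["disease"][0] == 0

    def test_gender_threshold(self, rng):
        state = make_state(rng)
        bundle = forward(rng.normal(size=(3, 6)), state)
        bundle.task_probs["gender"] = np.array([[0.49], [0.5], [0.51]])
        np.testing.assert_array_equal(predict(bundle)["gender"], [0, 0, 1])

    def test_argmax_matches_scan(self, rng):
        state = make_state(rng)
        bundle = forward(rng.normal(size=(20, 6)), state)
        expect = [max(range(3), key=lambda j: row[j]) for row in bundle.disease_probs]
        np.testing.assert_array_equal(predict(bundle)["disease"], expect)


def test_checkpoint_round_trip(tmp_path, rng):
    state = make_state(rng)
    state.vocabs = {"disease": ["healthy", "d1", "d2"], "age": list("abcdef"),
                    "gender": ["female", "male"], "bmi": list("wxyz"), "body_site": ["g", "s"]}
    path = tmp_path / "model.ckpt"
    save_checkpoint(state, path)
    back = load_checkpoint(path)
    assert back.config == state.config
    for k, v in state.params.items():
        np.testing.assert_array_equal(back.params[k], v)
    np.testing.assert_array_equal(back.mask, state.mask)
    assert back.vocabs == state.vocabs
    X = rng.normal(size=(2, 6))
    np.testing.assert_array_equal(forward(X, state).disease_probs, forward(X, back).disease_probs)
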