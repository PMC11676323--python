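"""Multitask loss, analytic gradients, optimisation loop and CV orchestration."""

import numpy as np
import pytest

from microkpnn_mt.network import ModelConfig, forward, init_state
from microkpnn_mt.synthetic import SimSpec, simulate_dataset
from microkpnn_mt.training import (
    TrainConfig,
    compute_task_weights,
    cross_validate,
    evaluate_on,
    loss_and_grads,
    multitask_loss,
    train,
)


def small_state(rng, n_species=5, n_hidden=4, n_disease=3, **kw):
    config = ModelConfig(n_species=n_species, n_hidden=n_hidden, n_disease=n_disease,
                         n_body_site=2, **kw)
    mask = (rng.random((n_species, n_hidden)) < 0.7).astype(float)
    mask[:, 0] = 1.0
    mask[0, :] = 1.0
    return init_state(config, mask, rng)


class TestTaskWeights:
    def test_ratio(self):
        obs = {"age": np.array([0] * 50 + [-1] * 50), "gender": np.zeros(100, dtype=int)}
        w = compute_task_weights(obs)
        assert w["age"] == 2.0 and w["gender"] == 1.0

    def test_all_observed_gives_ones(self):
        obs = {t: np.zeros(10, dtype=int) for t in ("age", "bmi")}
        assert all(v == 1.0 for v in compute_task_weights(obs).values())

    def test_paper_scale_ratio(self):
        """34233 samples of which 2094 have BMI -> weight ~16.349."""
        obs = {"bmi": np.array([0] * 2094 + [-1] * (34233 - 2094))}
        assert compute_task_weights(obs)["bmi"] == pytest.approx(34233 / 2094, abs=1e-9)

    def test_empty_task_dropped_with_warning(self):
        obs = {"bmi": np.full(10, -1)}
        with pytest.warns(UserWarning, match="bmi"):
            w = compute_task_weights(obs)
        assert "bmi" not in w

    def test_monotone_in_missingness(self):
        n = 100
        w_half = compute_task_weights({"age": np.array([0] * 50 + [-1] * 50)})["age"]
        w_less = compute_task_weights({"age": np.array([0] * 25 + [-1] * 75)})["age"]
        assert w_less > w_half >= 1.0


class TestMultitaskLoss:
    def test_perfect_predictions_zero_loss(self, rng):
        state = small_state(rng)
        bundle = forward(rng.normal(size=(2, 5)), state, {"age": np.array([1, 2])})
        # overwrite with perfect one-hot outputs
        bundle.task_probs["age"] = np.eye(6)[[1, 2]].astype(float)
        bundle.disease_probs = np.eye(3)[[0, 1]].astype(float)
        y = np.array([0, 1])
        loss, _ = multitask_loss(bundle, y, {"age": 1.0})
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_all_missing_reduces_to_disease_ce(self, rng):
        state = small_state(rng)
        bundle = forward(rng.normal(size=(3, 5)), state)
        y = np.array([0, 2, 1])
        weights = {"age": 3.0, "gender": 1.5, "bmi": 2.0, "body_site": 1.0}
        loss, terms = multitask_loss(bundle, y, weights)
        expect = -np.log(bundle.disease_probs[np.arange(3), y]).sum()
        assert loss == pytest.approx(expect, abs=1e-9)
        assert all(terms[t] == 0.0 for t in weights)

    def test_hand_computed_two_sample_toy(self, rng):
        """n=2, age observed for one sample, w_age = 2: the loss is
        2*CE_age(sample 0) + CE_disease(s0) + CE_disease(s1), each term a
        plain negative log probability."""
        state = small_state(rng)
        bundle = forward(rng.normal(size=(2, 5)), state, {"age": np.array([3, -1])})
        p_age = np.array([[0.1, 0.1, 0.2, 0.4, 0.1, 0.1], [1 / 6.0] * 6])
        p_dis = np.array([[0.7, 0.2, 0.1], [0.3, 0.5, 0.2]])
        bundle.task_probs["age"] = p_age
        bundle.disease_probs = p_dis
        y = np.array([0, 2])
        weights = compute_task_weights(bundle.observed, tasks=["age"])
        assert weights["age"] == 2.0
        loss, _ = multitask_loss(bundle, y, weights)
        hand = 2.0 * -np.log(0.4) + -np.log(0.7) + -np.log(0.2)
        assert loss == pytest.approx(hand, abs=1e-9)

    def test_decomposition_sums(self, rng):
        state = small_state(rng)
        obs = {"age": np.array([1, -1, 0]), "gender": np.array([-1, 1, 0])}
        bundle = forward(rng.normal(size=(3, 5)), state, obs)
        weights = {"age": 1.5, "gender": 3.0}
        loss, terms = multitask_loss(bundle, np.array([0, 1, 2]), weights)
        assert loss == pytest.approx(sum(terms.values()), abs=1e-12)


class TestGradients:
    def test_matches_finite_differences(self, rng):
        """Analytic backprop equals a central-difference oracle on every parameter."""
        state = small_state(rng)
        X = rng.normal(size=(4, 5)) * 0.5
        y = np.array([0, 1, 2, 0])
        obs = {"age": np.array([1, -1, 3, -1]), "gender": np.array([-1, 1, -1, 0]),
               "bmi": np.full(4, -1), "body_site": np.array([0, 1, -1, -1])}
        weights = {"age": 2.0, "gender": 2.0, "bmi": 4.0, "body_site": 2.0}
        _, grads = loss_and_grads(state, X, y, obs, weights)
        eps = 1e-6
        for name, param in state.params.items():
            flat = param.ravel()
            for idx in np.random.default_rng(0).choice(flat.size, size=min(8, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = multitask_loss(forward(X, state, obs), y, weights)
                flat[idx] = orig - eps
                lm, _ = multitask_loss(forward(X, state, obs), y, weights)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].ravel()[idx]
                if name == "W" and state.mask.ravel()[idx] == 0:
                    assert ana == 0.0
                else:
                    assert ana == pytest.approx(num, abs=1e-4, rel=1e-4), f"{name}[{idx}]"

    def test_stop_gradient_flag_blocks_decoder_updates(self, rng):
        """With the stop-gradient flag on predicted metadata and no observed
        labels, the metadata decoders receive no gradient at all."""
        state = small_state(rng, gradient_through_predicted_metadata=False)
        X = rng.normal(size=(4, 5))
        obs = {t: np.full(4, -1) for t in state.config.metadata_tasks}
        _, grads = loss_and_grads(state, X, np.array([0, 1, 2, 0]), obs, {})
        for t in state.config.metadata_tasks:
            assert np.all(grads[f"A_{t}"] == 0.0) and np.all(grads[f"c_{t}"] == 0.0)

    def test_gradient_masked_positions_zero(self, rng):
        state = small_state(rng)
        X = rng.normal(size=(6, 5))
        _, grads = loss_and_grads(state, X, np.array([0, 1, 2, 0, 1, 2]),
                                  {t: np.full(6, -1) for t in state.config.metadata_tasks},
                                  {})
        assert np.all(grads["W"][state.mask == 0] == 0.0)


@pytest.fixture(scope="module")
def strong_sim():
    """Near-separable cohort: strong planted effects, little noise."""
    return simulate_dataset(SimSpec(n_samples=250, n_species=30, n_genera=10,
                                    n_metabolites=6, n_communities=4,
                                    effect_disease=4.0, noise_sigma=0.1,
                                    project_offset_sigma=0.0, seed=5))


class TestTrain:
    def test_zero_epochs_returns_initial_state(self, strong_sim):
        _, mask = strong_sim.schema_and_mask()
        enc = strong_sim.dataset.encode()
        state, log = train(enc, mask.values, train_config=TrainConfig(max_epochs=0, seed=0))
        assert log == []
        rng = np.random.default_rng(0)
        ref = init_state(state.config, np.asarray(mask.values, dtype=float), rng,
                         vocabs=enc.vocabs)
        np.testing.assert_array_equal(state.params["W"], ref.params["W"])

    def test_separable_signal_learned(self, strong_sim):
        _, mask = strong_sim.schema_and_mask()
        enc = strong_sim.dataset.encode()
        state, log = train(enc, mask.values,
                           train_config=TrainConfig(max_epochs=60, patience=8, seed=1))
        assert log[-1].train_loss < 0.8 * log[0].train_loss
        rep = evaluate_on(state, enc)["disease"]
        assert rep.macro_f1 >= 0.95

    def test_deterministic_given_seed(self, strong_sim):
        _, mask = strong_sim.schema_and_mask()
        enc = strong_sim.dataset.encode()
        tc = TrainConfig(max_epochs=5, seed=42)
        _, log1 = train(enc, mask.values, train_config=tc)
        _, log2 = train(enc, mask.values, train_config=tc)
        assert [e.train_loss for e in log1] == [e.train_loss for e in log2]
        assert [e.val_loss for e in log1] == [e.val_loss for e in log2]

    def test_mask_conserved_after_training(self, strong_sim):
        _, mask = strong_sim.schema_and_mask()
        enc = strong_sim.dataset.encode()
        state, _ = train(enc, mask.values, train_config=TrainConfig(max_epochs=10, seed=2))
        assert np.all(state.params["W"][np.asarray(mask.values) == 0] == 0.0)

    def test_early_stopping_returns_best_validation_state(self, strong_sim):
        _, mask = strong_sim.schema_and_mask()
        enc = strong_sim.dataset.encode()
        state, log = train(enc, mask.values,
                           train_config=TrainConfig(max_epochs=40, patience=5, seed=3))
        best_seen = min(e.val_loss for e in log)
        # recompute the returned state's validation monitor via one more pass
        from microkpnn_mt.training import _stratified_holdout, validation_monitor
        _, val_idx = _stratified_holdout(enc.y_disease, 0.1, 3)
        val_loss = validation_monitor(state, enc.take(val_idx))
        assert val_loss == pytest.approx(best_seen, rel=1e-9)


class TestCrossValidate:
    def test_folds_partition_and_aggregate(self, strong_sim):
        _, mask = strong_sim.schema_and_mask()
        result = cross_validate(strong_sim.dataset, mask.values, k=3, seed=0,
                                train_config=TrainConfig(max_epochs=15, seed=0))
        assert len(result.per_fold) == 3
        assert set(result.folds) == {0, 1, 2}
        agg = result.aggregate()
        f1_vals = [r["disease"].macro_f1 for r in result.per_fold]
        assert agg.loc["disease", ("macro_f1", "mean")] == pytest.approx(np.mean(f1_vals))
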