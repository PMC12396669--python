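"""Autoencoder: architecture, forward pass, loss, training, grid search."""

import numpy as np
import pytest

from atnorm.cohort import SyntheticConfig, generate_cohort
from atnorm.features import ModelInput, fit_normalizer, normalize, normalize_many
from atnorm.model import (
    AEArchitecture,
    ArchitectureError,
    DivergenceError,
    Hyperparameters,
    best_models_report,
    build_model,
    encode_latent,
    evaluate_loss,
    grid_search,
    reconstruct,
    reconstruct_many,
    split_controls,
    subject_mse,
    train,
)


class TestArchitecture:
    def test_parameter_count_is_792(self):
        model = build_model(seed=0)
        # independent oracle: sum of (in*out + out) over the weight layers
        widths = (20, 15, 10, 4, 8, 10, 13)
        expected = sum(a * b + b for a, b in zip(widths[:-1], widths[1:]))
        assert expected == 792
        assert model.parameter_count() == expected

    def test_nonstandard_widths_rejected_without_override(self):
        with pytest.raises(ArchitectureError):
            build_model(AEArchitecture((20, 5, 13)), seed=0)
        m = build_model(AEArchitecture((20, 5, 13)), seed=0, allow_nonstandard=True)
        assert m.parameter_count() == 20 * 5 + 5 + 5 * 13 + 13

    def test_same_seed_identical_init(self):
        a = build_model(seed=3)
        b = build_model(seed=3)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_zero_weight_model_maps_to_zero(self):
        m = build_model(seed=0)
        for w in m.weights:
            w[:] = 0.0
        out = reconstruct_many(m, np.random.default_rng(0).normal(size=(5, 20)))
        assert np.array_equal(out, np.zeros((5, 13)))


class TestForward:
    def test_reconstruct_is_deterministic(self):
        m = build_model(seed=1)
        x = ModelInput(values=np.linspace(0, 1, 20))
        a = reconstruct(m, x)
        b = reconstruct(m, x)
        assert np.array_equal(a.values, b.values)
        assert len(a.values) == 13

    def test_wrong_input_width_rejected(self):
        m = build_model(seed=1)
        with pytest.raises(ValueError):
            reconstruct_many(m, np.zeros((2, 19)))

    def test_latent_is_width_four(self):
        m = build_model(seed=1)
        z = encode_latent(m, ModelInput(values=np.linspace(0, 1, 20)))
        assert z.shape == (4,)

    def test_encode_then_decode_matches_reconstruct(self):
        m = build_model(seed=2)
        x = ModelInput(values=np.linspace(-0.2, 1.2, 20))
        z = encode_latent(m, x)
        a = z.copy()
        for i in range(3, 6):  # decoder layers after the bottleneck
            pre = a @ m.weights[i] + m.biases[i]
            a = pre if i == 5 else np.maximum(pre, 0.0)
        assert np.allclose(a, reconstruct(m, x).values)

    def test_outputs_finite_for_finite_inputs(self):
        m = build_model(seed=4)
        X = np.random.default_rng(0).normal(scale=50, size=(20, 20))
        assert np.isfinite(reconstruct_many(m, X)).all()


class TestSubjectMSE:
    def test_identity_is_zero(self):
        assert subject_mse(np.ones(13), np.ones(13)) == 0.0

    def test_small_generalized_example(self):
        assert subject_mse(np.array([0.0, 0.0]), np.array([1.0, 2.0])) == 2.5

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            y = rng.normal(size=13)
            y_hat = rng.normal(size=13)
            acc = 0.0
            for i in range(13):
                acc += (y[i] - y_hat[i]) ** 2
            assert abs(subject_mse(y_hat, y) - acc / 13) < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subject_mse(np.zeros(13), np.zeros(12))


class TestSplit:
    def test_default_split_sizes(self):
        records = list(range(110))
        tr, va, te = split_controls(records, seed=0)
        assert (len(tr), len(va), len(te)) == (80, 20, 10)

    def test_partition_properties(self):
        records = list(range(57))
        tr, va, te = split_controls(records, seed=1)
        union = set(tr) | set(va) | set(te)
        assert union == set(records)
        assert len(tr) + len(va) + len(te) == 57

    def test_deterministic_membership(self):
        records = list(range(30))
        assert split_controls(records, seed=5) == split_controls(records, seed=5)

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError):
            split_controls([1, 2], seed=0)


class TestTraining:
    @pytest.fixture(scope="class")
    def small_data(self):
        cfg = SyntheticConfig(n_controls=40, n_at=4, seed=8)
        records = generate_cohort(cfg)
        controls = [r for r in records if r.group == "control"]
        tr, va, te = split_controls(controls, seed=8)
        norm = fit_normalizer(tr)
        return normalize_many(tr, norm), normalize_many(va, norm)

    def test_training_improves_validation_loss(self, small_data):
        X_tr, X_va = small_data
        hp = Hyperparameters(epochs=150)
        m0 = build_model(seed=8, hyperparameters=hp)
        before = evaluate_loss(m0, X_va)
        fitted = train(m0, X_tr, X_va, hp, seed=8)
        after = evaluate_loss(fitted, X_va)
        assert after < before
        assert min(fitted.loss_history["val"]) <= fitted.loss_history["val"][0]

    def test_memorizes_four_subjects(self, small_data):
        X_tr, _ = small_data
        tiny = X_tr[:4]
        hp = Hyperparameters(epochs=3000, patience=3000, batch_size=4)
        fitted = train(build_model(seed=9, hyperparameters=hp), tiny, tiny, hp, seed=9)
        assert evaluate_loss(fitted, tiny) < 1e-3

    def test_same_seed_identical_history(self, small_data):
        X_tr, X_va = small_data
        hp = Hyperparameters(epochs=40)
        a = train(build_model(seed=3, hyperparameters=hp), X_tr, X_va, hp, seed=3)
        b = train(build_model(seed=3, hyperparameters=hp), X_tr, X_va, hp, seed=3)
        assert a.loss_history == b.loss_history
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_parameter_count_preserved_after_training(self, small_data):
        X_tr, X_va = small_data
        hp = Hyperparameters(epochs=20)
        fitted = train(build_model(seed=3, hyperparameters=hp), X_tr, X_va, hp, seed=3)
        assert fitted.parameter_count() == 792

    def test_divergence_raises(self, small_data):
        X_tr, X_va = small_data
        hp = Hyperparameters(
            optimizer_name="sgd", learning_rate=1e9, epochs=50, patience=50
        )
        with pytest.raises(DivergenceError):
            train(build_model(seed=3, hyperparameters=hp), X_tr, X_va, hp, seed=3)

    def test_median_loss_variant_trains(self, small_data):
        X_tr, X_va = small_data
        hp = Hyperparameters(loss="median", epochs=150)
        m0 = build_model(seed=5, hyperparameters=hp)
        fitted = train(m0, X_tr, X_va, hp, seed=5)
        assert evaluate_loss(fitted, X_va, "median") < evaluate_loss(m0, X_va, "median")

    def test_checkpoint_round_trip(self, small_data, tmp_path):
        X_tr, X_va = small_data
        hp = Hyperparameters(epochs=20)
        fitted = train(build_model(seed=3, hyperparameters=hp), X_tr, X_va, hp, seed=3)
        fitted.save(tmp_path / "ckpt")
        from atnorm.model import TrainedModel

        back = TrainedModel.load(tmp_path / "ckpt")
        X = np.random.default_rng(0).uniform(size=(6, 20))
        assert np.array_equal(reconstruct_many(fitted, X), reconstruct_many(back, X))


class TestGridSearch:
    @pytest.fixture(scope="class")
    def data(self):
        cfg = SyntheticConfig(n_controls=24, n_at=2, seed=12)
        controls = [r for r in generate_cohort(cfg) if r.group == "control"]
        norm = fit_normalizer(controls)
        return normalize_many(controls, norm)

    def test_singleton_grid(self, data):
        hp = Hyperparameters(epochs=15)
        ranked = grid_search(data, [hp], k=3, seed=0)
        assert ranked[0][0] == hp and len(ranked) == 1

    def test_ranking_matches_exhaustive_oracle(self, data):
        grid = [
            Hyperparameters(epochs=10, learning_rate=lr, batch_size=bs)
            for lr in (1e-3, 5e-3)
            for bs in (8, 16)
        ]
        ranked = grid_search(data, grid, k=3, seed=4)
        # independent re-evaluation: same fold construction, same sub-seeds
        rng = np.random.default_rng(np.random.SeedSequence([4, 41]))
        idx = rng.permutation(len(data))
        folds = np.array_split(idx, 3)
        oracle = []
        for gi, hp in enumerate(grid):
            losses = []
            for fi in range(3):
                val_idx = folds[fi]
                tr_idx = np.concatenate([folds[j] for j in range(3) if j != fi])
                m0 = build_model(seed=4 + 1000 * gi + fi, hyperparameters=hp)
                fitted = train(m0, data[tr_idx], data[val_idx], hp, seed=4 + 1000 * gi + fi)
                losses.append(evaluate_loss(fitted, data[val_idx], hp.loss))
            oracle.append((hp, float(np.mean(losses))))
        oracle.sort(key=lambda t: t[1])
        assert [h for h, _ in ranked] == [h for h, _ in oracle]
        assert np.allclose([l for _, l in ranked], [l for _, l in oracle])

    def test_best_models_report_capped_at_five(self, data):
        grid = [Hyperparameters(epochs=5, learning_rate=lr)
                for lr in np.geomspace(1e-4, 1e-2, 6)]
        ranked = grid_search(data, grid, k=2, seed=1)
        assert len(best_models_report(ranked)) == 5
        assert len(best_models_report(ranked[:2])) == 2
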