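"""Flattening contract, network shapes, training, and subject-wise splits."""

import numpy as np
import pytest

from gaitsim.nnpipe import (
    INPUT_SHAPE,
    N_INPUT,
    N_OUTPUT,
    TARGET_SHAPE,
    MLP,
    ModelConfig,
    NormalizedSample,
    build_model,
    flatten,
    make_splits,
    run_scenario,
    train,
    unflatten,
)


def _sample(rng, subject="S0", source="measured"):
    return NormalizedSample(
        subject_id=subject,
        inputs=rng.standard_normal(INPUT_SHAPE),
        targets=rng.standard_normal(TARGET_SHAPE),
        source=source,
    )


class TestFlatten:
    def test_lengths_match_contract(self, rng):
        x, y = flatten(_sample(rng))
        assert x.shape == (3030,)
        assert y.shape == (1818,)
        assert N_INPUT == 30 * 101 and N_OUTPUT == 18 * 101

    def test_round_trip_exact(self, rng):
        s = _sample(rng)
        x, y = flatten(s)
        xi, yi = unflatten(x, y)
        assert np.array_equal(xi, s.inputs)
        assert np.array_equal(yi, s.targets)

    def test_channel_major_ordering(self, rng):
        """First 101 entries of the flat vector are channel 0's time course."""
        s = _sample(rng)
        x, _ = flatten(s)
        assert np.array_equal(x[:101], s.inputs[0])

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="inputs"):
            NormalizedSample("S0", rng.standard_normal((29, 101)), rng.standard_normal(TARGET_SHAPE))
        with pytest.raises(ValueError, match="length 1818"):
            unflatten(target_vec=np.zeros(1800))


class TestBuildModel:
    def test_kinematic_full_scale_widths(self):
        model = build_model(ModelConfig(task="kinematic"))
        assert [w.shape for w in model.W] == [(3030, 4000), (4000, 6000), (6000, 1818)]

    def test_kinetic_full_scale_widths_and_dropout(self):
        cfg = ModelConfig(task="kinetic")
        model = build_model(cfg)
        assert [w.shape for w in model.W] == [(3030, 6000), (6000, 4000), (4000, 1818)]
        assert cfg.dropout == 0.40 and cfg.steps_per_phase == 15_000

    def test_scale_rule(self):
        cfg = ModelConfig(task="kinematic", scale=0.01)
        assert cfg.scaled_hidden == (40, 60)
        assert cfg.scaled_steps == 125

    def test_output_batch_shape(self, rng):
        cfg = ModelConfig(task="kinematic", scale=0.01)
        model = build_model(cfg)
        samples = [_sample(rng) for _ in range(3)]
        X = np.stack([flatten(s)[0] for s in samples])
        Y = np.stack([flatten(s)[1] for s in samples])
        model.fit_scalers(X, Y)
        assert model.predict(X).shape == (3, 1818)

    def test_seeded_determinism(self, rng):
        a = build_model(ModelConfig(scale=0.01), seed=7)
        b = build_model(ModelConfig(scale=0.01), seed=7)
        assert all(np.array_equal(wa, wb) for wa, wb in zip(a.W, b.W))


class TestTrain:
    def test_history_has_four_phases(self, rng):
        cfg = ModelConfig(task="kinematic", scale=0.002)
        model = build_model(cfg, seed=0)
        samples = [_sample(rng) for _ in range(4)]
        _, history = train(model, samples, cfg, seed=0)
        assert len(history) == 4
        assert [h["batch_size"] for h in history] == [16, 32, 32, 64]

    def test_constant_targets_loss_vanishes(self, rng):
        """Bias-only solution: zero-noise constant targets are fit quickly."""
        cfg = ModelConfig(task="kinematic", scale=0.004, lr=1e-3, dropout=0.0)
        model = build_model(cfg, seed=1)
        const = np.ones(TARGET_SHAPE) * 3.0
        samples = [
            NormalizedSample(f"S{i}", rng.standard_normal(INPUT_SHAPE), const)
            for i in range(4)
        ]
        model, history = train(model, samples, cfg, seed=1)
        X = np.stack([flatten(s)[0] for s in samples])
        pred = model.predict(X)
        assert np.max(np.abs(pred - 3.0)) < 0.15

    def test_linear_task_recovered(self, rng):
        """Targets a fixed linear map of inputs + small noise: held-out r > 0.95.

        Inputs live on a 10-dimensional latent manifold (as gait cycles do),
        so the map is identifiable from a few dozen samples.
        """
        basis_x = rng.standard_normal((10, N_INPUT))
        basis_y = rng.standard_normal((10, N_OUTPUT))

        def make(subject, n):
            out = []
            for _ in range(n):
                c = rng.standard_normal(10)
                x = c @ basis_x
                y = c @ basis_y + 0.01 * rng.standard_normal(N_OUTPUT)
                out.append(NormalizedSample(subject, *unflatten(x, y)))
            return out

        train_samples = make("train", 200)
        test_samples = make("test", 10)
        cfg = ModelConfig(task="kinematic", scale=0.02, lr=1e-3, dropout=0.0)
        model = build_model(cfg, seed=2)
        model, _ = train(model, train_samples, cfg, seed=2)
        X = np.stack([flatten(s)[0] for s in test_samples])
        Y = np.stack([flatten(s)[1] for s in test_samples])
        pred = model.predict(X)
        rs = [np.corrcoef(pred[i], Y[i])[0, 1] for i in range(len(test_samples))]
        assert np.mean(rs) > 0.95

    def test_empty_pool_rejected(self):
        cfg = ModelConfig(scale=0.002)
        with pytest.raises(ValueError, match="at least one"):
            train(build_model(cfg), [], cfg)


class TestSplits:
    def test_loocv_one_fold_per_subject(self):
        subjects = [f"S{i}" for i in range(23)]
        plan = make_splits(subjects, "loocv")
        assert len(plan.folds) == 23
        tested = set().union(*(f["test"] for f in plan.folds))
        assert tested == set(subjects)

    def test_no_partition_overlap(self):
        plan = make_splits([f"S{i}" for i in range(12)], "kfold", seed=3)
        for fold in plan.folds:
            assert not fold["train"] & fold["validation"]
            assert not fold["train"] & fold["test"]
            assert not fold["validation"] & fold["test"]

    def test_kfold_seeded_repeatable(self):
        subjects = [f"S{i}" for i in range(10)]
        a = make_splits(subjects, "kfold", seed=11)
        b = make_splits(subjects, "kfold", seed=11)
        assert a.folds == b.folds

    def test_loocv_has_no_validation_set(self):
        plan = make_splits(["A", "B", "C"], "loocv")
        assert all(f["validation"] == set() for f in plan.folds)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            make_splits(["A", "B"], "kfold")
        with pytest.raises(ValueError):
            make_splits(["A"], "loocv")


class TestScenarios:
    @pytest.fixture()
    def tagged_samples(self, rng):
        samples = []
        for subject in ("S0", "S1", "S2"):
            samples += [_sample(rng, subject, "measured") for _ in range(2)]
            samples += [_sample(rng, subject, "simulated") for _ in range(3)]
        return samples

    def test_pool_arithmetic(self, tagged_samples):
        """Combined pool = measured pool + simulated pool of training subjects."""
        plan = make_splits(["S0", "S1", "S2"], "loocv")
        fold = plan.folds[0]
        measured_pool = [
            s for s in tagged_samples
            if s.subject_id in fold["train"] and s.source == "measured"
        ]
        simulated_pool = [
            s for s in tagged_samples
            if s.subject_id in fold["train"] and s.source == "simulated"
        ]
        combined_pool = [s for s in tagged_samples if s.subject_id in fold["train"]]
        assert len(combined_pool) == len(measured_pool) + len(simulated_pool)

    def test_held_out_subject_never_trained_on(self, tagged_samples):
        cfg = ModelConfig(task="kinematic", scale=0.002)
        plan = make_splits(["S0", "S1", "S2"], "loocv")
        preds = run_scenario(tagged_samples, "combined", plan, cfg, seed=0)
        # every test subject predicted exactly its measured samples
        for subject in ("S0", "S1", "S2"):
            assert len(preds[subject]) == 2

    def test_unknown_scenario_rejected(self, tagged_samples):
        plan = make_splits(["S0", "S1", "S2"], "loocv")
        with pytest.raises(ValueError, match="scenario"):
            run_scenario(tagged_samples, "everything", plan, ModelConfig(scale=0.002))
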