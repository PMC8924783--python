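"""Network construction, training mechanics, ensembling, fine-tuning."""

import dataclasses

import numpy as np
import pytest

from bitewatch.cnn import (
    ModelConfigError,
    ModelSpec,
    SplitPlan,
    TrainConfig,
    TrainedEnsemble,
    build_model,
    finetune_personal,
    make_split_plan,
    plan_pools,
    score_window_set,
    train_member,
)
from bitewatch.synthetic import GeneratorConfig, generate_cohort
from bitewatch.transforms import TransformConfig

from conftest import toy_window_set

SMALL = ModelSpec(input_length=80, input_channels=3, modality="gyro")
FAST = TrainConfig(learning_rate=1e-3, epochs=2, batch_size=16, seed=0)
TF = TransformConfig(normalization="centering", scale_range=None, rotation=False)


class TestArchitecture:
    @pytest.mark.parametrize("length", [63, 80, 1200, 15000])
    def test_pool_plan_keeps_every_kernel_feasible(self, length):
        kernels = ModelSpec().kernel_sizes
        pools = plan_pools(length, kernels)
        L = length
        for k, p in zip(kernels, pools):
            assert L >= k
            L = (L - k + 1) // p
        assert L >= 1

    def test_input_too_short_names_block(self):
        with pytest.raises(ModelConfigError, match="block 1"):
            plan_pools(5, ModelSpec().kernel_sizes)
        with pytest.raises(ModelConfigError, match="block"):
            plan_pools(62, ModelSpec().kernel_sizes)

    def test_wrong_filter_count_rejected(self):
        spec = dataclasses.replace(SMALL, filters_per_block=(8, 16))
        with pytest.raises(ModelConfigError, match="filters"):
            build_model(spec)

    def test_modality_channel_consistency(self):
        with pytest.raises(ModelConfigError, match="modality"):
            ModelSpec(input_channels=6, modality="gyro").validate()

    def test_forward_emits_probability(self, rng):
        m = build_model(SMALL, seed=0)
        x = rng.normal(size=(4, 80, 3)).astype(np.float32)
        p = m.predict_proba(x)
        assert p.shape == (4,)
        assert ((p >= 0) & (p <= 1)).all()
        assert m.n_parameters > 0

    def test_same_seed_same_weights(self):
        w1 = build_model(SMALL, seed=7).get_weights()
        w2 = build_model(SMALL, seed=7).get_weights()
        assert all(np.array_equal(a, b) for a, b in zip(w1, w2))
        w3 = build_model(SMALL, seed=8).get_weights()
        assert any(not np.array_equal(a, b) for a, b in zip(w1, w3))

    def test_inference_is_pure(self, rng):
        m = build_model(SMALL, seed=0)
        x = rng.normal(size=(3, 80, 3)).astype(np.float32)
        np.testing.assert_array_equal(m.predict_proba(x), m.predict_proba(x))


class TestTraining:
    def test_smoke_training_returns_finite_loss(self):
        train = toy_window_set(20, 20, rows=80, seed=1)
        val = toy_window_set(8, 24, rows=80, seed=2)
        model = build_model(SMALL, seed=0)
        model, hist = train_member(model, train, val, FAST, TF,
                                   np.random.default_rng(0))
        assert np.isfinite(hist["train_loss"]).all()
        assert len(hist["train_loss"]) == FAST.epochs

    def test_training_learns_separable_task(self):
        train = toy_window_set(60, 60, rows=80, seed=3)
        val = toy_window_set(15, 45, rows=80, seed=4)
        cfg = dataclasses.replace(FAST, epochs=4, best_epoch_metric="auc")
        model = build_model(SMALL, seed=1)
        model, hist = train_member(model, train, val, cfg, TF, np.random.default_rng(1))
        assert max(hist["val_metric"]) > 0.8

    def test_best_epoch_restore_returns_argbest_snapshot(self):
        """Restored weights equal the snapshot from the best-validation epoch."""
        train = toy_window_set(30, 30, rows=80, seed=5)
        val = toy_window_set(10, 30, rows=80, seed=6)
        cfg = dataclasses.replace(FAST, epochs=4)
        model = build_model(SMALL, seed=2)
        model, hist = train_member(model, train, val, cfg, TF,
                                   np.random.default_rng(2), keep_snapshots=True)
        best = int(np.argmin(hist["val_metric"]))
        assert hist["best_epoch"] == best
        for got, want in zip(model.get_weights(), hist["snapshots"][best]):
            np.testing.assert_array_equal(got, want)

    def test_empty_sets_rejected(self):
        ws = toy_window_set(5, 5)
        with pytest.raises(ValueError, match="non-empty"):
            train_member(build_model(SMALL), ws.subset(np.array([], dtype=int)), ws, FAST, TF)


class TestEnsemble:
    def test_combined_score_is_member_mean(self):
        class Stub:
            def __init__(self, v):
                self.v = v

            def predict_proba(self, x, batch_size=256):
                return np.full(len(x), self.v)

        ens = TrainedEnsemble(members=[Stub(v) for v in (0.2, 0.4, 0.6, 0.8, 1.0)], transforms=TF)
        np.testing.assert_allclose(ens.score(np.zeros((3, 8, 3))), 0.6)

    def test_identical_members_equal_any_member(self, rng):
        m = build_model(SMALL, seed=0)
        ens = TrainedEnsemble(members=[m, m, m], transforms=TF)
        ws = toy_window_set(4, 4, rows=80)
        np.testing.assert_allclose(
            score_window_set(ens, ws, TF), score_window_set(m, ws, TF), atol=1e-12
        )

    def test_member_matrix_shape(self):
        m1, m2 = build_model(SMALL, 0), build_model(SMALL, 1)
        ws = toy_window_set(3, 3, rows=80)
        mat = score_window_set(TrainedEnsemble([m1, m2], TF), ws, TF, return_members=True)
        assert mat.shape == (2, 6)
        np.testing.assert_allclose(
            mat.mean(axis=0), score_window_set(TrainedEnsemble([m1, m2], TF), ws, TF)
        )


class TestSplits:
    @pytest.mark.parametrize("seed", range(6))
    def test_subject_hygiene(self, seed):
        pids = [f"P{i:02d}" for i in range(14)]
        plan = make_split_plan(pids, np.random.default_rng(seed))
        assert len(plan.test_ids) == 3
        assert len(plan.resamples) == 5
        for train_ids, val_ids in plan.resamples:
            assert len(val_ids) == 2
            assert not (set(train_ids) & set(val_ids))
            assert not (set(train_ids) | set(val_ids)) & set(plan.test_ids)
            assert set(train_ids) | set(val_ids) | set(plan.test_ids) == set(pids)

    def test_too_few_participants(self):
        with pytest.raises(ValueError, match="at least"):
            make_split_plan(["a", "b", "c"], np.random.default_rng(0))

    def test_overlapping_plan_rejected(self):
        plan = SplitPlan(test_ids=["a"], resamples=[(["a", "b"], ["c"])])
        with pytest.raises(ValueError, match="disjoint"):
            plan.validate()


@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = GeneratorConfig(sampling_rate_hz=1.0)
    return generate_cohort(1, 10, cfg, seed=3)


class TestFinetune:
    def _global(self):
        m = build_model(ModelSpec(input_length=300, input_channels=3, modality="gyro"), seed=0)
        return TrainedEnsemble(members=[m], transforms=TF)

    def test_day_split_60_20_20(self, tiny_cohort):
        days = tiny_cohort.days["P01"]
        ens = self._global()
        cfg = dataclasses.replace(FAST, finetune_epochs=0)
        _, partition = finetune_personal(ens, days, cfg)
        assert (len(partition["train"]), len(partition["val"]), len(partition["test"])) == (6, 2, 2)
        keys = {d.key() for v in partition.values() for d in v}
        assert len(keys) == 10

    def test_zero_epochs_identity(self, tiny_cohort):
        days = tiny_cohort.days["P01"]
        ens = self._global()
        cfg = dataclasses.replace(FAST, finetune_epochs=0)
        tuned, _ = finetune_personal(ens, days, cfg)
        assert tuned.members[0] is ens.members[0]

    def test_too_few_days_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match=">= 5 days"):
            finetune_personal(self._global(), tiny_cohort.days["P01"][:4], FAST)

    def test_finetuning_updates_weights(self, tiny_cohort):
        days = tiny_cohort.days["P01"]
        ens = self._global()
        cfg = dataclasses.replace(
            FAST, finetune_epochs=1, max_train_positives=20, max_train_negatives=40,
            max_val_windows=50,
        )
        tuned, _ = finetune_personal(ens, days, cfg, rng_state=np.random.default_rng(0))
        before = ens.members[0].get_weights()
        after = tuned.members[0].get_weights()
        assert any(not np.array_equal(a, b) for a, b in zip(before, after))
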