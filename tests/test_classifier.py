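"""Siamese classifier: fusion blocks, training, evaluation, cross-validation."""

import numpy as np
import pytest

from fibrotwin import nn
from fibrotwin.classifier import (ClassifierCase, FusionConfig,
                                  SiameseClassifier, TrainConfig,
                                  evaluate_roc_auc, kfold_crossvalidate,
                                  moab_fuse, outer_ops, train_classifier)

from tests_oracles import STACK_SHAPE, separable_cohort


FAST = TrainConfig(learning_rate=1e-3, epochs=50, batch_size=16,
                   patience=50, seed=0, backbone_width=4)


class TestOuterOps:
    def test_toy_outer_sum(self):
        u = nn.Tensor(np.array([[1.0, 2.0]]))
        v = nn.Tensor(np.array([[3.0, 4.0]]))
        s, p, d, q = outer_ops(u, v)
        np.testing.assert_allclose(s.data[0], [[4, 5], [5, 6]])
        np.testing.assert_allclose(p.data[0], [[3, 4], [6, 8]])
        np.testing.assert_allclose(d.data[0], [[-2, -3], [-1, -2]])

    def test_zero_latents(self):
        z = nn.Tensor(np.zeros((1, 3)))
        for op in outer_ops(z, z):
            np.testing.assert_allclose(op.data, 0.0)

    def test_difference_antisymmetry(self, rng):
        u = nn.Tensor(rng.standard_normal((2, 5)))
        v = nn.Tensor(rng.standard_normal((2, 5)))
        duv = outer_ops(u, v)[2].data
        dvu = outer_ops(v, u)[2].data
        np.testing.assert_allclose(duv, -np.swapaxes(dvu, 1, 2))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            outer_ops(nn.Tensor(np.zeros((1, 3))), nn.Tensor(np.zeros((1, 4))))
        with pytest.raises(ValueError):
            moab_fuse(np.zeros(3), np.zeros(4))

    def test_moab_stack_matches_module_ops(self, rng):
        u, v = rng.standard_normal(4), rng.standard_normal(4)
        stack = moab_fuse(u, v)
        ops = outer_ops(nn.Tensor(u[None]), nn.Tensor(v[None]))
        for k in range(4):
            np.testing.assert_allclose(stack[k], ops[k].data[0])


class TestFusionBlocks:
    @pytest.mark.parametrize("mode", ["concat", "moab", "foaa"])
    def test_output_width_is_30(self, mode, rng):
        model = SiameseClassifier(FusionConfig(mode=mode),
                                  TrainConfig(seed=0, backbone_width=4))
        model.eval()
        u = nn.Tensor(rng.standard_normal((3, 32)))
        v = nn.Tensor(rng.standard_normal((3, 32)))
        assert model.fusion(u, v).shape == (3, 30)

    def test_foaa_direction_sensitive(self, rng):
        model = SiameseClassifier(FusionConfig(mode="foaa"),
                                  TrainConfig(seed=1, backbone_width=4))
        model.eval()
        u = nn.Tensor(rng.standard_normal((1, 32)))
        v = nn.Tensor(rng.standard_normal((1, 32)))
        assert not np.allclose(model.fusion(u, v).data,
                               model.fusion(v, u).data)

    def test_foaa_zeroed_modality_deterministic(self, rng):
        model = SiameseClassifier(FusionConfig(mode="foaa"),
                                  TrainConfig(seed=2, backbone_width=4))
        model.eval()
        u = nn.Tensor(rng.standard_normal((1, 32)))
        z = nn.Tensor(np.zeros((1, 32)))
        a = model.fusion(u, z).data
        b = model.fusion(u, z).data
        np.testing.assert_array_equal(a, b)  # skip path keeps u's signal

    def test_fusion_swap_keeps_backbone_weights(self):
        """Ablation-comparison fairness: only the fusion block differs."""
        ms = {m: SiameseClassifier(FusionConfig(mode=m),
                                   TrainConfig(seed=7, backbone_width=4))
              for m in ("concat", "moab", "foaa")}
        ref = [p.data for p in ms["concat"].backbone.parameters()]
        for m in ("moab", "foaa"):
            got = [p.data for p in ms[m].backbone.parameters()]
            assert len(ref) == len(got)
            for a, b in zip(ref, got):
                np.testing.assert_array_equal(a, b)

    def test_probabilities_bounded(self, rng):
        model = SiameseClassifier(FusionConfig(mode="moab"),
                                  TrainConfig(seed=0, backbone_width=4))
        cases = separable_cohort(4, seed=0)
        probs = model.predict_proba(cases)
        assert probs.shape == (4, 4)
        assert np.all((probs >= 0) & (probs <= 1))


class _StubModel:
    def __init__(self, probs):
        self.probs = np.asarray(probs, float)

    def predict_proba(self, cases):
        return self.probs


class TestEvaluation:
    def test_perfect_and_inverted_predictions(self):
        cases = separable_cohort(20, seed=0)
        labels = np.stack([c.labels for c in cases])
        assert evaluate_roc_auc(_StubModel(labels), cases)["mean"] == 1.0
        assert evaluate_roc_auc(_StubModel(1 - labels), cases)["mean"] == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        cases = []
        for i in range(1000):
            labels = rng.integers(0, 2, 4).astype(float)
            cases.append(ClassifierCase(np.zeros(STACK_SHAPE),
                                        np.zeros(STACK_SHAPE), labels))
        out = evaluate_roc_auc(_StubModel(rng.uniform(0, 1, (1000, 4))), cases)
        assert out["mean"] == pytest.approx(0.5, abs=0.05)

    def test_single_class_output_excluded_with_warning(self):
        cases = separable_cohort(10, seed=0)
        for c in cases:
            c.labels = c.labels.copy()
            c.labels[3] = 1.0  # degenerate fourth output
        probs = np.random.default_rng(0).uniform(0, 1, (10, 4))
        with pytest.warns(UserWarning):
            out = evaluate_roc_auc(_StubModel(probs), cases)
        assert np.isnan(out["per_strategy"][3])
        assert not np.isnan(out["mean"])


class TestTraining:
    def test_separable_cohort_reaches_high_auc(self):
        train = separable_cohort(60, seed=0)
        val = separable_cohort(40, seed=100)
        model, history = train_classifier(train, FusionConfig(mode="concat"),
                                          FAST, validation_cases=val)
        assert evaluate_roc_auc(model, val)["mean"] >= 0.95
        assert history["loss"][-1] < history["loss"][0]

    def test_label_shuffled_cohort_is_chance_level(self):
        train = separable_cohort(60, seed=0, shuffle_labels=True)
        val = separable_cohort(40, seed=100, shuffle_labels=True)
        test = separable_cohort(60, seed=200, shuffle_labels=True)
        model, _ = train_classifier(train, FusionConfig(mode="concat"),
                                    FAST, validation_cases=val)
        # fresh held-out data (the early-stopped val set is selection-biased)
        assert 0.4 <= evaluate_roc_auc(model, test)["mean"] <= 0.6

    def test_seeded_training_reproducible(self):
        train = separable_cohort(20, seed=0)
        cfg = TrainConfig(learning_rate=1e-3, epochs=3, seed=4,
                          backbone_width=4)
        _, h1 = train_classifier(train, FusionConfig(mode="moab"), cfg)
        _, h2 = train_classifier(train, FusionConfig(mode="moab"), cfg)
        assert h1["loss"] == h2["loss"]

    def test_all_single_class_rejected(self):
        cases = separable_cohort(10, seed=0)
        for c in cases:
            c.labels = np.ones(4)
        with pytest.raises(ValueError):
            train_classifier(cases, FusionConfig(mode="concat"), FAST)


class TestCrossValidation:
    def test_folds_partition_and_pool_disjointness(self):
        cases = separable_cohort(40, seed=3)
        cfg = TrainConfig(learning_rate=1e-3, epochs=2, seed=0,
                          backbone_width=4)
        out = kfold_crossvalidate(cases, k=4, train_config=cfg, seed=1)
        assign = np.array(out["fold_assignment"])
        assert assign.shape == (40,)
        assert set(assign) == {0, 1, 2, 3}
        # no fibrosis-map id appears in two folds
        for mid in {c.la_map_id for c in cases} | {c.ra_map_id for c in cases}:
            folds = {assign[i] for i, c in enumerate(cases)
                     if mid in (c.la_map_id, c.ra_map_id)}
            assert len(folds) == 1
        assert len(out["fold_aucs"]) == 4
        assert all(0 <= a <= 1 for a in out["fold_aucs"] if not np.isnan(a))

    def test_deterministic_assignment(self):
        cases = separable_cohort(30, seed=3)
        cfg = TrainConfig(learning_rate=1e-3, epochs=1, seed=0,
                          backbone_width=4)
        a = kfold_crossvalidate(cases, k=3, train_config=cfg, seed=5)
        b = kfold_crossvalidate(cases, k=3, train_config=cfg, seed=5)
        assert a["fold_assignment"] == b["fold_assignment"]

    def test_k_larger_than_cohort_rejected(self):
        with pytest.raises(ValueError):
            kfold_crossvalidate(separable_cohort(3, seed=0), k=5)
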