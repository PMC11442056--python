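import numpy as np
import pytest

from embryo3d.classifier import (ClassifierData, StratificationError,
                                 TrainConfig, assert_no_leakage,
                                 build_fusion_model, hyperparameter_grid,
                                 make_cv_plan, predict, predict_scores,
                                 reference_architecture, train_classifier)

TINY_ARCH = dict(reference_architecture())
TINY_ARCH.update(stem_channels=2, trunk_channels=4, feature_dim=4,
                 head_hidden=8, input_pool=[2, 4, 4])


def tiny_config(**kw):
    base = dict(batch_size=8, learning_rate=3e-3, l2_lambda=0.002,
                augment_times=1, max_epochs=2, early_stopping_patience=5,
                seed=0)
    base.update(kw)
    return TrainConfig(**base)


def tiny_data(n=24, d=3, px=24, seed=0, prefix="E"):
    rng = np.random.default_rng(seed)
    q = rng.uniform(size=n)
    vols = rng.uniform(0, 0.3, size=(n, d, px, px)).astype(np.float32)
    vols += q[:, None, None, None] * 0.5
    cee = rng.uniform(0.2, 0.8, size=(n, 9))
    labels = (q + 0.3 * rng.normal(size=n) > 0.5).astype(int)
    if n >= 2:  # force both classes
        labels[0], labels[1] = 0, 1
    ids = np.array([f"{prefix}{i}" for i in range(n)])
    return ClassifierData(vols, cee, labels, ids)


class TestFusionModel:
    def test_softmax_pair_sums_to_one(self):
        model = build_fusion_model(tiny_config(), arch=TINY_ARCH)
        data = tiny_data(4)
        proba = model.predict_proba(data.volumes.astype(float)[:, None], data.cee)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(proba > 0)

    def test_zero_volume_still_valid(self):
        model = build_fusion_model(tiny_config(), arch=TINY_ARCH)
        vol = np.zeros((3, 24, 24))
        score = predict(model, vol, np.full(9, 0.5))
        assert 0.0 <= score <= 1.0

    def test_identical_inputs_identical_outputs(self):
        model = build_fusion_model(tiny_config(), arch=TINY_ARCH)
        data = tiny_data(2)
        s1 = predict(model, data.volumes[0].astype(float), data.cee[0])
        s2 = predict(model, data.volumes[0].astype(float), data.cee[0])
        assert s1 == s2

    def test_invalid_variant(self):
        with pytest.raises(ValueError, match="variant"):
            build_fusion_model(tiny_config(), variant="hologram")

    def test_score_is_implantation_class_probability(self):
        model = build_fusion_model(tiny_config(), arch=TINY_ARCH)
        # zero the final layer: symmetric logits -> score exactly 0.5
        model.lin4.w.value[...] = 0.0
        model.lin4.b.value[...] = 0.0
        data = tiny_data(1)
        score = predict(model, data.volumes[0].astype(float), data.cee[0])
        assert score == pytest.approx(0.5)

    def test_single_image_variant_shape_contract(self):
        model = build_fusion_model(tiny_config(), variant="single_image",
                                   arch=TINY_ARCH)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 1, 3, 24, 24)), np.zeros((1, 9)))
        out = model.forward(np.zeros((1, 1, 1, 24, 24)), np.full((1, 9), 0.5))
        assert out.shape == (1, 2)

    def test_reference_architecture_layer_budget(self):
        arch = reference_architecture()
        assert arch["total_layers"] == 36
        counted = (arch["convolutional"] + arch["batch_normalization"]
                   + arch["catenate"] + arch["elementwise"] + arch["linear"]
                   + arch["rectified_linear"] + arch["threading"])
        assert counted == 36


class TestCVPlan:
    def test_reference_cohort_sizes(self):
        rng = np.random.default_rng(0)
        labels = np.zeros(977, int)
        labels[:458] = 1
        rng.shuffle(labels)
        plan = make_cv_plan(977, labels, seed=1)
        assert len(plan.test_idx) in (195, 196)
        rest = 977 - len(plan.test_idx)
        assert rest in (781, 782)
        for tr, va in plan.inner_folds:
            assert len(tr) + len(va) == rest

    def test_minimal_cohort(self):
        labels = np.tile([0, 1], 13)[:25]  # 25 embryos
        plan = make_cv_plan(25, labels, seed=0)
        assert len(plan.test_idx) == 5
        sizes = sorted(len(va) for _, va in plan.inner_folds)
        assert sizes == [4, 4, 4, 4, 4]

    def test_deterministic(self):
        labels = np.tile([0, 1], 30)
        p1 = make_cv_plan(60, labels, seed=5)
        p2 = make_cv_plan(60, labels, seed=5)
        np.testing.assert_array_equal(p1.test_idx, p2.test_idx)
        for (a, b), (c, d) in zip(p1.inner_folds, p2.inner_folds):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_partition_properties(self):
        labels = np.tile([0, 1], 40)
        plan = make_cv_plan(80, labels, seed=2)
        plan.validate()
        test = set(plan.test_idx.tolist())
        for tr, va in plan.inner_folds:
            assert not (set(tr) | set(va)) & test
        all_val = np.sort(np.concatenate([va for _, va in plan.inner_folds]))
        rest = np.sort(np.setdiff1d(np.arange(80), plan.test_idx))
        np.testing.assert_array_equal(all_val, rest)

    def test_stratification_error(self):
        labels = np.zeros(30, int)
        labels[:3] = 1  # minority class smaller than k
        with pytest.raises(StratificationError):
            make_cv_plan(30, labels, seed=0)

    def test_too_few_embryos(self):
        with pytest.raises(ValueError):
            make_cv_plan(20, np.tile([0, 1], 10), seed=0)


class TestTraining:
    def test_leakage_assertion(self):
        train = tiny_data(12, prefix="A")
        val = tiny_data(12, prefix="A")  # same ids
        with pytest.raises(RuntimeError, match="leakage"):
            train_classifier(train, val, tiny_config(), arch=TINY_ARCH)

    def test_assert_no_leakage_passes_on_disjoint(self):
        assert_no_leakage(["A1", "A2"], ["B1"], ["C1"])
        with pytest.raises(RuntimeError):
            assert_no_leakage(["A1"], ["A1"])

    def test_l2_changes_final_weights(self):
        train, val = tiny_data(16, prefix="A"), tiny_data(8, seed=9, prefix="B")
        m0 = train_classifier(train, val, tiny_config(l2_lambda=0.0),
                              arch=TINY_ARCH)
        m1 = train_classifier(train, val, tiny_config(l2_lambda=0.02),
                              arch=TINY_ARCH)
        diffs = [np.abs(a.value - b.value).max()
                 for a, b in zip(m0.params(), m1.params())]
        assert max(diffs) > 0

    def test_deterministic_given_seed(self):
        train, val = tiny_data(16, prefix="A"), tiny_data(8, seed=9, prefix="B")
        m1 = train_classifier(train, val, tiny_config(seed=4), arch=TINY_ARCH)
        m2 = train_classifier(train, val, tiny_config(seed=4), arch=TINY_ARCH)
        np.testing.assert_array_equal(predict_scores(m1, val),
                                      predict_scores(m2, val))

    def test_history_recorded(self):
        train, val = tiny_data(16, prefix="A"), tiny_data(8, seed=9, prefix="B")
        model = train_classifier(train, val, tiny_config(max_epochs=3),
                                 arch=TINY_ARCH)
        assert model.history["epochs_run"] <= 3
        assert len(model.history["val_loss"]) == model.history["epochs_run"]
        assert model.history["optimizer"] == "adam"

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(augment_times=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1.0)


class TestHyperparameterGrid:
    def test_grid_shape_and_columns(self):
        train = tiny_data(16, prefix="A")
        val = tiny_data(8, seed=9, prefix="B")
        test = tiny_data(8, seed=10, prefix="C")
        table = hyperparameter_grid(train, val, test, tiny_config(),
                                    l2_values=[0.0, 0.02],
                                    augment_values=[1, 2], seeds=[0, 1],
                                    arch=TINY_ARCH)
        assert len(table) == 8
        assert set(table.columns) == {"l2", "augment", "seed", "auc"}
        assert table["auc"].between(0, 1).all()

    def test_null_grid_identical_cells(self):
        # degenerate grid whose cells share one config: AUCs must coincide
        train = tiny_data(16, prefix="A")
        val = tiny_data(8, seed=9, prefix="B")
        test = tiny_data(8, seed=10, prefix="C")
        table = hyperparameter_grid(train, val, test, tiny_config(),
                                    l2_values=[0.01, 0.01],
                                    augment_values=[1, 1], seeds=[3],
                                    arch=TINY_ARCH)
        assert table["auc"].nunique() == 1

    def test_augmentation_not_inferior(self):
        # rotation-invariant signal: augmented training must not lose more
        # than 0.05 validation AUC against the unaugmented run
        from embryo3d.evaluation import roc_auc

        train = tiny_data(24, d=3, px=24, seed=5, prefix="A")
        val = tiny_data(16, d=3, px=24, seed=6, prefix="B")
        aucs = {}
        for times in (1, 4):
            aug = train.augmented(times, seed=1)
            model = train_classifier(aug, val, tiny_config(max_epochs=4,
                                                           augment_times=times),
                                     arch=TINY_ARCH)
            aucs[times] = roc_auc(predict_scores(model, val), val.labels).auc
        assert aucs[4] >= aucs[1] - 0.05

    def test_needs_two_levels(self):
        train = tiny_data(16, prefix="A")
        val = tiny_data(8, seed=9, prefix="B")
        test = tiny_data(8, seed=10, prefix="C")
        with pytest.raises(ValueError):
            hyperparameter_grid(train, val, test, tiny_config(),
                                l2_values=[0.0], augment_values=[1, 2],
                                seeds=[0], arch=TINY_ARCH)
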