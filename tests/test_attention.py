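import dataclasses

import numpy as np
import pandas as pd
import pytest

from attnomics.containers import OmicsMatrix
from attnomics.attention import (
    AttentionConfig,
    TransformerEncoderNet,
    attention_importance,
    cross_validate,
    default_config,
    dual_filter,
    fold_fit_transform,
    select_top_fraction,
    train_encoder,
)

from conftest import toy_matrix


class TestDefaultConfig:
    def test_metabolome_settings(self):
        cfg = default_config("metabolome")
        assert cfg.n_components == 10 and cfg.n_heads == 2
        assert cfg.learning_rate == 5e-4 and cfg.patience == 8

    def test_transcriptome_settings(self):
        cfg = default_config("transcriptome")
        assert cfg.n_components == 30 and cfg.n_heads == 6
        assert cfg.learning_rate == 1e-4 and cfg.patience == 10

    def test_shared_regularization(self):
        for mod in ("metabolome", "transcriptome"):
            cfg = default_config(mod)
            assert cfg.n_layers == 3 and cfg.dropout == 0.5
            assert cfg.weight_decay == 0.1 and cfg.n_folds == 5

    def test_unknown_modality_and_bad_config(self):
        with pytest.raises(ValueError):
            default_config("proteome")
        with pytest.raises(ValueError):
            AttentionConfig(embed_dim=25, n_heads=2)


class TestFoldFitTransform:
    def test_test_equals_train_gives_identical_scores(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 12))
        str_, ste_, L, _ = fold_fit_transform(X, X, 5)
        np.testing.assert_allclose(str_, ste_, atol=1e-10)

    def test_loadings_orthonormal_and_variance_monotone(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 15)) * rng.uniform(0.5, 3, 15)
        str_, _, L, _ = fold_fit_transform(X, X, 6)
        np.testing.assert_allclose(L.T @ L, np.eye(6), atol=1e-8)
        var = str_.var(axis=0)
        assert (np.diff(var) <= 1e-10).all()

    def test_full_rank_roundtrip_recovers_standardized_matrix(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 8))
        str_, _, L, sc = fold_fit_transform(X, X, 8)
        Z = (X - sc["mean"]) / sc["sd"]
        np.testing.assert_allclose(str_ @ L.T, Z - Z.mean(axis=0), atol=1e-6)

    def test_too_many_components_rejected(self):
        X = np.random.default_rng(3).standard_normal((10, 4))
        with pytest.raises(ValueError):
            fold_fit_transform(X, X, 10)


class TestEncoderTraining:
    def small_cfg(self, **kw):
        base = dict(n_components=4, n_layers=2, n_heads=2, embed_dim=8,
                    dropout=0.0, weight_decay=0.0, batch_size=8, seed=3)
        base.update(kw)
        return AttentionConfig(**base)

    def test_backward_matches_numerical_gradients(self):
        cfg = self.small_cfg()
        net = TransformerEncoderNet(n_tokens=4, config=cfg)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5, 4))
        y = rng.integers(0, 2, 5).astype(float)
        _, cache = net.forward(X)
        grads = net.backward(y, cache)

        def loss():
            p, _ = net.forward(X)
            return net.bce_loss(p, y)

        eps = 1e-6
        for k in net.params:
            flat = net.params[k].ravel()
            g = grads[k].ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[i]) < 1e-6 + 1e-4 * abs(num), k

    def test_seeded_determinism_of_weights_and_history(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 4))
        y = (X[:, 0] > 0).astype(float)
        cfg = dataclasses.replace(default_config("metabolome", seed=5), n_components=4)
        m1, h1 = train_encoder(X, y, cfg)
        m2, h2 = train_encoder(X, y, cfg)
        assert h1 == h2
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_separable_data_reaches_high_training_accuracy(self):
        rng = np.random.default_rng(5)
        n = 80
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        X = rng.standard_normal((n, 4))
        X[:, 0] += 3 * y
        X[:, 1] -= 2 * y
        cfg = dataclasses.replace(default_config("metabolome", seed=6), n_components=4)
        model, _ = train_encoder(X, y, cfg)
        acc = ((model.predict_proba(X) >= 0.5) == y).mean()
        assert acc >= 0.95

    def test_permuted_labels_stop_early_near_ln2(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((60, 4))
        y = rng.permutation(np.r_[np.zeros(30), np.ones(30)])
        cfg = dataclasses.replace(default_config("metabolome", seed=7), n_components=4)
        model, hist = train_encoder(X, y, cfg)
        assert hist["stopped_epoch"] < cfg.max_epochs
        assert abs(min(hist["val_loss"]) - np.log(2)) < 0.1

    def test_non_binary_labels_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(ValueError):
            train_encoder(X, np.arange(10.0), self.small_cfg())


class TestAttentionImportance:
    def trained_model(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((50, 5))
        y = (X[:, 1] > 0).astype(float)
        cfg = AttentionConfig(n_components=5, n_layers=2, n_heads=2, embed_dim=8,
                              dropout=0.2, weight_decay=0.01, batch_size=8,
                              max_epochs=40, seed=9)
        model, _ = train_encoder(X, y, cfg)
        return model, X

    def test_attention_rows_are_distributions(self):
        model, X = self.trained_model()
        for P in model.attention_matrices(X):
            np.testing.assert_allclose(P.sum(axis=-1), 1.0, atol=1e-6)
            assert (P >= 0).all()

    def test_component_importance_sums_to_one(self):
        model, X = self.trained_model()
        imp = attention_importance(model, X)
        np.testing.assert_allclose(imp["component_importance"].sum(), 1.0, atol=1e-10)

    def test_uniform_attention_gives_uniform_importance(self):
        model, X = self.trained_model()
        # zeroing the query/key maps makes every softmax row exactly uniform
        for l in range(model.L):
            model.params[f"Wq{l}"][:] = 0.0
            model.params[f"bq{l}"][:] = 0.0
        imp = attention_importance(model, X)
        np.testing.assert_allclose(imp["component_importance"], 1 / 5, atol=1e-12)

    def test_dominant_feature_through_dominant_component_ranks_first(self):
        model, X = self.trained_model()
        # constructed fixture: feature 0 dominates PC1, PC1 dominates attention
        loadings = np.full((30, 5), 0.05)
        loadings[0, 0] = 0.95
        for l in range(model.L):
            model.params[f"Wq{l}"][:] = 0.0
            model.params[f"bq{l}"][:] = 0.0
        imp = attention_importance(model, X, loadings)
        fi = imp["feature_importance"]
        assert fi.argmax() == 0

    def test_sign_flip_invariance(self):
        model, X = self.trained_model()
        rng = np.random.default_rng(10)
        loadings = rng.standard_normal((20, 5))
        flip = loadings * np.array([1, -1, 1, -1, 1])
        a = attention_importance(model, X, loadings)["feature_importance"]
        b = attention_importance(model, X, flip)["feature_importance"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_untrained_model_rejected(self):
        net = TransformerEncoderNet(4, AttentionConfig(n_components=4, embed_dim=8,
                                                       n_heads=2, seed=0))
        with pytest.raises(ValueError):
            attention_importance(net, np.zeros((3, 4)))


class TestSelection:
    def test_exact_count(self):
        imp = pd.Series(np.random.default_rng(0).random(100),
                        index=[f"f{j:03d}" for j in range(100)])
        assert len(select_top_fraction(imp, 0.2)) == 20

    def test_all_equal_uses_lexicographic_ties(self):
        imp = pd.Series(1.0, index=[f"f{j:02d}" for j in range(10)])
        assert select_top_fraction(imp, 0.3) == ["f00", "f01", "f02"]

    def test_rule_application(self):
        imp = pd.Series([5, 4, 3, 2, 1.0], index=["f1", "f2", "f3", "f4", "f5"])
        assert select_top_fraction(imp, 0.4) == ["f1", "f2"]

    def test_dual_filter_set_algebra(self):
        assert dual_filter({"a", "b"}, {"a", "b"}) == {"a", "b"}
        assert dual_filter({"a", "b", "c"}, {"b", "c", "d"}) == {"b", "c"}
        assert dual_filter({"a"}, {"b"}) == set()
        with pytest.raises(ValueError):
            dual_filter({"a"}, {"z"}, universe={"a", "b"})


class TestCrossValidate:
    def test_stratification_and_metrics_shape(self, metabolome_planted):
        from attnomics.preprocess import preprocess_metabolome
        m, _ = metabolome_planted
        proc, _ = preprocess_metabolome(m)
        cfg = dataclasses.replace(default_config("metabolome", seed=1),
                                  n_components=6, max_epochs=30)
        report = cross_validate(proc, config=cfg)
        assert list(report.fold_metrics.columns) == [
            "auc", "accuracy", "precision", "recall", "f1"]
        assert len(report.fold_metrics) == 5
        assert len(report.selected) == int(np.ceil(0.2 * proc.n_features))
        np.testing.assert_allclose(
            [c.sum() for c in report.component_importance], 1.0, atol=1e-10)

    def test_seeded_report_determinism(self, metabolome_planted):
        from attnomics.preprocess import preprocess_metabolome
        m, _ = metabolome_planted
        proc, _ = preprocess_metabolome(m)
        cfg = dataclasses.replace(default_config("metabolome", seed=2),
                                  n_components=5, max_epochs=15)
        r1 = cross_validate(proc, config=cfg)
        r2 = cross_validate(proc, config=cfg)
        pd.testing.assert_series_equal(r1.feature_importance, r2.feature_importance)
        pd.testing.assert_frame_equal(r1.fold_metrics, r2.fold_metrics)
        assert r1.selected == r2.selected

    def test_strong_two_feature_signal_yields_high_cv_auc(self):
        rng = np.random.default_rng(30)
        n = 50
        y = np.r_[np.zeros(n), np.ones(n)]
        vals = rng.standard_normal((2 * n, 40))
        vals[:, 0] += 3.0 * y
        vals[:, 1] -= 3.0 * y
        m = toy_matrix(vals, groups=np.where(y == 1, "RA_ane", "RA"))
        cfg = dataclasses.replace(default_config("metabolome", seed=3), n_components=8)
        report = cross_validate(m, config=cfg)
        assert report.fold_metrics["auc"].mean() >= 0.85

    def test_permuted_labels_cv_auc_near_half(self, metabolome_planted):
        from attnomics.preprocess import preprocess_metabolome
        m, _ = metabolome_planted
        proc, _ = preprocess_metabolome(m)
        rng = np.random.default_rng(13)
        perm = pd.Series(rng.permutation(proc.group_labels.to_numpy()),
                         index=proc.values.index)
        mm = OmicsMatrix(values=proc.values, modality="metabolome", group_labels=perm)
        cfg = dataclasses.replace(default_config("metabolome", seed=4), n_components=6)
        aucs = [cross_validate(mm, config=dataclasses.replace(cfg, seed=40 + i)
                               ).fold_metrics["auc"].mean() for i in range(3)]
        assert 0.3 <= np.mean(aucs) <= 0.7
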