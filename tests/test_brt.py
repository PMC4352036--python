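"""Boosted-tree fitting, tuning, pruning, influence, partial dependence."""

import numpy as np
import pandas as pd
import pytest

from sdmtransfer import brt


def _frame(X: dict, labels, weight=None):
    df = pd.DataFrame(X)
    df["label"] = np.asarray(labels, dtype=int)
    df["weight"] = 1.0 if weight is None else weight
    return df


def _logistic_labels(rng, z):
    return (rng.uniform(0, 1, len(z)) < 1 / (1 + np.exp(-z))).astype(int)


FAST = dict(tree_complexity=2, learning_rate=0.1, cv_folds=3,
            max_trees=100, tree_step=25, seed=0)


class TestFitBRT:
    def test_perfectly_separable(self, rng):
        x = rng.integers(0, 2, 400).astype(float)
        df = _frame({"x": x}, x)
        model = brt.fit_brt(df, brt.BRTConfig(**FAST), predictors=["x"])
        assert model.cv_auc >= 0.99

    def test_single_class_error(self, rng):
        df = _frame({"x": rng.normal(size=50)}, np.ones(50))
        with pytest.raises(ValueError):
            brt.fit_brt(df, brt.BRTConfig(**FAST), predictors=["x"])

    def test_predictions_in_unit_interval(self, mini_model, mini_dataset):
        p = mini_model.predict(mini_dataset.test)
        assert np.all((p > 0) & (p < 1))

    def test_refit_reproducibility(self, rng):
        x = rng.normal(size=600)
        df = _frame({"x": x}, _logistic_labels(rng, 1.5 * x))
        m1 = brt.fit_brt(df, brt.BRTConfig(**FAST), predictors=["x"])
        m2 = brt.fit_brt(df, brt.BRTConfig(**FAST), predictors=["x"])
        assert m1.n_trees == m2.n_trees
        assert m1.cv_auc == m2.cv_auc
        assert m1.cv_deviance_explained == m2.cv_deviance_explained
        np.testing.assert_array_equal(m1.predict(df), m2.predict(df))

    def test_weight_duplication_equivalence(self, rng):
        # duplicating a row equals doubling its weight (no bagging randomness)
        x = rng.normal(size=120)
        y = _logistic_labels(rng, x)
        cfg = brt.BRTConfig(tree_complexity=2, learning_rate=0.2, cv_folds=3,
                            max_trees=50, tree_step=25, bag_fraction=1.0,
                            min_node_size=5, seed=0)
        base = _frame({"x": x}, y)
        dup = pd.concat([base, base.iloc[[0]]], ignore_index=True)
        wt = base.copy()
        wt.loc[0, "weight"] = 2.0
        m_dup = brt.fit_brt(dup, cfg, predictors=["x"])
        m_wt = brt.fit_brt(wt, cfg, predictors=["x"])
        grid = _frame({"x": np.linspace(x.min(), x.max(), 50)}, np.zeros(50))
        np.testing.assert_allclose(m_dup.estimator.predict_proba(
            m_dup.encoder.transform(grid))[:, 1],
            m_wt.estimator.predict_proba(m_wt.encoder.transform(grid))[:, 1],
            atol=1e-6)

    def test_max_trees_boundary_warns(self, rng):
        x = rng.normal(size=400)
        df = _frame({"x": x}, _logistic_labels(rng, 2 * x))
        cfg = brt.BRTConfig(tree_complexity=1, learning_rate=0.001, cv_folds=3,
                            max_trees=50, tree_step=25, seed=0)
        with pytest.warns(UserWarning, match="max_trees"):
            model = brt.fit_brt(df, cfg, predictors=["x"])
        assert not model.converged


class TestInfluence:
    def test_single_predictor_is_100(self, rng):
        x = rng.normal(size=300)
        df = _frame({"x": x}, _logistic_labels(rng, 2 * x))
        model = brt.fit_brt(df, brt.BRTConfig(**FAST), predictors=["x"])
        assert brt.relative_influence(model)["x"] == pytest.approx(100.0, abs=0.01)

    def test_sum_is_100(self, mini_model):
        assert mini_model.influence.sum() == pytest.approx(100.0, abs=0.01)
        assert (mini_model.influence >= 0).all()

    def test_informative_beats_noise(self, rng):
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.normal(size=500)
            noise = r.normal(size=500)
            df = _frame({"x": x, "noise": noise}, _logistic_labels(r, 1.5 * x))
            cfg = brt.BRTConfig(**{**FAST, "seed": seed})
            model = brt.fit_brt(df, cfg, predictors=["x", "noise"])
            wins += model.influence["x"] > model.influence["noise"]
        assert wins >= 9


class TestTune:
    def test_lr_rule_and_determinism(self, rng):
        x = rng.normal(size=500)
        x2 = rng.normal(size=500)
        df = _frame({"x": x, "x2": x2},
                    _logistic_labels(rng, 0.8 * x + 0.5 * x2))
        cfg = brt.BRTConfig(tree_complexity=1, learning_rate=0.1, cv_folds=3,
                            max_trees=700, tree_step=50, seed=0)
        model, log = brt.tune_brt(df, tc_grid=(1, 2), lr_schedule=(0.5, 0.01),
                                  config=cfg, min_trees=300,
                                  predictors=["x", "x2"])
        # the aggressive rate stops far before the tree floor; the small one
        # is the largest rate that clears it and must be the one accepted
        for tc in (1, 2):
            sub = log[log["tc"] == tc]
            assert not sub[sub["lr"] == 0.5]["accepted"].any()
            assert sub[sub["lr"] == 0.01]["accepted"].all()
        assert model.config.learning_rate == 0.01
        assert model.n_trees > 300
        model2, log2 = brt.tune_brt(df, tc_grid=(1, 2), lr_schedule=(0.5, 0.01),
                                    config=cfg, min_trees=300,
                                    predictors=["x", "x2"])
        pd.testing.assert_frame_equal(log, log2)
        assert model2.config == model.config

    def test_no_candidate_error(self, rng):
        x = rng.normal(size=300)
        df = _frame({"x": x}, _logistic_labels(rng, 2 * x))
        cfg = brt.BRTConfig(**FAST)
        with pytest.raises(RuntimeError, match="smaller learning rates"):
            brt.tune_brt(df, tc_grid=(1,), lr_schedule=(0.5,), config=cfg,
                         min_trees=1000, predictors=["x"])


class TestPrune:
    def test_nothing_dropped_when_all_strong(self, rng):
        x = rng.normal(size=800)
        x2 = rng.normal(size=800)
        df = _frame({"x": x, "x2": x2},
                    _logistic_labels(rng, 1.2 * x + 1.2 * x2))
        model, dropped = brt.prune_predictors(df, brt.BRTConfig(**FAST),
                                              predictors=["x", "x2"])
        assert dropped == []
        assert set(model.predictors) == {"x", "x2"}

    def test_noise_predictors_pruned(self, rng):
        n = 1200
        x = rng.normal(size=n)
        x2 = rng.normal(size=n)
        noise = {f"n{i}": rng.normal(size=n) for i in range(3)}
        df = _frame({"x": x, "x2": x2, **noise},
                    _logistic_labels(rng, 1.5 * x + 1.2 * x2))
        model, dropped = brt.prune_predictors(
            df, brt.BRTConfig(**FAST), predictors=["x", "x2", *noise])
        assert {"x", "x2"} <= set(model.predictors)
        assert (model.influence >= 5.0 - 1e-9).all()

    def test_retained_contributions_meet_threshold(self, mini_dataset,
                                                   light_config):
        model, dropped = brt.prune_predictors(mini_dataset.train,
                                              light_config.brt_config)
        assert (model.influence >= 5.0 - 1e-9).all()
        assert set(dropped).isdisjoint(model.predictors)


class TestPartialDependence:
    def test_optimum_recovery(self, rng):
        t = rng.uniform(0, 20, 2500)
        z = 3.0 * np.exp(-0.5 * ((t - 10) / 2.5) ** 2) - 1.5
        df = _frame({"t": t}, _logistic_labels(rng, z))
        model = brt.fit_brt(df, brt.BRTConfig(**{**FAST, "max_trees": 150}),
                            predictors=["t"])
        curve = brt.partial_dependence(model, "t")
        assert float(curve.peak) == pytest.approx(10.0, abs=1.5)

    def test_flat_for_unsplit_predictor(self, rng):
        x = rng.normal(size=400)
        df = _frame({"x": x, "c": np.zeros(400)}, _logistic_labels(rng, 2 * x))
        model = brt.fit_brt(df, brt.BRTConfig(**FAST), predictors=["x", "c"])
        curve = brt.partial_dependence(model, "c",
                                       grid=np.linspace(-1, 1, 9))
        assert np.ptp(curve.values) < 1e-9

    def test_monotone_truth_monotone_curve(self, rng):
        from scipy.stats import spearmanr

        x = rng.uniform(0, 1, 2000)
        df = _frame({"x": x}, _logistic_labels(rng, 4 * x - 2))
        model = brt.fit_brt(df, brt.BRTConfig(**FAST), predictors=["x"])
        curve = brt.partial_dependence(model, "x")
        r = spearmanr(curve.grid, curve.values).statistic
        assert r > 0.9

    def test_unknown_predictor(self, mini_model):
        with pytest.raises(KeyError):
            brt.partial_dependence(mini_model, "nope")

    def test_rug_is_deciles(self, mini_model):
        pred = next(p for p in mini_model.predictors
                    if p not in mini_model.encoder.categories)
        curve = brt.partial_dependence(mini_model, pred)
        expect = np.percentile(mini_model._train_df[pred].to_numpy(float),
                               np.arange(10, 100, 10))
        np.testing.assert_allclose(curve.rug, expect)


class TestMonthInteraction:
    @staticmethod
    def _month_frame(rng, shift_per_month):
        rows = []
        for k, m in enumerate((10, 11, 12)):
            t = rng.uniform(0, 20, 700)
            z = 3 * np.exp(-0.5 * ((t - 10 - shift_per_month * k) / 2.5) ** 2) - 1.5
            rows.append(_frame({"t": t, "month": m}, _logistic_labels(rng, z)))
        return pd.concat(rows, ignore_index=True)

    def test_invariant_truth_low_month_influence(self, rng):
        df = self._month_frame(rng, 0.0)
        model = brt.fit_brt(df, brt.BRTConfig(**FAST), predictors=["t", "month"])
        report = brt.month_interaction_check(model)
        assert report["month_influence"] < 5.0

    def test_shifted_truth_elevates_interaction(self, rng):
        flat = brt.month_interaction_check(brt.fit_brt(
            self._month_frame(rng, 0.0), brt.BRTConfig(**FAST),
            predictors=["t", "month"]))
        shifted = brt.month_interaction_check(brt.fit_brt(
            self._month_frame(rng, 6.0), brt.BRTConfig(**FAST),
            predictors=["t", "month"]))
        assert shifted["max_interaction"] > flat["max_interaction"]

    def test_single_month_constant(self, rng):
        t = rng.uniform(0, 20, 400)
        df = _frame({"t": t, "month": 11},
                    _logistic_labels(rng, 0.3 * (t - 10)))
        model = brt.fit_brt(df, brt.BRTConfig(**FAST), predictors=["t", "month"])
        with pytest.warns(UserWarning, match="single level"):
            report = brt.month_interaction_check(model)
        assert report["month_influence"] == 0.0


def test_model_roundtrip(tmp_path, mini_model, mini_dataset):
    path = tmp_path / "model.joblib"
    brt.save_model(mini_model, path)
    loaded = brt.load_model(path)
    np.testing.assert_array_equal(loaded.predict(mini_dataset.test),
                                  mini_model.predict(mini_dataset.test))
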