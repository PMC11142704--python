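import numpy as np
import pytest

from protmol.gbm import (
    DEFAULT_SPACE,
    GbmHyperparams,
    LeakageError,
    SearchSpaceError,
    BoostedRepresentationEnsemble,
    ensemble_predict,
    fit_ensemble_weights,
    random_search,
    sample_hyperparams,
    simplex_grid,
    train_gbm,
)

HP = GbmHyperparams(
    learning_rate=0.3, max_tree_depth=4, lambda_reg=1.0, alpha_reg=0.0,
    max_delta_step=0.0, min_child_weight=1.0, num_rounds=60,
)


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(260, 6))
    y = X @ np.array([1.0, -2.0, 0.5, 0.0, 0.0, 1.5]) + rng.normal(scale=0.1, size=260)
    return X[:200], y[:200], X[200:], y[200:]


class TestTrainGbm:
    def test_fits_linear_signal(self, linear_data):
        Xtr, ytr, Xva, yva = linear_data
        model = train_gbm(Xtr, ytr, HP, seed=0)
        mse = np.mean((model.predict(Xva) - yva) ** 2)
        assert mse < np.var(yva)

    def test_decision_stump_has_two_leaf_values_per_tree(self, linear_data):
        Xtr, ytr, _, _ = linear_data
        hp = GbmHyperparams(
            learning_rate=0.5, max_tree_depth=1, lambda_reg=0.0, alpha_reg=0.0,
            max_delta_step=0.0, min_child_weight=1.0, num_rounds=1,
        )
        model = train_gbm(Xtr, ytr, hp, seed=0)
        assert len(np.unique(model.predict(Xtr))) <= 2

    def test_deterministic_given_seed(self, linear_data):
        Xtr, ytr, Xva, _ = linear_data
        p1 = train_gbm(Xtr, ytr, HP, seed=3).predict(Xva)
        p2 = train_gbm(Xtr, ytr, HP, seed=3).predict(Xva)
        assert np.array_equal(p1, p2)

    def test_width_mismatch_raises(self, linear_data):
        Xtr, ytr, _, _ = linear_data
        model = train_gbm(Xtr, ytr, HP, seed=0)
        with pytest.raises(ValueError, match="width"):
            model.predict(Xtr[:, :3])


class TestRandomSearch:
    def test_single_point_space(self, linear_data):
        Xtr, ytr, Xva, yva = linear_data
        space = {k: (v, v, "uniform") for k, v in
                 [("learning_rate", 0.3), ("max_delta_step", 0.0), ("min_child_weight", 1.0),
                  ("lambda_reg", 1.0), ("alpha_reg", 0.0)]}
        space["max_tree_depth"] = (3, 3, "int")
        space["num_rounds"] = (30, 30, "int")
        hp, log = random_search(Xtr, ytr, Xva, yva, space=space, n_iter=4, seed=0)
        assert hp.max_tree_depth == 3 and hp.num_rounds == 30
        assert len(log) == 4

    def test_log_deterministic_and_best_selected(self, linear_data):
        Xtr, ytr, Xva, yva = linear_data
        hp1, log1 = random_search(Xtr, ytr, Xva, yva, n_iter=8, seed=5)
        hp2, log2 = random_search(Xtr, ytr, Xva, yva, n_iter=8, seed=5)
        assert log1.equals(log2)
        assert log1.val_score.max() == log1[log1.val_score == log1.val_score.max()].val_score.iloc[0]
        best_row = log1.loc[log1.val_score.idxmax()]
        assert hp1.num_rounds == int(best_row.num_rounds)

    def test_degenerate_space_rejected(self, linear_data):
        Xtr, ytr, Xva, yva = linear_data
        bad = dict(DEFAULT_SPACE)
        bad["num_rounds"] = (50, 20, "int")
        with pytest.raises(SearchSpaceError):
            random_search(Xtr, ytr, Xva, yva, space=bad, n_iter=2, seed=0)

    def test_sampling_within_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            hp = sample_hyperparams(DEFAULT_SPACE, rng, "binary_classification")
            assert 1e-3 <= hp.learning_rate <= 0.5
            assert 2 <= hp.max_tree_depth <= 14
            assert 20 <= hp.num_rounds <= 2000
            assert 0.1 <= hp.negative_class_weight <= 1.0


class TestEnsembleWeights:
    def test_grid_size_and_simplex(self):
        grid = simplex_grid(0.05)
        assert len(grid) == 231
        assert all(abs(sum(w) - 1) < 1e-12 for w in grid)

    def test_perfect_model_gets_all_weight(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=50)
        w = fit_ensemble_weights([y, rng.normal(size=50), rng.normal(size=50)], y)
        assert w == (1.0, 0.0, 0.0)

    def test_identical_predictions_tie_break(self):
        y = np.arange(10.0)
        p = y + 0.1
        w = fit_ensemble_weights([p, p, p], y)
        assert w == (0.0, 0.0, 1.0)  # first grid point in lexicographic order

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=30)
        preds = [y + rng.normal(scale=s, size=30) for s in (0.2, 0.5, 1.0)]
        w = fit_ensemble_weights(preds, y)
        assert abs(sum(w) - 1.0) < 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fit_ensemble_weights([np.ones(3), np.ones(3), np.ones(4)], np.ones(3))

    def test_grid_optimum_not_worse_than_vertices(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=60)
        preds = [y + rng.normal(scale=s, size=60) for s in (0.3, 0.4, 0.6)]
        w = fit_ensemble_weights(preds, y)
        mix = np.stack(preds, axis=1) @ np.array(w)
        mse_mix = np.mean((mix - y) ** 2)
        for p in preds:
            assert mse_mix <= np.mean((p - y) ** 2) + 1e-12


class TestEnsemblePredict:
    def _models(self, linear_data):
        Xtr, ytr, _, _ = linear_data
        m = train_gbm(Xtr, ytr, HP, seed=0)
        return {"cls_only": m, "pooled_pair": m, "all": m}

    def test_degenerate_weights_reproduce_model(self, linear_data):
        Xtr, _, Xva, _ = linear_data
        models = self._models(linear_data)
        feats = {v: Xva for v in models}
        out = ensemble_predict(models, (1.0, 0.0, 0.0), feats)
        assert np.array_equal(out, models["cls_only"].predict(Xva))

    def test_weighted_mean_arithmetic(self, linear_data):
        models = self._models(linear_data)
        # hand-check on constants via monkeypatched predictions
        class Const:
            def __init__(self, v, n):
                self.v, self.n_features = v, n
            def predict(self, X):
                return np.full(len(X), self.v)
        n = 6
        consts = {"cls_only": Const(4.0, n), "pooled_pair": Const(0.0, n), "all": Const(8.0, n)}
        X = np.zeros((3, n))
        feats = {v: X for v in consts}
        out = ensemble_predict(consts, (0.5, 0.25, 0.25), feats)
        assert np.allclose(out, 4.0)
        out2 = ensemble_predict(consts, (1 / 3, 1 / 3, 1 / 3), {v: X for v in consts})
        assert np.allclose(out2, 4.0)

    def test_missing_variant_raises(self, linear_data):
        models = self._models(linear_data)
        with pytest.raises(ValueError, match="missing"):
            ensemble_predict(models, (1, 0, 0), {"cls_only": np.zeros((2, 6))})


class TestBoostedRepresentationEnsemble:
    def test_fit_predict_and_finalize(self, linear_data):
        Xtr, ytr, Xva, yva = linear_data
        feats_tr = {"cls_only": Xtr[:, :2], "pooled_pair": Xtr[:, 2:], "all": Xtr}
        feats_va = {"cls_only": Xva[:, :2], "pooled_pair": Xva[:, 2:], "all": Xva}
        ens = BoostedRepresentationEnsemble(n_iter=4, seed=0).fit(feats_tr, ytr, feats_va, yva)
        assert abs(sum(ens.weights_) - 1.0) < 1e-12
        pred = ens.predict(feats_va)
        assert pred.shape == yva.shape
        # finalists saw train + val rows
        assert ens.models_["all"].booster.num_boosted_rounds() == ens.hyperparams_["all"].num_rounds

    def test_leakage_audit(self, linear_data):
        Xtr, ytr, Xva, yva = linear_data
        feats_tr = {"cls_only": Xtr, "pooled_pair": Xtr, "all": Xtr}
        feats_va = {"cls_only": Xva, "pooled_pair": Xva, "all": Xva}
        with pytest.raises(LeakageError):
            BoostedRepresentationEnsemble(n_iter=1).fit(
                feats_tr, ytr, feats_va, yva,
                train_keys=["a", "b"], test_keys={"b", "c"},
            )

    def test_classification_outputs_in_unit_interval(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(240, 5))
        y = (X[:, 0] + 0.3 * rng.normal(size=240) > 0).astype(float)
        feats_tr = {v: X[:200] for v in ("cls_only", "pooled_pair", "all")}
        feats_va = {v: X[200:] for v in ("cls_only", "pooled_pair", "all")}
        ens = BoostedRepresentationEnsemble(
            task="binary_classification", n_iter=4, seed=1
        ).fit(feats_tr, y[:200], feats_va, y[200:])
        p = ens.predict(feats_va)
        assert (p >= 0).all() and (p <= 1).all()
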