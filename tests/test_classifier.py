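"""RBF-SVM training, cross-validation partitioning, and grid search."""

import numpy as np
import pytest

from enzid.classifier import (
    SVMConfig,
    cross_validate,
    grid_search,
    load_model,
    predict_sequences,
    save_model,
    train,
)
from enzid.encoding import EncodingSpec, encode_dataset
from enzid.sequence_io import ProteinSequence


def _clouds(n=30, gap=6.0, seed=0):
    """Two well-separated Gaussian point clouds in 2-D."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(gap, 1, (n, 2))])
    y = np.array([0] * n + [1] * n)
    return X, y


class TestSVMConfig:
    def test_log2_parameterization(self):
        cfg = SVMConfig.from_log2(0.2, 7.2)
        assert cfg.c == pytest.approx(2**0.2)
        assert cfg.gamma == pytest.approx(2**7.2)

    @pytest.mark.parametrize("c,g", [(0, 1), (1, 0), (-1, 1)])
    def test_positive_parameters_required(self, c, g):
        with pytest.raises(ValueError):
            SVMConfig(c, g)


class TestTrain:
    def test_separable_clouds_training_accuracy_one(self):
        X, y = _clouds()
        model = train(X, y, SVMConfig(1.0, 0.5))
        assert (model.predict(X) == y).all()

    def test_decision_scores_sign_convention(self):
        X, y = _clouds()
        scores = train(X, y, SVMConfig(1.0, 0.5)).decision_function(X)
        assert (scores[y == 1] > 0).all() and (scores[y == 0] < 0).all()

    def test_deterministic_for_fixed_config(self):
        X, y = _clouds(seed=5)
        s1 = train(X, y, SVMConfig(2.0, 1.0)).decision_function(X)
        s2 = train(X, y, SVMConfig(2.0, 1.0)).decision_function(X)
        assert np.array_equal(s1, s2)

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="both classes"):
            train(X, np.ones(4, int), SVMConfig(1.0, 1.0))

    def test_missing_values_rejected(self):
        X, y = _clouds(n=5)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            train(X, y, SVMConfig(1.0, 1.0))


class TestCrossValidate:
    def test_partition_is_disjoint_and_covering(self):
        X, y = _clouds(n=25, seed=2)
        for seed in (0, 1, 99):
            cv = cross_validate(X, y, SVMConfig(1.0, 0.5), n_folds=5, seed=seed)
            counts = np.bincount(cv.fold_assignment, minlength=5)
            assert counts.sum() == len(y)  # every sample in exactly one fold
            assert (counts == 10).all()

    def test_pooled_equals_fold_sum(self):
        X, y = _clouds(n=20, seed=3)
        cv = cross_validate(X, y, SVMConfig(1.0, 0.5), n_folds=4, seed=1)
        assert cv.pooled.tp == sum(f.tp for f in cv.folds)
        assert cv.pooled.total == len(y)

    def test_same_seed_identical_result(self):
        X, y = _clouds(n=20, seed=4)
        a = cross_validate(X, y, SVMConfig(1.0, 0.5), n_folds=4, seed=7)
        b = cross_validate(X, y, SVMConfig(1.0, 0.5), n_folds=4, seed=7)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        assert np.array_equal(a.scores, b.scores)
        assert a.metric_set == b.metric_set

    def test_leave_one_out_limiting_case(self):
        """Jackknife: n_folds = n gives n validation folds of size 1."""
        X, y = _clouds(n=5, seed=0)  # 10 samples total
        cv = cross_validate(
            X, y, SVMConfig(1.0, 0.5), n_folds=10, seed=0, stratified=False
        )
        assert len(cv.folds) == 10
        assert all(f.total == 1 for f in cv.folds)

    def test_pure_noise_near_chance(self):
        rng = np.random.default_rng(11)
        X = rng.random((120, 10))
        y = np.array([0, 1] * 60)
        cv = cross_validate(X, y, SVMConfig(1.0, 1.0), n_folds=6, seed=0)
        # binomial 3-sigma band around 0.5 at n=120 is about +/-0.14
        assert abs(cv.accuracy - 0.5) <= 0.15

    def test_too_many_folds_rejected(self):
        X, y = _clouds(n=3)
        with pytest.raises(ValueError, match="n_folds"):
            cross_validate(X, y, SVMConfig(1.0, 1.0), n_folds=7, stratified=False)

    def test_stratified_bounded_by_class_size(self):
        X, y = _clouds(n=4)
        with pytest.raises(ValueError, match="smallest class"):
            cross_validate(X, y, SVMConfig(1.0, 1.0), n_folds=5, stratified=True)


class TestGridSearch:
    def test_single_point_grid_returns_that_config(self):
        X, y = _clouds(n=12)
        gs = grid_search(X, y, [0.2], [7.2], n_folds=4, seed=0)
        assert gs.best.c == pytest.approx(1.1487, abs=5e-5)
        assert gs.best.gamma == pytest.approx(147.0334, abs=5e-5)

    def test_separable_data_reaches_perfect_accuracy(self):
        X, y = _clouds(n=18, gap=8.0)
        gs = grid_search(X, y, [-2.0, 0.0, 2.0], [-4.0, -2.0, 0.0], n_folds=3, seed=0)
        assert gs.best_accuracy == 1.0

    def test_tie_breaks_toward_smaller_exponents(self):
        X, y = _clouds(n=18, gap=10.0)
        # many points achieve accuracy 1.0; argmax must be the smallest (a, b)
        gs = grid_search(X, y, [2.0, -2.0, 0.0], [0.0, -4.0, -2.0], n_folds=3, seed=0)
        perfect = gs.table[gs.table["acc"] == gs.best_accuracy]
        expect = min(zip(perfect["log2c"], perfect["log2gamma"]))
        assert gs.best_log2 == expect

    def test_table_matches_pointwise_reruns(self):
        X, y = _clouds(n=12, gap=3.0, seed=6)
        gs = grid_search(X, y, [-1.0, 1.0], [-1.0, 1.0], n_folds=3, seed=4)
        for _, row in gs.table.iterrows():
            cv = cross_validate(
                X, y, SVMConfig.from_log2(row["log2c"], row["log2gamma"]),
                n_folds=3, seed=4,
            )
            assert cv.accuracy == pytest.approx(row["acc"])

    def test_empty_grid_rejected(self):
        X, y = _clouds(n=6)
        with pytest.raises(ValueError, match="non-empty"):
            grid_search(X, y, [], [0.0])


class TestModelBundle:
    def test_save_load_predict_round_trip(self, tmp_path, small_dataset):
        ds, _ = small_dataset
        spec = EncodingSpec(include_aac=True, subset=("A***A", "L***L"))
        fm = encode_dataset(ds, spec)
        cfg = SVMConfig(8.0, 8.0)
        model = train(fm, config=cfg)
        path = tmp_path / "model.joblib"
        save_model(path, model, cfg, spec)
        bundle = load_model(path)
        assert bundle["config"] == cfg
        assert bundle["encoding_spec"] == spec
        preds = predict_sequences(bundle, ds.sequences)
        assert (preds["error"] == "").all()
        agree = (preds["label"].to_numpy(int) == ds.labels).mean()
        assert agree >= 0.9  # training-set predictions on separable data

    def test_predict_short_sequence_gets_error_row(self, tmp_path, small_dataset):
        ds, _ = small_dataset
        spec = EncodingSpec(include_aac=True, subset=("A***A",))
        fm = encode_dataset(ds, spec)
        cfg = SVMConfig(1.0, 1.0)
        save_model(tmp_path / "m.joblib", train(fm, config=cfg), cfg, spec)
        bundle = load_model(tmp_path / "m.joblib")
        out = predict_sequences(
            bundle, [ProteinSequence("tiny", "ACD"), ds.sequences[0]]
        )
        assert out.loc[0, "error"] != "" and out.loc[1, "error"] == ""

    def test_load_rejects_foreign_file(self, tmp_path):
        import joblib

        joblib.dump({"whatever": 1}, tmp_path / "x.joblib")
        with pytest.raises(ValueError, match="not a recognized"):
            load_model(tmp_path / "x.joblib")
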