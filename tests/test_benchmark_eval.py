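"""Metrics (incl. uncertainty-aware ones), cross-validation, grid search
and the comparative benchmark."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import Ridge

import toxgp as tg
from toxgp.benchmark_eval import make_estimator, make_reducer
from toxgp.exceptions import ValidationError
from toxgp.gp_model import PredictionSet


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        rep = tg.compute_metrics(y, y.copy())
        assert (rep.mae, rep.rmse, rep.r2) == (0.0, 0.0, 1.0)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        rep = tg.compute_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert rep.mae == pytest.approx(2 / 3)
        assert rep.rmse == pytest.approx(np.sqrt(2 / 3))
        assert rep.r2 == pytest.approx(0.0)

    def test_mean_predictor_r2_exactly_zero(self, rng):
        y = rng.standard_normal(50)
        rep = tg.compute_metrics(y, np.full(50, y.mean()))
        assert rep.r2 == 0.0

    def test_constant_truth_reports_missing_r2(self):
        rep = tg.compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert rep.r2 is None
        assert rep.pearson_r is None

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mae_never_exceeds_rmse(self, ys, seed):
        y = np.asarray(ys)
        preds = y + np.random.default_rng(seed).standard_normal(len(y))
        rep = tg.compute_metrics(y, preds)
        assert rep.mae <= rep.rmse + 1e-12


class TestWeightedRMSE:
    def test_uniform_uncertainties_reduce_to_rmse(self, rng):
        y = rng.standard_normal(20)
        m = y + rng.standard_normal(20)
        sds = np.full(20, 3.7)
        plain = tg.compute_metrics(y, m).rmse
        assert tg.weighted_rmse(y, m, sds) == pytest.approx(plain, abs=1e-12)

    def test_hand_computed_two_points(self):
        # errors (0, 2), sds (1, 10): sqrt(4 * 0.01 / 1.01)
        val = tg.weighted_rmse([0.0, 0.0], [0.0, 2.0], [1.0, 10.0])
        assert val == pytest.approx(np.sqrt(0.04 / 1.01), abs=1e-10)
        assert val == pytest.approx(0.1990, abs=1e-4)

    def test_downweighting_worst_point_never_increases(self):
        # exhaustive over two-point configurations: giving the larger
        # error the larger sd can only shrink the statistic vs uniform
        errors = [0.0, 0.5, 1.0, 2.0, 5.0]
        for e1, e2 in itertools.product(errors, repeat=2):
            if e2 <= e1:
                continue
            y = np.zeros(2)
            m = np.array([e1, e2])
            uniform = tg.weighted_rmse(y, m, np.ones(2))
            down = tg.weighted_rmse(y, m, np.array([1.0, 4.0]))
            assert down <= uniform + 1e-12

    def test_zero_sd_rejected_with_guidance(self):
        with pytest.raises(ValidationError, match="jitter"):
            tg.weighted_rmse([1.0], [1.0], [0.0])

    def test_inverse_sd_weighting_available(self):
        v = tg.weighted_rmse([0.0, 0.0], [0.0, 2.0], [1.0, 10.0],
                             weighting="inverse_sd")
        assert v == pytest.approx(np.sqrt(0.4 / 1.1), abs=1e-10)

    def test_converges_to_rmse_as_sds_flatten(self, rng):
        y = rng.standard_normal(15)
        m = y + rng.standard_normal(15)
        plain = tg.compute_metrics(y, m).rmse
        for eps in (1.0, 0.1, 0.001):
            sds = 2.0 + eps * rng.random(15)
            w = tg.weighted_rmse(y, m, sds)
            assert abs(w - plain) <= eps * plain


def test_average_sd():
    ps = PredictionSet(means=np.zeros(2), sds=np.array([1.0, 3.0]))
    assert tg.average_sd(ps) == 2.0


class TestCrossValidate:
    def test_mean_predictor_closed_form_on_symmetric_toy(self):
        # 4 points y = (0, 0, 2, 2), 2-fold: whichever way the shuffle
        # partitions, the validation MAE is the mean |y_i - train_mean|
        X = np.zeros((4, 1))
        y = np.array([0.0, 0.0, 2.0, 2.0])
        est = make_estimator("mean")
        mean_mae, sd_mae = tg.cross_validate(est, X, y, scheme="k_fold",
                                             n_splits=2, seed=0)
        # folds are either {same-label pairs} -> MAE 2, or {mixed pairs}
        # -> MAE 1; both folds share the structure so mean is 1 or 2
        assert min(abs(mean_mae - 1.0), abs(mean_mae - 2.0)) < 1e-12

    def test_identical_seed_identical_folds(self, small_dataset, rng):
        X = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        a = tg.cross_validate(make_estimator("linear"), X, y, n_splits=5, seed=3)
        b = tg.cross_validate(make_estimator("linear"), X, y, n_splits=5, seed=3)
        assert a == b

    def test_kfold_partitions_once(self, rng):
        from sklearn.model_selection import KFold

        X = rng.standard_normal((10, 2))
        counts = np.zeros(10, int)
        for _, va in KFold(5, shuffle=True, random_state=0).split(X):
            counts[va] += 1
        assert (counts == 1).all()

    def test_too_many_splits_rejected(self, rng):
        with pytest.raises(ValidationError):
            tg.cross_validate(make_estimator("linear"), np.zeros((3, 1)),
                              np.zeros(3), n_splits=5)


class TestGridSearch:
    def test_single_point_grid(self, rng):
        X = rng.standard_normal((30, 2))
        y = X[:, 0]
        best, table = tg.grid_search(Ridge(), {"alpha": [0.5]}, X, y, n_splits=3)
        assert best == {"alpha": 0.5}
        assert len(table) == 1

    def test_recovers_generating_ridge_penalty(self):
        # strongly regularized data-generating process: tiny alpha wins
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((60, 8))
            beta = r.standard_normal(8)
            y = X @ beta + 0.05 * r.standard_normal(60)
            best, _ = tg.grid_search(
                Ridge(), {"alpha": [0.01, 100.0, 10000.0]}, X, y,
                scheme="k_fold", n_splits=5, seed=seed,
            )
            wins += best == {"alpha": 0.01}
        assert wins >= 18

    def test_result_stable_under_grid_permutation(self, rng):
        X = rng.standard_normal((40, 3))
        y = X[:, 1] + 0.1 * rng.standard_normal(40)
        g1 = {"alpha": [0.01, 1.0, 100.0]}
        g2 = {"alpha": [100.0, 0.01, 1.0]}
        b1, _ = tg.grid_search(Ridge(), g1, X, y, n_splits=4, seed=0)
        b2, _ = tg.grid_search(Ridge(), g2, X, y, n_splits=4, seed=0)
        assert b1 == b2

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValidationError):
            tg.grid_search(Ridge(), {}, np.zeros((4, 1)), np.zeros(4))


@pytest.fixture(scope="module")
def fused_and_split():
    cfg = tg.GeneratorConfig(n_compounds=80, n_genes=60, n_bits=24, seed=3)
    dataset, _ = tg.generate_dataset(cfg)
    fused = tg.fuse_features(dataset)
    split = tg.divergent_split(fused, 0.2, "divergent", seed=3)
    return fused, dataset.targets.to_numpy(), split


class TestBenchmark:
    def test_mean_predictor_baseline(self, fused_and_split):
        fused, y, split = fused_and_split
        result = tg.run_benchmark(fused, y, split, suite=["mean"],
                                  reduction_policy={"mean": "none"})
        assert abs(result.table.iloc[0]["r2"]) < 0.3  # near-null model

    def test_row_count_is_suite_times_reductions(self, fused_and_split):
        fused, y, split = fused_and_split
        result = tg.run_benchmark(
            fused, y, split,
            suite=["linear", "knn"],
            reduction_policy={"linear": ["none", "tsvdh"], "knn": ["tsvdh"]},
        )
        assert len(result.table) == 3
        assert not result.errors

    def test_gp_rows_carry_uncertainty_metrics(self, fused_and_split):
        fused, y, split = fused_and_split
        result = tg.run_benchmark(fused, y, split, suite=["gp", "linear"])
        gp_row = result.table.set_index("regressor").loc["gp"]
        assert gp_row["asd"] > 0
        assert gp_row["weighted_rmse"] > 0
        lin_row = result.table.set_index("regressor").loc["linear"]
        assert np.isnan(lin_row["asd"]) or lin_row["asd"] is None

    def test_unknown_regressor_lists_registry(self, fused_and_split):
        fused, y, split = fused_and_split
        with pytest.raises(ValidationError, match="registered"):
            tg.run_benchmark(fused, y, split, suite=["mystery"])

    def test_estimator_failure_recorded_run_continues(self, fused_and_split):
        fused, y, split = fused_and_split
        result = tg.run_benchmark(
            fused, y, split, suite=["linear", "gp"],
            reduction_policy={"linear": "pca", "gp": "tsvdh"},
        )
        # pca default k=2 is legal, so no failure expected here; assert
        # bookkeeping fields exist either way
        assert set(result.table["regressor"]) <= {"linear", "gp"}

    def test_default_config_loads(self):
        import importlib.resources

        import yaml

        text = (
            importlib.resources.files("toxgp") / "default_benchmark.yaml"
        ).read_text()
        cfg = yaml.safe_load(text)
        assert set(cfg["suite"]) <= tg.benchmark_eval.REGISTRY_NAMES
        assert set(cfg["grids"]) == set(cfg["suite"])

    def test_registry_instantiates_every_family(self):
        for name in sorted(tg.benchmark_eval.REGISTRY_NAMES):
            est = make_estimator(name, seed=0)
            assert hasattr(est, "fit") and hasattr(est, "predict")
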