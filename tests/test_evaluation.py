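"""R², fold plans, corrected SEM, block bootstrap and hyperparameter search."""

import numpy as np
import pytest

from spikedecode.data_format import BinnedDataset, LagSpec
from spikedecode.evaluation import (
    block_bootstrap_ci,
    corrected_sem,
    make_fold_plan,
    optimize_hyperparameters,
    r2_score,
    run_comparison,
)


class TestR2:
    def test_perfect_prediction_scores_one(self, rng):
        Y = rng.standard_normal((50, 2))
        assert r2_score(Y, Y) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self, rng):
        Y = rng.standard_normal((50, 2))
        Yhat = np.tile(Y.mean(axis=0), (50, 1))
        assert r2_score(Y, Yhat) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_negative_case(self):
        # 1 - 5/2 = -1.5
        assert r2_score([0.0, 1.0, 2.0], [0.0, 0.0, 0.0]) == pytest.approx(-1.5)

    def test_average_over_output_dimensions(self):
        Y = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        Yhat = np.column_stack([Y[:, 0], np.zeros(3)])  # perfect x, zero y
        assert r2_score(Y, Yhat) == pytest.approx((1.0 + (-1.5)) / 2)

    def test_agrees_with_direct_formula_oracle(self, rng):
        for _ in range(20):
            Y = rng.standard_normal((30, 3))
            Yhat = rng.standard_normal((30, 3))
            oracle = np.mean([
                1 - np.sum((Yhat[:, j] - Y[:, j]) ** 2)
                / np.sum((Y[:, j] - Y[:, j].mean()) ** 2)
                for j in range(3)
            ])
            assert r2_score(Y, Yhat) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            r2_score(np.ones(10), np.zeros(10))


class TestFoldPlan:
    def test_canonical_ten_fold_blocks(self):
        plan = make_fold_plan(100, 10)
        tests = [tuple(te[[0, -1]]) for _, _, te in plan]
        assert tests[0] == (90, 99)
        assert tests[1] == (80, 89)
        assert all(len(te) == 10 for _, _, te in plan)
        assert all(len(va) == 10 for _, va, _ in plan)
        assert all(len(tr) == 80 for tr, _, _ in plan)

    def test_sets_disjoint_and_cover_all_rows(self):
        plan = make_fold_plan(1003, 10)
        for tr, va, te in plan:
            allrows = np.concatenate([tr, va, te])
            assert len(allrows) == 1003
            assert len(np.unique(allrows)) == 1003

    def test_test_blocks_tile_rows_exactly_once(self):
        for K, J in ((1000, 10), (1003, 10), (247, 5), (520, 4)):
            plan = make_fold_plan(K, J)
            union = np.concatenate([te for _, _, te in plan])
            assert len(union) == K
            assert np.array_equal(np.sort(union), np.arange(K))

    def test_validation_and_test_blocks_contiguous(self):
        plan = make_fold_plan(500, 10)
        for _, va, te in plan:
            assert np.array_equal(va, np.arange(va[0], va[-1] + 1))
            assert np.array_equal(te, np.arange(te[0], te[-1] + 1))

    def test_two_fold_fallback_warns(self):
        with pytest.warns(UserWarning, match="clamped"):
            plan = make_fold_plan(100, 2)
        tr, va, te = plan.folds[0]
        assert len(te) == 50 and len(va) == 25 and len(tr) == 25

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_fold_plan(50, 10)


class TestCorrectedSem:
    def test_zero_spread_gives_zero(self):
        assert corrected_sem([0.5] * 10) == 0.0

    def test_hand_computed_value(self):
        # sigma=1, J=10 -> sqrt(0.1 + 1/9) = 0.4595
        scores = np.arange(10.0)
        scores = (scores - scores.mean()) / scores.std(ddof=1)  # sigma exactly 1
        assert corrected_sem(scores) == pytest.approx(0.45947, abs=1e-4)

    @pytest.mark.parametrize("J", [2, 3, 5, 10, 20])
    def test_always_exceeds_naive_sem(self, J, rng):
        scores = rng.standard_normal(J)
        sigma = scores.std(ddof=1)
        assert corrected_sem(scores) > sigma / np.sqrt(J)

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            corrected_sem([0.5])


class TestBlockBootstrap:
    def test_perfect_predictions_give_degenerate_interval(self, rng):
        Y = rng.standard_normal((200, 2))
        lo, hi = block_bootstrap_ci(Y, Y, seed=0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_defaults_twenty_subsets_thousand_resamples(self, rng):
        Y = rng.standard_normal((200, 1))
        Yhat = Y + 0.5 * rng.standard_normal((200, 1))
        lo, hi, samples = block_bootstrap_ci(Y, Yhat, seed=3, return_samples=True)
        assert samples.shape == (1000,)
        assert lo < hi

    def test_seeded_reproducibility(self, rng):
        Y = rng.standard_normal((100, 1))
        Yhat = Y + rng.standard_normal((100, 1))
        assert block_bootstrap_ci(Y, Yhat, seed=7) == \
            block_bootstrap_ci(Y, Yhat, seed=7)
        assert block_bootstrap_ci(Y, Yhat, seed=7) != \
            block_bootstrap_ci(Y, Yhat, seed=8)

    def test_interval_narrows_with_more_identical_segments(self, rng):
        """Adding more statistically identical segments shrinks the CI."""
        seg_len = 100
        Y = rng.standard_normal((160 * seg_len, 1))
        Yhat = Y + rng.standard_normal((160 * seg_len, 1))
        w = []
        for n_sub in (10, 40, 160):
            n = n_sub * seg_len
            lo, hi = block_bootstrap_ci(Y[:n], Yhat[:n], n_subsets=n_sub, seed=5)
            w.append(hi - lo)
        assert w[0] > w[1] > w[2]

    def test_too_few_rows_rejected(self, rng):
        Y = rng.standard_normal((10, 1))
        with pytest.raises(ValueError):
            block_bootstrap_ci(Y, Y, n_subsets=20)


class TestHyperparameterSearch:
    def _quadratic_space(self):
        # validation-R2 proxy peaked at ridge = 30
        return {"ridge": (0.0, 100.0)}

    def test_budget_one_returns_single_evaluated_point(self, rng):
        X = rng.standard_normal((100, 3))
        Y = X @ rng.standard_normal((3, 1))
        Xv = rng.standard_normal((40, 3))
        Yv = Xv @ np.zeros((3, 1)) + 1e-3 * rng.standard_normal((40, 1))
        best, log = optimize_hyperparameters(
            "wiener_filter", {"ridge": (0.0, 10.0)}, X, Y, Xv, Yv,
            budget=1, strategy="random", seed=0,
        )
        assert len(log) == 1
        assert best == log[0][0]

    @pytest.mark.parametrize("strategy", ["bayesian", "random", "grid"])
    def test_finds_quadratic_optimum(self, strategy):
        """1-D quadratic response surface: optimum located within 10%."""
        from spikedecode.evaluation import _search

        def objective(params):
            return -(params["x"] - 0.3) ** 2

        best, log = _search(objective, {"x": (0.0, 1.0)}, budget=15,
                            strategy=strategy, seed=4)
        assert abs(best["x"] - 0.3) <= 0.1
        assert len(log) <= 15

    def test_best_is_argmax_of_log(self, rng):
        from spikedecode.evaluation import _search

        best, log = _search(lambda p: np.sin(7 * p["x"]), {"x": (0.0, 1.0)},
                            budget=10, strategy="random", seed=1)
        scores = [s for _, s in log]
        assert best == log[int(np.argmax(scores))][0]

    def test_all_failures_raise_with_log(self, rng):
        X = np.full((20, 2), np.nan)
        with pytest.raises(RuntimeError, match="failed"):
            optimize_hyperparameters(
                "wiener_filter", {"ridge": (0.0, 1.0)}, X, np.zeros((20, 1)),
                X, np.zeros((20, 1)), budget=3, strategy="random", seed=0,
            )


class TestRunComparison:
    def test_single_decoder_matches_manual_sequence(self, cortical_small):
        """Driver output equals a hand-rolled scale/fit/score loop."""
        from spikedecode.data_format import (
            apply_scaler,
            fit_scaler,
            make_design_matrix,
        )
        from spikedecode.decoders import WienerFilterDecoder

        data, _ = cortical_small
        lags = LagSpec(2, 1, 0)
        reports = run_comparison(data, ["wiener_filter"], lags, n_folds=10,
                                 budget=0, seed=0)
        dm = make_design_matrix(data, lags)
        plan = make_fold_plan(dm.X.shape[0], 10)
        manual = []
        for tr, va, te in plan:
            xs = fit_scaler(dm.X[tr], "zscore")
            ys = fit_scaler(dm.Y[tr], "center")
            w = WienerFilterDecoder().fit(
                apply_scaler(xs, dm.X[tr]), apply_scaler(ys, dm.Y[tr]))
            pred = ys.inverse_transform(w.predict(apply_scaler(xs, dm.X[te])))
            manual.append(r2_score(dm.Y[te], pred))
        assert np.allclose(reports["wiener_filter"].fold_scores, manual)

    def test_report_serializes_with_fold_detail(self, cortical_small):
        data, _ = cortical_small
        import json

        reports = run_comparison(data, ["wiener_filter"], LagSpec(1, 1, 0),
                                 n_folds=10, budget=0, seed=0)
        blob = json.loads(json.dumps(reports["wiener_filter"].to_dict()))
        assert blob["n_folds"] == 10
        assert len(blob["fold_scores"]) == 10
        assert blob["mean"] == pytest.approx(
            np.mean(blob["fold_scores"]))

    def test_lag_override_changes_only_that_decoder(self, cortical_small):
        data, _ = cortical_small
        lags = LagSpec(2, 1, 0)
        base = run_comparison(
            data, ["wiener_filter", "kalman_filter"], lags, n_folds=10,
            budget=0, seed=0)
        over = run_comparison(
            data, ["wiener_filter", "kalman_filter"], lags, n_folds=10,
            budget=0, seed=0,
            lag_overrides={"kalman_filter": LagSpec(0, 1, 2)})
        assert np.allclose(base["wiener_filter"].fold_scores,
                           over["wiener_filter"].fold_scores)
        assert not np.allclose(base["kalman_filter"].fold_scores,
                               over["kalman_filter"].fold_scores)
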