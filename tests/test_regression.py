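import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ddg_errorband import (
    best_subset_select,
    bic,
    effect_on_interval_width,
    error_bound,
    fit_ols,
    predict_interval,
    stepwise_select,
)
from ddg_errorband.features import PredictorTable
from ddg_errorband.regression import predict


def make_table(X: np.ndarray, y: np.ndarray, names=None) -> PredictorTable:
    names = names or [f"x{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df["error_abs"] = y
    df["system_id"] = "S1"
    return PredictorTable(
        df=df, predictors=names, blocks={n: [n] for n in names}, pool="model3"
    )


def random_table(rng, n=40, p=4):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = 1.0 + X @ beta + rng.normal(size=n)
    return make_table(X, y)


class TestFitOls:
    def test_matches_statsmodels_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            table = random_table(rng, n=int(rng.integers(15, 60)), p=int(rng.integers(1, 6)))
            m = fit_ols(table)
            ref = sm.OLS(table.y, sm.add_constant(table.X.to_numpy())).fit()
            np.testing.assert_allclose(m.params, ref.params, atol=1e-8)
            assert m.loglik == pytest.approx(ref.llf, abs=1e-8)
            assert m.adj_r2 == pytest.approx(ref.rsquared_adj, abs=1e-8)
            assert m.s2 == pytest.approx(ref.mse_resid, abs=1e-8)

    def test_intercept_only(self):
        rng = np.random.default_rng(0)
        y = rng.normal(2.0, 1.0, size=30)
        table = make_table(rng.normal(size=(30, 1)), y)
        m = fit_ols(table, predictors=[])
        assert m.params[0] == pytest.approx(y.mean())
        assert m.adj_r2 == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_fit_is_error_unless_floored(self):
        x = np.linspace(0, 1, 20)
        table = make_table(x[:, None], 2.0 + 3.0 * x)
        with pytest.raises(ValueError, match="RSS"):
            fit_ols(table)
        m = fit_ols(table, rss_floor=True)
        assert np.isfinite(m.loglik)
        assert m.params[1] == pytest.approx(3.0)

    def test_aliased_column_dropped_keep_first(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        X = np.column_stack([x, 2 * x])
        y = 1 + x + rng.normal(size=30)
        m = fit_ols(make_table(X, y))
        assert m.predictor_names == ["x0"]
        assert m.dropped == ["x1"]

    def test_reproduces_training_fitted_values(self):
        rng = np.random.default_rng(5)
        table = random_table(rng)
        m = fit_ols(table)
        ref = sm.OLS(table.y, sm.add_constant(table.X.to_numpy())).fit()
        fitted = [predict(m, row) for _, row in table.df.iterrows()]
        np.testing.assert_allclose(fitted, ref.fittedvalues, atol=1e-10)


class TestBic:
    def test_formula_against_independent_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            table = random_table(rng)
            m = fit_ols(table)
            n, d = m.n, len(m.predictor_names)
            # independently coded Gaussian max-loglik BIC
            resid = table.y - np.array([predict(m, r) for _, r in table.df.iterrows()])
            rss = float(resid @ resid)
            ll = -n / 2 * (math.log(2 * math.pi) + math.log(rss / n) + 1)
            assert bic(m) == pytest.approx(-2 * ll + math.log(n) * d, abs=1e-8)

    def test_penalty_difference(self):
        # equal loglik, d = 3 vs 5, n = 100 -> BIC difference 2 ln 100
        ll, n = -140.0, 100
        b3 = -2 * ll + math.log(n) * 3
        b5 = -2 * ll + math.log(n) * 5
        assert b5 - b3 == pytest.approx(2 * math.log(100))

    def test_convention_shift_preserves_ranking(self):
        rng = np.random.default_rng(8)
        table = random_table(rng, n=50, p=4)
        m1 = fit_ols(table, predictors=["x0", "x1"])
        m2 = fit_ols(table, predictors=["x0", "x1", "x2"])
        shift = math.log(m1.n)
        assert bic(m1, "plus_intercept") - bic(m1) == pytest.approx(shift)
        order_paper = bic(m1) < bic(m2)
        order_alt = bic(m1, "plus_intercept") < bic(m2, "plus_intercept")
        assert order_paper == order_alt


class TestPredictInterval:
    def test_matches_closed_form_oracle_on_toy(self):
        # 5-point textbook regression, hand-coded PI formula
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.4])
        m = fit_ols(make_table(x[:, None], y))
        from scipy import stats as ss

        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        rss = float(((y - X @ beta) ** 2).sum())
        s2 = rss / 3
        for x0 in (0.0, 2.5, 7.0):
            v = np.array([1.0, x0])
            half = ss.t.ppf(0.975, 3) * math.sqrt(s2 * (1 + v @ np.linalg.inv(X.T @ X) @ v))
            pb = predict_interval(m, [x0], level=0.95)
            assert pb.point == pytest.approx(float(v @ beta), abs=1e-8)
            assert pb.upper == pytest.approx(float(v @ beta) + half, abs=1e-8)
            assert pb.lower == pytest.approx(float(v @ beta) - half, abs=1e-8)

    def test_matches_statsmodels_out_of_sample(self):
        rng = np.random.default_rng(3)
        table = random_table(rng, n=30, p=3)
        m = fit_ols(table)
        ref = sm.OLS(table.y, sm.add_constant(table.X.to_numpy())).fit()
        x0 = rng.normal(size=3)
        frame = ref.get_prediction(np.concatenate([[1.0], x0])).summary_frame(alpha=0.05)
        pb = predict_interval(m, x0, level=0.95)
        assert pb.lower == pytest.approx(frame["obs_ci_lower"].iloc[0], abs=1e-8)
        assert pb.upper == pytest.approx(frame["obs_ci_upper"].iloc[0], abs=1e-8)

    def test_levels_are_nested(self):
        rng = np.random.default_rng(4)
        table = random_table(rng)
        m = fit_ols(table)
        x0 = rng.normal(size=4)
        inner = predict_interval(m, x0, level=0.80)
        outer = predict_interval(m, x0, level=0.99)
        assert outer.lower < inner.lower < inner.upper < outer.upper

    def test_wider_at_higher_leverage(self):
        rng = np.random.default_rng(6)
        table = random_table(rng, n=50, p=2)
        m = fit_ols(table)
        centre = table.X.mean().to_numpy()
        near = predict_interval(m, centre, level=0.95)
        far = predict_interval(m, centre + 5.0, level=0.95)
        assert far.upper - far.lower > near.upper - near.lower

    def test_zero_variance_degenerates_to_point(self):
        x = np.linspace(0, 1, 10)
        m = fit_ols(make_table(x[:, None], 1.0 + 2.0 * x), rss_floor=True)
        m.s2 = 0.0
        pb = predict_interval(m, [0.3], level=0.95)
        assert pb.lower == pb.point == pb.upper

    def test_bad_inputs(self):
        rng = np.random.default_rng(9)
        m = fit_ols(random_table(rng))
        with pytest.raises(ValueError, match="level"):
            predict_interval(m, np.zeros(4), level=1.5)
        with pytest.raises(ValueError):
            predict_interval(m, np.zeros(3), level=0.95)

    def test_one_sided_bound_is_level_quantile(self):
        rng = np.random.default_rng(10)
        table = random_table(rng)
        m = fit_ols(table)
        x0 = rng.normal(size=4)
        # one-sided 95% bound == upper of the central 90% interval
        assert error_bound(m, x0, level=0.95, kind="one_sided") == pytest.approx(
            predict_interval(m, x0, level=0.90).upper, abs=1e-12
        )
        assert error_bound(m, x0, level=0.95, kind="two_sided_upper") == pytest.approx(
            predict_interval(m, x0, level=0.95).upper, abs=1e-12
        )


def exhaustive_best_bic(table, blocks, max_size):
    """Independent oracle: enumerate every block subset, min BIC."""
    names = sorted(blocks)
    best = (math.inf, ())
    for k in range(0, max_size + 1):
        for combo in itertools.combinations(names, k):
            cols = [c for b in combo for c in blocks[b]]
            try:
                m = fit_ols(table, cols)
                value = bic(m)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if value < best[0] - 1e-10:
                best = (value, combo)
    return best


class TestSubsetSelection:
    def test_branch_and_bound_equals_exhaustive(self):
        rng = np.random.default_rng(2024)
        for _ in range(8):
            n, p = 60, int(rng.integers(4, 9))
            X = rng.normal(size=(n, p))
            beta = np.where(rng.random(p) < 0.4, rng.normal(size=p), 0.0)
            y = 0.5 + X @ beta + rng.normal(size=n)
            table = make_table(X, y)
            res = best_subset_select(table, max_size=p)
            oracle_bic, oracle_set = exhaustive_best_bic(table, table.blocks, p)
            assert set(res.chosen_blocks) == set(oracle_set)
            assert bic(res.model) == pytest.approx(oracle_bic, abs=1e-8)

    def test_grouped_block_all_in_or_out(self):
        rng = np.random.default_rng(12)
        n = 80
        X = rng.normal(size=(n, 4))
        y = 1 + 2 * X[:, 0] + 0.5 * X[:, 2] + 0.5 * X[:, 3] + rng.normal(size=n)
        table = make_table(X, y)
        blocks = {"x0": ["x0"], "x1": ["x1"], "grp": ["x2", "x3"]}
        res = best_subset_select(table, blocks=blocks, max_size=3)
        chosen_cols = [c for b in res.chosen_blocks for c in blocks[b]]
        assert ("x2" in chosen_cols) == ("x3" in chosen_cols)

    def test_max_size_zero_returns_intercept_only(self, table5):
        res = best_subset_select(table5, max_size=0)
        assert res.chosen_blocks == ()
        assert res.model.predictor_names == []

    def test_recovers_true_predictor_among_noise(self):
        # 1 real predictor + 9 pure noise at n = 500: the signal must always
        # be found; BIC admits the best of 9 spurious predictors with
        # probability ~ 9 * P(chi2_1 > ln 500) ~ 11%, so exact recovery is
        # expected in ~89% of replicates.
        rng = np.random.default_rng(77)
        exact = 0
        reps = 40
        for _ in range(reps):
            n = 500
            X = rng.normal(size=(n, 10))
            y = 1.0 + 2.0 * X[:, 0] + rng.normal(size=n)
            res = best_subset_select(make_table(X, y), max_size=10)
            assert "x0" in res.chosen_blocks
            exact += res.chosen_blocks == ("x0",)
        assert exact >= int(0.80 * reps)

    def test_stepwise_agrees_on_orthogonal_design(self):
        rng = np.random.default_rng(31)
        n, p = 64, 6
        # orthogonalized design
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        y = 0.3 + 1.5 * Q[:, 1] - 2.0 * Q[:, 4] + 0.2 * rng.normal(size=n)
        table = make_table(Q, y)
        assert set(stepwise_select(table).chosen_blocks) == set(
            best_subset_select(table, max_size=p).chosen_blocks
        )

    def test_stepwise_deterministic_and_stops_at_optimum(self):
        rng = np.random.default_rng(15)
        table = random_table(rng, n=100, p=5)
        r1 = stepwise_select(table)
        r2 = stepwise_select(table)
        assert r1.chosen_blocks == r2.chosen_blocks
        assert [t[1] for t in r1.trace] == [t[1] for t in r2.trace]
        # restart from the already-chosen subset: no further move improves
        sub = PredictorTable(
            df=table.df,
            predictors=list(r1.chosen_blocks),
            blocks={b: [b] for b in r1.chosen_blocks},
            pool=table.pool,
        )
        again = stepwise_select(sub, start="full")
        assert again.n_steps == 0


class TestEffectOnIntervalWidth:
    def test_matches_hand_computed_contrast(self):
        rng = np.random.default_rng(21)
        n = 120
        X = rng.normal(loc=[1.0, -0.5, 2.0], scale=[1.0, 2.0, 0.5], size=(n, 3))
        y = 0.5 + X @ np.array([1.0, 0.3, -0.7]) + rng.normal(size=n)
        table = make_table(X, y)
        m = fit_ols(table)
        got = effect_on_interval_width(m, table, "x1", quantile=0.10)
        # oracle: direct application of the contrast definition
        vals = X[:, 1]
        hi = vals[vals >= np.quantile(vals, 0.90)].mean()
        lo = vals[vals <= np.quantile(vals, 0.10)].mean()
        base = {f"x{j}": X[:, j].mean() for j in range(3)}
        b_hi = error_bound(m, dict(base, x1=hi), level=0.95)
        b_lo = error_bound(m, dict(base, x1=lo), level=0.95)
        assert got == pytest.approx(b_hi - b_lo, abs=1e-12)
        # and the sign follows the coefficient's
        assert math.copysign(1, got) == math.copysign(1, m.coef["x1"])

    def test_binary_contrast_is_one_vs_zero(self):
        rng = np.random.default_rng(22)
        n = 100
        flag = (rng.random(n) < 0.3).astype(float)
        x = rng.normal(size=n)
        y = 0.2 + 0.8 * flag + 0.5 * x + rng.normal(size=n)
        table = make_table(np.column_stack([flag, x]), y, names=["flag", "x"])
        m = fit_ols(table)
        got = effect_on_interval_width(m, table, "flag")
        base = {"flag": flag.mean(), "x": x.mean()}
        expect = error_bound(m, dict(base, flag=1.0)) - error_bound(m, dict(base, flag=0.0))
        assert got == pytest.approx(expect, abs=1e-12)

    def test_constant_predictor(self):
        rng = np.random.default_rng(23)
        n = 50
        X = np.column_stack([np.full(n, 2.0), rng.normal(size=n)])
        y = 1 + X[:, 1] + rng.normal(size=n)
        table = make_table(X, y)
        m = fit_ols(table, predictors=["x1"])
        # x0 constant: aliased in a fit, and a zero/error contrast
        with pytest.raises(ValueError, match="not in the fitted model"):
            effect_on_interval_width(m, table, "x0")
        m2 = fit_ols(table)  # x0 aliased with intercept -> dropped
        assert "x0" in m2.dropped
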