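import numpy as np
import pandas as pd
import pytest

import bedbench as bb
from bedbench.cmh_index import build_composite
from bedbench.exceptions import (
    SingularDesignError,
    UndefinedStatisticError,
    ValidationError,
)
from bedbench.regression import (
    TERMS,
    build_design,
    design_row,
    fit_statistics,
    fit_wls,
    population_weights,
    predict_with_se,
)


def normal_equations(X, y, w=None):
    """Brute-force WLS oracle: solve (X'WX) B = X'Wy directly."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=float)
    XtW = X.T * w
    return np.linalg.solve(XtW @ X, XtW @ y)


def random_instance(rng, n):
    """A random full-rank 8-column design with intercept, plus outcome/weights."""
    X = np.column_stack(
        [
            np.ones(n),
            rng.normal(0.05, 0.01, n),
            rng.normal(0.003, 0.001, n),
            rng.normal(0, 1, n),
            rng.normal(1, 0.5, n),
            rng.normal(0, 2, n),
            rng.normal(38, 3, n),
            rng.normal(79, 2, n),
        ]
    )
    y = rng.normal(0.03, 0.01, n)
    w = rng.uniform(0.1, 10.0, n)
    return pd.DataFrame(X, columns=list(TERMS)), pd.Series(y), w


class TestBuildDesign:
    def test_polynomial_terms_are_exact_powers(self, synthetic_table):
        comp = build_composite(synthetic_table)
        X, y = build_design(synthetic_table, comp)
        assert np.allclose(X["cmh_sq"], X["cmh"] ** 2)
        assert np.allclose(X["cmh_cu"], X["cmh"] ** 3)
        assert np.allclose(X["disability_sq"], X["disability"] ** 2)
        assert (X["const"] == 1).all()

    def test_design_row_example(self):
        row = design_row(0.0, 2.0, 38.0, 79.0)
        assert row["cmh_sq"] == 4.0
        assert row["cmh_cu"] == 8.0
        assert row["disability_sq"] == 0.0

    def test_elementwise_recomputation_oracle(self, synthetic_table):
        """Each matrix cell equals an independent per-element recomputation."""
        comp = build_composite(synthetic_table)
        X, y = build_design(synthetic_table, comp)
        frame = synthetic_table.to_frame()
        c = comp.index.to_numpy()
        for i, row in frame.iterrows():
            expected = [
                1.0,
                row.disability_pct,
                row.disability_pct**2,
                c[i],
                c[i] ** 2,
                c[i] ** 3,
                row.married_pct,
                row.life_expectancy,
            ]
            assert np.allclose(X.iloc[i].to_numpy(), expected)
            assert y.iloc[i] == pytest.approx(1.0 / row.bed_rate, rel=1e-15)


class TestFitWls:
    def test_noiseless_recovery(self, rng):
        """y generated exactly from known B is recovered to 1e-8."""
        X, _, _ = random_instance(rng, 20)
        b_true = rng.normal(size=8)
        y = X.to_numpy() @ b_true
        fm = fit_wls(X, pd.Series(y))
        assert np.allclose(fm.params.to_numpy(), b_true, atol=1e-8)
        assert fm.scale == pytest.approx(0.0, abs=1e-16)

    def test_equal_weights_match_ols_oracle(self, rng):
        X, y, _ = random_instance(rng, 40)
        fm = fit_wls(X, y, weights=np.ones(40))
        expected = normal_equations(X, y)
        assert np.allclose(fm.params.to_numpy(), expected, atol=1e-10)

    def test_weight_scale_invariance(self, rng):
        X, y, w = random_instance(rng, 30)
        fm1 = fit_wls(X, y, weights=w)
        fm2 = fit_wls(X, y, weights=2.0 * w)
        assert np.allclose(fm1.params.to_numpy(), fm2.params.to_numpy(), rtol=1e-12)
        assert fm1.scale == pytest.approx(fm2.scale, rel=1e-12)

    def test_oracle_equivalence_on_random_instances(self, rng):
        """WLS matches the normal-equations oracle to 1e-8 relative error."""
        for _ in range(20):
            n = int(rng.integers(12, 101))
            X, y, w = random_instance(rng, n)
            fm = fit_wls(X, y, weights=w)
            expected = normal_equations(X, y, w)
            rel = np.linalg.norm(fm.params.to_numpy() - expected) / np.linalg.norm(expected)
            assert rel < 1e-8

    def test_weighted_residual_mean_zero(self, rng):
        X, y, w = random_instance(rng, 50)
        fm = fit_wls(X, y, weights=w)
        assert abs(np.sum(fm.weights * fm.resid.to_numpy())) < 1e-10

    def test_rank_deficiency_names_columns(self, rng):
        X, y, w = random_instance(rng, 30)
        X["cmh_sq"] = 2.0 * X["cmh"]
        with pytest.raises(SingularDesignError) as exc:
            fit_wls(X, y, weights=w)
        assert "cmh" in str(exc.value)

    def test_too_few_units_rejected(self, rng):
        X, y, _ = random_instance(rng, 8)
        with pytest.raises(ValidationError):
            fit_wls(X, y)


class TestFitStatistics:
    def test_perfect_fit(self, rng):
        X, _, _ = random_instance(rng, 20)
        y = X.to_numpy() @ rng.normal(size=8)
        fm = fit_wls(X, pd.Series(y))
        assert fm.rsquared == pytest.approx(1.0, abs=1e-10)
        assert fm.rsquared_adj == pytest.approx(1.0, abs=1e-10)
        assert np.isinf(fm.fvalue)

    def test_constant_outcome_undefined(self, rng):
        X, _, _ = random_instance(rng, 20)
        with pytest.raises(UndefinedStatisticError):
            fit_wls(X, pd.Series(np.full(20, 0.04)))

    def test_sums_of_squares_oracle(self, rng):
        """R^2 / adjusted R^2 / F agree with direct RSS/TSS computation."""
        X, y, w = random_instance(rng, 60)
        fm = fit_wls(X, y, weights=w)
        wn = w * (60 / w.sum())
        b = normal_equations(X, y, w)
        resid = y.to_numpy() - X.to_numpy() @ b
        rss = np.sum(wn * resid**2)
        ybar = np.sum(wn * y.to_numpy()) / wn.sum()
        tss = np.sum(wn * (y.to_numpy() - ybar) ** 2)
        r2 = 1 - rss / tss
        assert fm.rsquared == pytest.approx(r2, abs=1e-10)
        assert fm.rsquared_adj == pytest.approx(1 - (1 - r2) * 59 / 52, abs=1e-10)
        f = (r2 / 7) / ((1 - r2) / 52)
        assert fm.fvalue == pytest.approx(f, rel=1e-10)
        assert fm.rsquared_adj <= fm.rsquared
        assert fm.df_resid == 52

    def test_adjusted_never_exceeds_raw(self, rng):
        X, y, w = random_instance(rng, 25)
        fm = fit_wls(X, y, weights=w)
        assert fm.rsquared_adj <= fm.rsquared


class TestPredictWithSe:
    def test_se_at_centroid_equal_weights(self, rng):
        """At the design centroid with equal weights, SE(mean) = s / sqrt(n)."""
        X, y, _ = random_instance(rng, 50)
        fm = fit_wls(X, y)
        centroid = X.mean(axis=0)
        _, se = predict_with_se(fm, centroid)
        assert se == pytest.approx(np.sqrt(fm.scale / 50), abs=1e-8)

    def test_fitted_value_matches_matrix_multiply(self, rng):
        X, y, w = random_instance(rng, 40)
        fm = fit_wls(X, y, weights=w)
        x0 = X.iloc[7]
        fitted, _ = predict_with_se(fm, x0)
        assert fitted == pytest.approx(float(x0.to_numpy() @ fm.params.to_numpy()), rel=1e-12)

    def test_zero_noise_gives_zero_se(self, rng):
        X, _, _ = random_instance(rng, 20)
        y = X.to_numpy() @ rng.normal(size=8)
        fm = fit_wls(X, pd.Series(y))
        _, se = predict_with_se(fm, X.iloc[0])
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_prediction_interval_wider_than_confidence(self, rng):
        X, y, w = random_instance(rng, 30)
        fm = fit_wls(X, y, weights=w)
        _, se_c = predict_with_se(fm, X.iloc[3], interval="confidence")
        _, se_p = predict_with_se(fm, X.iloc[3], interval="prediction")
        assert se_p > se_c

    def test_leverage_minimized_near_weighted_centroid(self, rng):
        """SE at the weighted centroid is below SE at every training row."""
        X, y, w = random_instance(rng, 50)
        fm = fit_wls(X, y, weights=w)
        wn = fm.weights
        centroid = pd.Series(
            (X.to_numpy() * wn[:, None]).sum(axis=0) / wn.sum(), index=X.columns
        )
        _, se_c = predict_with_se(fm, centroid)
        ses = [predict_with_se(fm, X.iloc[i])[1] for i in range(50)]
        assert se_c <= min(ses) + 1e-12


def test_population_weights_sum_to_n():
    w = population_weights([1e6, 3e6, 6e6])
    assert w.sum() == pytest.approx(3.0)
    assert np.allclose(w, [0.3, 0.9, 1.8])
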