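"""Extension regression: OLS against a normal-equations oracle, bands, flags."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riverhealth.extension import (
    PUBLISHED_MODEL,
    QUALIFIERS,
    RegressionDataset,
    band_and_flag,
    fit_extension_model,
    predict_bmwp,
)
from riverhealth.simulate import GradientScenario, generate_regression_table


def make_dataset(rng, n, cols=("N_total", "NO2"), noise_sd=0.0):
    predictors = pd.DataFrame(
        {c: rng.uniform(0.1, 10 if c != "NO2" else 0.3, n) for c in cols}
    )
    obs = np.full(n, PUBLISHED_MODEL.intercept)
    for name, coef in PUBLISHED_MODEL.coefficients.items():
        if name in cols:
            obs = obs + coef * predictors[name].to_numpy()
    if noise_sd:
        obs = obs + rng.normal(0, noise_sd, n)
    return RegressionDataset(
        tuple(f"s{i}" for i in range(n)), np.maximum(obs, 0), predictors
    )


# -- prediction --------------------------------------------------------------


@pytest.mark.parametrize(
    "predictors,expected",
    [
        ({"N_total": 0.0, "NO2": 0.0}, 92.697),
        ({"N_total": 1.0, "NO2": 0.0}, 86.715),
        ({"N_total": 0.0, "NO2": 0.1}, 118.7604),
    ],
)
def test_published_equation_evaluation(predictors, expected):
    assert predict_bmwp(PUBLISHED_MODEL, predictors) == pytest.approx(expected)


def test_predict_is_affine():
    rng = np.random.default_rng(11)
    x1 = {"N_total": rng.uniform(0, 10), "NO2": rng.uniform(0, 0.3)}
    x2 = {"N_total": rng.uniform(0, 10), "NO2": rng.uniform(0, 0.3)}
    for a in (0.0, 0.25, 0.7, 1.0):
        mix = {k: a * x1[k] + (1 - a) * x2[k] for k in x1}
        assert predict_bmwp(PUBLISHED_MODEL, mix) == pytest.approx(
            a * predict_bmwp(PUBLISHED_MODEL, x1)
            + (1 - a) * predict_bmwp(PUBLISHED_MODEL, x2)
        )


def test_predict_missing_variable_errors():
    with pytest.raises(KeyError, match="NO2"):
        predict_bmwp(PUBLISHED_MODEL, {"N_total": 1.0})


# -- fitting -----------------------------------------------------------------


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ols_matches_normal_equations_oracle(seed):
    """Coefficients agree with (X'X)^-1 X'y computed independently."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 21))
    data = make_dataset(rng, n, cols=("N_total", "NO2", "pH"), noise_sd=5.0)
    fitted = fit_extension_model(data, selection="none")
    X = np.column_stack(
        [np.ones(n)] + [data.predictors[c] for c in data.predictors.columns]
    )
    beta = np.linalg.solve(X.T @ X, X.T @ data.bmwp_obs)
    assert fitted.intercept == pytest.approx(beta[0], rel=1e-8)
    for j, c in enumerate(data.predictors.columns):
        assert fitted.coefficients[c] == pytest.approx(beta[j + 1], rel=1e-8)


def test_noiseless_recovery_of_published_coefficients():
    data = generate_regression_table(GradientScenario(n_sites=12, seed=5))
    fitted = fit_extension_model(data, selection="backward")
    assert set(fitted.selected_variables) == {"N_total", "NO2"}
    assert fitted.intercept == pytest.approx(92.697, rel=1e-6)
    assert fitted.coefficients["N_total"] == pytest.approx(-5.982, rel=1e-6)
    assert fitted.coefficients["NO2"] == pytest.approx(260.634, rel=1e-6)
    assert fitted.r_squared == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("seed", [3, 4, 5])
def test_noisy_estimates_converge_at_large_n(seed):
    data = generate_regression_table(
        GradientScenario(n_sites=1000, seed=seed), noise_sd=10.0
    )
    fitted = fit_extension_model(
        data, selection="none", variables=["N_total", "NO2"]
    )
    assert fitted.coefficients["N_total"] == pytest.approx(-5.982, abs=0.5)
    assert fitted.coefficients["NO2"] == pytest.approx(260.634, rel=0.05)


def test_constant_response_gives_zero_r_squared():
    predictors = pd.DataFrame({"pH": np.linspace(6, 9, 8)})
    data = RegressionDataset(
        tuple(f"s{i}" for i in range(8)), np.full(8, 50.0), predictors
    )
    fitted = fit_extension_model(data, selection="none")
    assert fitted.r_squared == 0.0
    assert fitted.coefficients["pH"] == pytest.approx(0.0, abs=1e-10)


def test_too_few_rows_errors():
    rng = np.random.default_rng(0)
    data = make_dataset(rng, 3, cols=tuple(QUALIFIERS))
    with pytest.raises(ValueError, match="rows"):
        fit_extension_model(data, selection="backward")


def test_collinear_predictors_error():
    rng = np.random.default_rng(1)
    no3 = rng.uniform(1, 10, 10)
    predictors = pd.DataFrame({"NO3": no3, "N_total": 2.0 * no3})
    data = RegressionDataset(
        tuple(f"s{i}" for i in range(10)), rng.uniform(20, 100, 10), predictors
    )
    with pytest.raises(ValueError, match="rank deficient"):
        fit_extension_model(data, selection="none")


def test_unknown_qualifier_rejected():
    with pytest.raises(ValueError, match="unknown qualifier"):
        RegressionDataset(
            ("a", "b"), np.array([1.0, 2.0]),
            pd.DataFrame({"turbidity": [1.0, 2.0]}),
        )


# -- band and flag -----------------------------------------------------------


def _closed_form_confidence_band(obs, calc, level):
    """Textbook mean-response band from the normal equations (oracle)."""
    n = len(obs)
    X = np.column_stack([np.ones(n), obs])
    beta = np.linalg.solve(X.T @ X, X.T @ calc)
    fitted = X @ beta
    s2 = ((calc - fitted) ** 2).sum() / (n - 2)
    xtx_inv = np.linalg.inv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    half = stats.t.ppf(0.5 + level / 2, n - 2) * np.sqrt(s2 * h)
    return fitted - half, fitted + half


def test_band_matches_closed_form_oracle_and_flags_displaced_point():
    rng = np.random.default_rng(9)
    obs = np.linspace(10, 120, 10)
    calc = 5.0 + 0.9 * obs + rng.normal(0, 2.0, 10)
    obs = np.append(obs, 65.0)
    calc = np.append(calc, 5.0 + 0.9 * 65.0 + 150.0)  # far beyond any band
    verdict = band_and_flag(list(zip(obs, calc)), level=0.95, band="confidence")
    lower, upper = _closed_form_confidence_band(obs, calc, 0.95)
    assert np.allclose(verdict.lower, lower, rtol=1e-10)
    assert np.allclose(verdict.upper, upper, rtol=1e-10)
    assert verdict.outside_sites == ("site_10",)


def test_point_on_fitted_line_is_inside():
    rng = np.random.default_rng(2)
    obs = np.linspace(0, 100, 12)
    calc = 10 + 0.8 * obs + rng.normal(0, 4, 12)
    verdict = band_and_flag(list(zip(obs, calc)))
    X = np.column_stack([np.ones(12), obs])
    beta = np.linalg.solve(X.T @ X, X.T @ calc)
    on_line = float(beta[0] + beta[1] * 50.0)
    v2 = band_and_flag(list(zip(obs, calc))[:-1] + [(50.0, on_line)])
    assert bool(v2.inside_band[-1]) is True
    assert verdict.band == "confidence" and verdict.level == 0.95


def test_band_level_and_type_monotonicity():
    rng = np.random.default_rng(4)
    obs = np.linspace(5, 95, 15)
    calc = 20 + 0.7 * obs + rng.normal(0, 5, 15)
    pairs = list(zip(obs, calc))
    narrow = band_and_flag(pairs, level=0.5)
    wide = band_and_flag(pairs, level=0.95)
    pred = band_and_flag(pairs, level=0.95, band="prediction")
    assert np.all(wide.upper - wide.lower >= narrow.upper - narrow.lower)
    assert np.all(pred.upper - pred.lower >= wide.upper - wide.lower)


@pytest.mark.parametrize(
    "pairs,msg",
    [
        ([(1, 1), (2, 2)], "at least 3"),
        ([(5, 1), (5, 2), (5, 3)], "zero variance"),
    ],
)
def test_band_input_contracts(pairs, msg):
    with pytest.raises(ValueError, match=msg):
        band_and_flag(pairs)
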