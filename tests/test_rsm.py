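"""Quadratic response-surface fitting, ANOVA, reduction, prediction."""

import numpy as np
import pandas as pd
import pytest

import chitopt as c
from chitopt.rsm import design_matrix, format_term, full_quadratic_terms, parse_term


def make_table(coded: np.ndarray, y: np.ndarray, name: str = "y") -> pd.DataFrame:
    df = pd.DataFrame(coded, columns=[f"x{i+1}" for i in range(coded.shape[1])])
    df[name] = y
    return df


# --- term algebra ----------------------------------------------------------


@pytest.mark.parametrize(
    "s,expected",
    [
        ("1", (0, 0, 0)),
        ("x1", (1, 0, 0)),
        ("x1:x3", (1, 0, 1)),
        ("x2^2", (0, 2, 0)),
    ],
)
def test_term_parse_format_round_trip(s, expected):
    t = parse_term(s, 3)
    assert t == expected
    assert parse_term(format_term(t), 3) == t


def test_full_quadratic_term_count():
    # 1 + k + k(k-1)/2 + k terms
    for k in (1, 2, 3, 4):
        assert len(full_quadratic_terms(k)) == 1 + 2 * k + k * (k - 1) // 2


def test_cubic_term_rejected():
    with pytest.raises(ValueError):
        parse_term("x1^3", 3)


# --- design matrix ---------------------------------------------------------


def test_design_matrix_entries(table2):
    coded = table2[["x1", "x2", "x3"]].to_numpy()
    X = design_matrix(coded, [(0, 0, 0), (1, 0, 1), (2, 0, 0)])
    assert (X[:, 0] == 1).all()  # intercept
    # run (1, -1, 1): x1*x3 = 1; centre runs: any degree>=1 term is 0
    i = np.flatnonzero((coded == [1, -1, 1]).all(axis=1))[0]
    assert X[i, 1] == 1.0
    centre = (coded == 0).all(axis=1)
    assert (X[centre, 1:] == 0).all()
    # axial run (1.68, 0, 0): x1^2 = 2.8224
    j = np.flatnonzero((coded == [1.68, 0, 0]).all(axis=1))[0]
    assert X[j, 2] == pytest.approx(2.8224)


def test_duplicate_terms_rejected(table2):
    coded = table2[["x1", "x2", "x3"]].to_numpy()
    with pytest.raises(ValueError, match="duplicate"):
        design_matrix(coded, [(0, 0, 0), (1, 0, 0), (1, 0, 0)])


# --- OLS fitting -----------------------------------------------------------


def test_noiseless_linear_fit_is_exact():
    rng = np.random.default_rng(7)
    coded = rng.uniform(-1.68, 1.68, size=(12, 1))
    y = 2.0 + 3.0 * coded[:, 0]
    fit = c.fit_ols(make_table(coded, y), "y", ["1", "x1"])
    np.testing.assert_allclose(fit.model.coefficients, [2.0, 3.0], rtol=1e-10)
    assert fit.r_squared == pytest.approx(1.0)
    np.testing.assert_allclose(fit.se, 0.0, atol=1e-7)


def test_normal_equations_oracle(table2):
    """statsmodels-backed estimates match a direct normal-equations solve."""
    fit = c.fit_ols(table2, "mm_kda")
    coded = table2[["x1", "x2", "x3"]].to_numpy()
    X = design_matrix(coded, list(fit.model.terms))
    y = table2["mm_kda"].to_numpy()
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    np.testing.assert_allclose(fit.model.coefficients, beta, rtol=1e-8)
    resid = y - X @ beta
    s2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(s2 * np.diag(np.linalg.inv(XtX)))
    np.testing.assert_allclose(fit.se, se, rtol=1e-8)


def test_residuals_orthogonal_to_design_columns(table2):
    for resp in ("dd_pct", "mm_kda"):
        fit = c.fit_ols(table2, resp)
        coded = table2[["x1", "x2", "x3"]].to_numpy()
        X = design_matrix(coded, list(fit.model.terms))
        np.testing.assert_allclose(X.T @ np.array(fit.residuals), 0, atol=1e-7)


def test_rank_deficiency_reported():
    coded = np.array([[1.0, 1.0], [-1.0, -1.0], [0.5, 0.5], [0.0, 0.0], [2.0, 2.0]])
    y = np.arange(5.0)
    with pytest.raises(ValueError, match="rank deficient"):
        c.fit_ols(make_table(coded, y), "y", ["1", "x1", "x2"])


# --- reduction -------------------------------------------------------------


def test_reduce_keep_all_is_identity(table2, dd_full):
    again = c.reduce_and_refit(table2, dd_full, list(dd_full.model.terms))
    np.testing.assert_allclose(again.model.coefficients, dd_full.model.coefficients)
    assert again.r_squared == pytest.approx(dd_full.r_squared)


def test_reduced_r2_never_exceeds_superset(table2, dd_full, dd_reduced):
    assert dd_reduced.r_squared <= dd_full.r_squared + 1e-12


def test_reduction_requires_intercept_and_subset(table2, dd_full):
    with pytest.raises(ValueError, match="intercept"):
        c.reduce_and_refit(table2, dd_full, ["x1", "x3"])
    with pytest.raises(ValueError, match="empty"):
        c.reduce_and_refit(table2, dd_full, [])


def test_dropping_orthogonal_terms_preserves_estimates():
    """On a CCD, removing linear/interaction terms leaves retained linear and
    interaction coefficients unchanged (column orthogonality)."""
    spec = c.deacetylation_design()
    truth = c.published_mm_model()
    table = c.simulate_responses(c.SyntheticConfig((truth,), (50.0,), spec, seed=11))
    full = c.fit_ols(table, "mm_kda")
    red = c.reduce_and_refit(table, full, ["1", "x1", "x3", "x1:x3", "x1^2", "x2^2", "x3^2"])
    # dropped: x2, x1:x2, x2:x3 — all orthogonal to every retained non-intercept term
    for term in ("x1", "x3", "x1:x3"):
        assert red.coef(term) == pytest.approx(full.coef(term), rel=1e-10)


def test_pvalue_screening(dd_full):
    keep = c.reduction_by_pvalue(dd_full, 0.05, protect=("x2",))
    assert set(keep) == {"1", "x1", "x2", "x3", "x1^2"}
    assert set(c.reduction_by_pvalue(dd_full, 1.0)) == set(dd_full.model.term_strings())
    assert set(c.reduction_by_pvalue(dd_full, 0.0, protect=("x2",))) == {"1", "x2"}


# --- prediction ------------------------------------------------------------


def test_predict_intercept_at_origin(dd_reduced):
    assert dd_reduced.model.predict([0, 0, 0]) == pytest.approx(
        dd_reduced.coef("1")
    )


def test_predict_matches_manual_polynomial():
    model = c.QuadraticModel(
        terms=((0, 0), (1, 0), (0, 1), (1, 1), (2, 0), (0, 2)),
        coefficients=(1.0, 2.0, -3.0, 0.5, -1.5, 0.25),
    )
    x = (0.7, -1.2)
    manual = 1 + 2 * 0.7 - 3 * -1.2 + 0.5 * 0.7 * -1.2 - 1.5 * 0.7**2 + 0.25 * 1.2**2
    assert model.predict(x) == pytest.approx(manual, rel=1e-14)
    # vectorized path agrees with scalar path
    pts = np.array([[0.7, -1.2], [0.0, 0.0]])
    np.testing.assert_allclose(model.predict(pts), [manual, 1.0], rtol=1e-14)


def test_predict_dimension_mismatch(dd_reduced):
    with pytest.raises(ValueError):
        dd_reduced.model.predict([0.0, 0.0])


def test_model_json_round_trip(mm_reduced):
    model = mm_reduced.model
    again = c.QuadraticModel.from_dict(model.to_dict())
    assert again.terms == model.terms
    np.testing.assert_allclose(again.coefficients, model.coefficients)
    assert again.response == model.response
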