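"""Second-order response-surface models: fitting, ANOVA, reduction, prediction.

The working model is the full quadratic in k coded factors,

    y = b0 + sum_i bi*xi + sum_{i<j} bij*xi*xj + sum_i bii*xi^2,

fit by ordinary least squares to a designed-experiment table.  On an
orthogonal central composite design the linear and interaction columns are
mutually orthogonal, so dropping insignificant linear/interaction terms and
refitting leaves the retained estimates unchanged — the property that makes
judgment-based model reduction cheap on a CCD.

Terms are represented as exponent tuples over the factors: ``(0,0,0)`` is
the intercept, ``(1,0,0)`` is x1, ``(1,0,1)`` is x1*x3, ``(2,0,0)`` is x1^2.
The string syntax ``"1"``, ``"x1"``, ``"x1:x3"``, ``"x1^2"`` round-trips
through :func:`parse_term` / :func:`format_term`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "Term",
    "QuadraticModel",
    "FitResult",
    "full_quadratic_terms",
    "parse_term",
    "format_term",
    "design_matrix",
    "fit_ols",
    "reduce_and_refit",
    "reduction_by_pvalue",
]

Term = tuple[int, ...]

#: the keep-list reproducing the published reduced DD model
DD_KEEP = ("1", "x1", "x2", "x3", "x1:x3", "x1^2", "x3^2")
#: the keep-list reproducing the published reduced MM model
MM_KEEP = ("1", "x1", "x3", "x1:x3", "x1^2", "x2^2", "x3^2")


def full_quadratic_terms(k: int) -> list[Term]:
    """All terms of the full second-order model for k factors, canonical order:
    intercept, linear, interactions (lexicographic), pure quadratics."""
    terms: list[Term] = [tuple([0] * k)]
    for i in range(k):
        e = [0] * k
        e[i] = 1
        terms.append(tuple(e))
    for i in range(k):
        for j in range(i + 1, k):
            e = [0] * k
            e[i] = e[j] = 1
            terms.append(tuple(e))
    for i in range(k):
        e = [0] * k
        e[i] = 2
        terms.append(tuple(e))
    return terms


def _validate_term(t: Term) -> Term:
    t = tuple(int(e) for e in t)
    if any(e < 0 for e in t) or sum(t) > 2:
        raise ValueError(f"term exponents must be nonnegative with total degree <= 2: {t}")
    return t


def parse_term(s: str, k: int) -> Term:
    """Parse ``"1"``, ``"x2"``, ``"x1:x3"`` or ``"x2^2"`` into an exponent tuple."""
    s = s.strip()
    e = [0] * k
    if s == "1":
        return tuple(e)
    for part in s.split(":"):
        part = part.strip()
        if "^" in part:
            base, _, power = part.partition("^")
            p = int(power)
        else:
            base, p = part, 1
        if not base.startswith("x"):
            raise ValueError(f"cannot parse term {s!r}")
        i = int(base[1:]) - 1
        if not 0 <= i < k:
            raise ValueError(f"factor {base} out of range for k={k}")
        e[i] += p
    return _validate_term(tuple(e))


def format_term(t: Term) -> str:
    if sum(t) == 0:
        return "1"
    parts = []
    for i, e in enumerate(t):
        if e == 1:
            parts.append(f"x{i + 1}")
        elif e >= 2:
            parts.append(f"x{i + 1}^{e}")
    return ":".join(parts)


@dataclass(frozen=True)
class QuadraticModel:
    """An ordered set of terms with one coefficient each.

    response: name of the modelled response (e.g. ``"dd_pct"``);
    units: its unit string (``"%"`` or ``"kDa"``).
    """

    terms: tuple[Term, ...]
    coefficients: tuple[float, ...]
    response: str = "y"
    units: str = ""

    def __post_init__(self) -> None:
        terms = tuple(_validate_term(t) for t in self.terms)
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate terms in model")
        if len(terms) != len(self.coefficients):
            raise ValueError("terms and coefficients length mismatch")
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    @property
    def k(self) -> int:
        return len(self.terms[0])

    def predict(self, coded_point) -> float | np.ndarray:
        """Evaluate the polynomial at one coded point or an (n, k) array."""
        x = np.atleast_2d(np.asarray(coded_point, dtype=float))
        if x.shape[1] != self.k:
            raise ValueError(
                f"point has {x.shape[1]} coordinates, model has {self.k} factors"
            )
        # accumulate coef * prod(x_i^e_i) term by term; cheap even on large grids
        vals = np.zeros(len(x))
        for term, coef in zip(self.terms, self.coefficients):
            col = np.full(len(x), coef)
            for i, e in enumerate(term):
                for _ in range(e):
                    col *= x[:, i]
            vals += col
        return float(vals[0]) if np.ndim(coded_point) <= 1 else vals

    def term_strings(self) -> list[str]:
        return [format_term(t) for t in self.terms]

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "units": self.units,
            "terms": self.term_strings(),
            "coefficients": list(self.coefficients),
            "k": self.k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticModel":
        k = int(d["k"])
        return cls(
            terms=tuple(parse_term(s, k) for s in d["terms"]),
            coefficients=tuple(d["coefficients"]),
            response=d.get("response", "y"),
            units=d.get("units", ""),
        )


def predict(model: QuadraticModel, coded_point):
    """Functional alias for :meth:`QuadraticModel.predict`."""
    return model.predict(coded_point)


def design_matrix(coded: np.ndarray | pd.DataFrame, terms: list[Term]) -> np.ndarray:
    """Model matrix with one column per term: entry (i, j) is run i's coded
    values raised to term j's exponents and multiplied out."""
    terms = [_validate_term(t) for t in terms]
    if len(set(terms)) != len(terms):
        raise ValueError("duplicate terms in term list")
    X = np.asarray(coded, dtype=float)
    if X.ndim != 2:
        raise ValueError("coded values must be a 2-D array (runs x factors)")
    exps = np.array(terms)
    if exps.shape[1] != X.shape[1]:
        raise ValueError("term factor count does not match the table")
    return np.prod(X[:, None, :] ** exps[None, :, :], axis=2)


@dataclass(frozen=True)
class FitResult:
    """OLS fit of a quadratic model with the usual ANOVA companions."""

    model: QuadraticModel
    se: tuple[float, ...]
    t_values: tuple[float, ...]
    p_values: tuple[float, ...]
    df_residual: int
    r_squared: float
    f_statistic: float
    f_pvalue: float
    residuals: tuple[float, ...]
    coded: np.ndarray = field(repr=False, compare=False, default=None)

    def anova_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.model.term_strings(),
                "coefficient": self.model.coefficients,
                "se": self.se,
                "t": self.t_values,
                "p": self.p_values,
            }
        )

    def coef(self, term: str) -> float:
        return self.model.coefficients[self.model.term_strings().index(term)]

    def pvalue(self, term: str) -> float:
        return self.p_values[self.model.term_strings().index(term)]


def _coded_matrix(table: pd.DataFrame, k: int | None = None) -> np.ndarray:
    cols = [c for c in table.columns if c.startswith("x") and c[1:].isdigit()]
    cols = sorted(cols, key=lambda c: int(c[1:]))
    if k is not None:
        cols = cols[:k]
    if not cols:
        raise ValueError("table has no coded factor columns x1..xk")
    block = table[cols]
    if block.isna().any().any():
        raise ValueError("missing coded values in the experiment table")
    return block.to_numpy(dtype=float)


def fit_ols(
    table: pd.DataFrame,
    response: str,
    terms: list[Term] | list[str] | None = None,
    units: str = "",
) -> FitResult:
    """Fit a quadratic model to one response of an experiment table by OLS.

    ``terms`` defaults to the full second-order model; strings like
    ``"x1:x3"`` are accepted.  Raises on rank deficiency, naming the
    collinear columns.
    """
    coded = _coded_matrix(table)
    k = coded.shape[1]
    if terms is None:
        terms = full_quadratic_terms(k)
    terms = [parse_term(t, k) if isinstance(t, str) else _validate_term(t) for t in terms]
    X = design_matrix(coded, terms)
    y = table[response].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more runs ({n}) than terms ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        names = [format_term(t) for t in terms]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {p} terms); "
            f"check for collinear terms among {names}"
        )
    res = sm.OLS(y, X).fit()
    model = QuadraticModel(
        terms=tuple(terms),
        coefficients=tuple(res.params),
        response=response,
        units=units,
    )
    return FitResult(
        model=model,
        se=tuple(res.bse),
        t_values=tuple(res.tvalues),
        p_values=tuple(res.pvalues),
        df_residual=int(res.df_resid),
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        residuals=tuple(res.resid),
        coded=coded,
    )


def reduce_and_refit(
    table: pd.DataFrame,
    fit: FitResult,
    keep_terms: list[str] | list[Term],
) -> FitResult:
    """Refit keeping only ``keep_terms`` (must include the intercept and be a
    subset of the fitted terms)."""
    k = fit.model.k
    keep = [parse_term(t, k) if isinstance(t, str) else _validate_term(t) for t in keep_terms]
    if not keep:
        raise ValueError("keep_terms must not be empty")
    fitted = set(fit.model.terms)
    missing = [format_term(t) for t in keep if t not in fitted]
    if missing:
        raise ValueError(f"keep_terms not in the fitted model: {missing}")
    if tuple([0] * k) not in keep:
        raise ValueError("keep_terms must include the intercept")
    return fit_ols(table, fit.model.response, keep, units=fit.model.units)


def reduction_by_pvalue(
    fit: FitResult, threshold: float, protect: tuple[str, ...] = ()
) -> list[str]:
    """Terms with p <= threshold, plus the intercept and any protected terms.

    Advisory screening only: published reduced models here are reproduced
    from explicit keep-lists, since reduction in practice is a judgment call
    (a near-insignificant linear term may be kept to retain a factor's
    influence, as the liquid:solid ratio is in the DD model).
    """
    names = fit.model.term_strings()
    keep = [
        name
        for name, p in zip(names, fit.p_values)
        if p <= threshold or name == "1" or name in protect
    ]
    return keep
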