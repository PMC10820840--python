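"""Shared fixtures: the 17-run experiment table, its fits, and the
(expensive) Pareto machinery, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

import chitopt as c


@pytest.fixture(scope="session")
def table2():
    return c.packaged_table2()


@pytest.fixture(scope="session")
def spec3():
    return c.deacetylation_design()


@pytest.fixture(scope="session")
def dd_full(table2):
    return c.fit_ols(table2, "dd_pct", units="%")


@pytest.fixture(scope="session")
def mm_full(table2):
    return c.fit_ols(table2, "mm_kda", units="kDa")


@pytest.fixture(scope="session")
def dd_reduced(table2, dd_full):
    return c.reduce_and_refit(table2, dd_full, list(c.DD_KEEP))


@pytest.fixture(scope="session")
def mm_reduced(table2, mm_full):
    return c.reduce_and_refit(table2, mm_full, list(c.MM_KEEP))


@pytest.fixture(scope="session")
def problem_max_max(dd_reduced, mm_reduced):
    return c.MooProblem(
        (
            c.Objective(dd_reduced.model, "max", "dd_pct"),
            c.Objective(mm_reduced.model, "max", "mm_kda"),
        )
    )


@pytest.fixture(scope="session")
def problem_max_min(dd_reduced, mm_reduced):
    return c.MooProblem(
        (
            c.Objective(dd_reduced.model, "max", "dd_pct"),
            c.Objective(mm_reduced.model, "min", "mm_kda"),
        )
    )


@pytest.fixture(scope="session")
def oracle_max_max(problem_max_max):
    return c.grid_pareto_oracle(problem_max_max, 201)


@pytest.fixture(scope="session")
def oracle_max_min(problem_max_min):
    return c.grid_pareto_oracle(problem_max_min, 201)


@pytest.fixture(scope="session")
def ga_front_max_max(problem_max_max):
    return c.nsga2(problem_max_max, c.GaConfig(seed=1))


@pytest.fixture(scope="session")
def ga_front_max_min(problem_max_min):
    return c.nsga2(problem_max_min, c.GaConfig(seed=1))


# printed Pareto-front rows: coded point, DD %, MM kDa
MAX_MAX_REFERENCE_ROWS = [
    ((0.80, -0.10, 0.31), 97.60, 863.66),
    ((0.86, -0.01, 0.25), 97.18, 865.66),
    ((0.75, -0.29, 0.34), 98.10, 853.78),
    ((0.78, -0.20, 0.29), 97.83, 860.45),
]
MAX_MIN_REFERENCE_ROWS = [
    ((0.35, -1.67, 1.61), 96.57, 122.4),
    ((0.36, -1.67, 1.43), 97.79, 225.3),
    ((0.32, -1.67, 1.67), 96.00, 75.60),
    ((0.37, -1.68, 1.47), 97.52, 199.7),
]


def brute_force_nondominated(values: np.ndarray, senses) -> np.ndarray:
    """O(n^2) pairwise dominance oracle used to validate the fast filter."""
    signs = np.array([1.0 if s == "max" else -1.0 for s in senses])
    V = np.asarray(values, dtype=float) * signs
    n = len(V)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        ge = (V >= V[i]).all(axis=1)
        gt = (V > V[i]).any(axis=1)
        keep[i] = not (ge & gt).any()
    return keep
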