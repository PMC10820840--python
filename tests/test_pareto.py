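"""Dominance, Pareto filtering, the lattice oracle, NSGA-II and the
analytic quadratic maximizer."""

import numpy as np
import pytest

import chitopt as c
from chitopt.pareto import GaConfig, SingleOptimum, nondominated_mask
from conftest import brute_force_nondominated


# --- dominance -------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,senses,expected",
    [
        ((2, 3), (1, 3), ("max", "max"), True),
        ((2, 3), (2, 3), ("max", "max"), False),
        ((97, 120), (96, 200), ("max", "min"), True),
        ((1, 1), (2, 0), ("max", "max"), False),
        ((1, 2), (2, 1), ("min", "min"), False),
    ],
)
def test_dominates(a, b, senses, expected):
    assert c.dominates(a, b, senses) is expected


def test_dominates_length_mismatch():
    with pytest.raises(ValueError):
        c.dominates((1, 2), (1, 2, 3), ("max", "max", "max"))


# --- nondominated filter ---------------------------------------------------


def test_filter_small_example():
    vals = np.array([[1, 1], [2, 2], [0, 3]], dtype=float)
    front = c.nondominated_filter(vals, vals, ("max", "max"))
    assert {tuple(v) for v in front.values} == {(2.0, 2.0), (0.0, 3.0)}


def test_filter_identical_points_all_retained():
    vals = np.ones((5, 2))
    front = c.nondominated_filter(vals, vals, ("max", "min"))
    assert len(front) == 5


@pytest.mark.parametrize("senses", [("max", "max"), ("max", "min"), ("min", "min")])
def test_filter_matches_pairwise_oracle_2d(senses):
    rng = np.random.default_rng(42)
    vals = rng.normal(size=(400, 2))
    # add exact ties to stress the scan
    vals[::7] = vals[3]
    mask = nondominated_mask(vals, senses)
    np.testing.assert_array_equal(mask, brute_force_nondominated(vals, senses))


def test_filter_matches_pairwise_oracle_large_2d():
    rng = np.random.default_rng(1)
    vals = rng.uniform(size=(10_000, 2))
    mask = nondominated_mask(vals, ("max", "max"))
    brute = brute_force_nondominated(vals, ("max", "max"))
    np.testing.assert_array_equal(mask, brute)


def test_filter_matches_pairwise_oracle_3d():
    rng = np.random.default_rng(5)
    vals = rng.normal(size=(300, 3))
    mask = nondominated_mask(vals, ("max", "min", "max"))
    np.testing.assert_array_equal(
        mask, brute_force_nondominated(vals, ("max", "min", "max"))
    )


def test_filter_order_independent():
    rng = np.random.default_rng(9)
    vals = rng.normal(size=(200, 2))
    mask = nondominated_mask(vals, ("max", "max"))
    perm = rng.permutation(200)
    mask_perm = nondominated_mask(vals[perm], ("max", "max"))
    np.testing.assert_array_equal(mask_perm, mask[perm])


# --- grid oracle -----------------------------------------------------------


def test_grid_single_objective_is_argmax(mm_reduced):
    prob = c.MooProblem((c.Objective(mm_reduced.model, "max"),))
    front = c.grid_pareto_oracle(prob, 41)
    assert len(front) == 1
    # lattice argmax is near the analytic optimum
    np.testing.assert_allclose(front.points[0], [0.8583, 0, 0.268], atol=0.05)


def test_grid_identical_objectives_single_point(mm_reduced):
    prob = c.MooProblem(
        (c.Objective(mm_reduced.model, "max", "a"), c.Objective(mm_reduced.model, "max", "b"))
    )
    front = c.grid_pareto_oracle(prob, 41)
    assert len(front) == 1


def test_grid_refinement_is_consistent(problem_max_max):
    """Doubling the lattice resolution must not dominate the coarse front by
    more than the coarse grid's own spacing allows."""
    coarse = c.grid_pareto_oracle(problem_max_max, 41)
    fine = c.grid_pareto_oracle(problem_max_max, 81)
    # every coarse point is within a small objective-space distance of the fine front
    for v in coarse.values:
        d_dd = np.abs(fine.values[:, 0] - v[0])
        d_mm = np.abs(fine.values[:, 1] - v[1])
        assert np.min(np.maximum(d_dd / 0.5, d_mm / 5.0)) < 1.0


def test_grid_lattice_cap():
    model = c.published_mm_model()
    prob = c.MooProblem((c.Objective(model, "max"), c.Objective(model, "min")))
    with pytest.raises(ValueError, match="cap"):
        c.grid_pareto_oracle(prob, 5000)
    with pytest.raises(ValueError, match="resolution"):
        c.grid_pareto_oracle(prob, 1)


# --- NSGA-II ---------------------------------------------------------------


def test_ga_config_validation():
    with pytest.raises(ValueError, match="population"):
        GaConfig(pop_size=7)
    with pytest.raises(ValueError, match="probability"):
        GaConfig(crossover_prob=1.5)


def test_nsga2_reproducible(problem_max_max):
    f1 = c.nsga2(problem_max_max, GaConfig(pop_size=20, n_generations=10, seed=3))
    f2 = c.nsga2(problem_max_max, GaConfig(pop_size=20, n_generations=10, seed=3))
    np.testing.assert_array_equal(f1.points, f2.points)


def test_nsga2_single_objective_degenerate_converges():
    """max -(x1^2+x2^2+x3^2) has its optimum at the origin."""
    model = c.QuadraticModel(
        terms=((0, 0, 0), (2, 0, 0), (0, 2, 0), (0, 0, 2)),
        coefficients=(0.0, -1.0, -1.0, -1.0),
    )
    prob = c.MooProblem((c.Objective(model, "max"),))
    front = c.nsga2(prob, GaConfig(pop_size=50, n_generations=100, seed=2))
    best = front.points[np.argmax(front.values[:, 0])]
    np.testing.assert_allclose(best, 0.0, atol=1e-2)


def test_nsga2_front_mutually_nondominated(ga_front_max_max, ga_front_max_min):
    assert ga_front_max_max.is_mutually_nondominated()
    assert ga_front_max_min.is_mutually_nondominated()


def test_nsga2_within_grid_oracle_hull(ga_front_max_max, oracle_max_max):
    """No lattice point may dominate a GA solution by more than the stated
    tolerance (0.05 DD units, 1 kDa)."""
    for v in ga_front_max_max.values:
        dominated = (oracle_max_max.values[:, 0] >= v[0] + 0.05) & (
            oracle_max_max.values[:, 1] >= v[1] + 1.0
        )
        assert not dominated.any()


def test_nsga2_converges_across_seeds(problem_max_max, oracle_max_max):
    """Across 5 seeds the GA front stays within 1 % of each objective's range
    of the 201-per-axis lattice front (max over GA points of min distance)."""
    ranges = oracle_max_max.values.max(axis=0) - oracle_max_max.values.min(axis=0)
    for seed in range(5):
        front = c.nsga2(problem_max_max, GaConfig(seed=seed))
        for v in front.values:
            rel = np.abs(oracle_max_max.values - v) / ranges
            assert np.min(rel.max(axis=1)) < 0.01


# --- analytic maximization -------------------------------------------------


def test_maximize_concave_origin():
    model = c.QuadraticModel(
        terms=((0, 0, 0), (2, 0, 0), (0, 2, 0), (0, 0, 2)),
        coefficients=(0.0, -1.0, -1.0, -1.0),
    )
    opt = c.maximize_single(model)
    assert opt.interior
    np.testing.assert_allclose(opt.point, 0.0, atol=1e-12)
    assert opt.value == pytest.approx(0.0, abs=1e-12)


def test_maximize_convex_hits_boundary():
    model = c.QuadraticModel(terms=((0,), (2,)), coefficients=(0.0, 1.0))
    opt = c.maximize_single(model, bounds=((-1.68, 1.68),))
    assert not opt.interior
    assert abs(opt.point[0]) == pytest.approx(1.68, abs=1e-6)
    assert opt.value == pytest.approx(1.68**2, rel=1e-6)


def test_maximize_published_mm_surface(mm_reduced):
    opt = c.maximize_single(mm_reduced.model)
    assert opt.interior
    np.testing.assert_allclose(opt.point, [0.8583, 0.0, 0.268], atol=1e-3)
    assert opt.value == pytest.approx(865.0, abs=1.0)


# --- reporting -------------------------------------------------------------


def test_front_report_layout(ga_front_max_max, spec3):
    report = c.front_report(ga_front_max_max, spec3)
    assert list(report.columns) == [
        "x1", "x2", "x3", "naoh_pct", "ratio", "duration_min", "dd_pct", "mm_kda",
    ]
    assert len(report) == len(ga_front_max_max)
    # sorted by first objective; decode contract on the duration column
    assert report["dd_pct"].is_monotonic_increasing
    np.testing.assert_allclose(report["duration_min"], 120 + 30 * report["x3"], rtol=1e-12)


def test_front_report_empty_rejected(spec3):
    empty = c.ParetoFront(np.empty((0, 3)), np.empty((0, 2)), ("max", "max"))
    with pytest.raises(ValueError, match="empty"):
        c.front_report(empty, spec3)
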