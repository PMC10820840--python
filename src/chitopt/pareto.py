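"""Multiobjective optimization of fitted response surfaces over the coded box.

Two machineries are provided and cross-checked against each other:

* a deterministic brute-force lattice oracle (:func:`grid_pareto_oracle`)
  that evaluates the objectives on a full grid and keeps the nondominated
  points — slow but exact to the grid resolution, and
* an elitist genetic algorithm (:func:`nsga2`) with fast nondominated
  sorting, crowding-distance diversity, binary tournament selection,
  simulated-binary crossover and polynomial mutation.

The feasible region is the coded cube (default [-1.68, 1.68] per factor).
Interior maxima of a single quadratic are found analytically from the
stationarity system (:func:`maximize_single`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignSpec, decode_point
from .rsm import QuadraticModel

__all__ = [
    "Objective",
    "MooProblem",
    "GaConfig",
    "ParetoFront",
    "dominates",
    "nondominated_filter",
    "nondominated_mask",
    "grid_pareto_oracle",
    "nsga2",
    "maximize_single",
    "front_report",
]

DEFAULT_BOUND = 1.68


@dataclass(frozen=True)
class Objective:
    model: QuadraticModel
    sense: str  # "max" | "min"
    label: str = ""

    def __post_init__(self) -> None:
        if self.sense not in ("max", "min"):
            raise ValueError(f"sense must be 'max' or 'min', got {self.sense!r}")
        if not self.label:
            object.__setattr__(self, "label", self.model.response)


@dataclass(frozen=True)
class MooProblem:
    """Objectives over a coded box; bounds are (lower, upper) per coordinate."""

    objectives: tuple[Objective, ...]
    bounds: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        k = self.objectives[0].model.k
        for obj in self.objectives:
            if obj.model.k != k:
                raise ValueError("all objective models must share the same dimension")
        if not self.bounds:
            object.__setattr__(
                self, "bounds", tuple((-DEFAULT_BOUND, DEFAULT_BOUND) for _ in range(k))
            )
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bounds ({lo}, {hi})")
        if len(self.bounds) != k:
            raise ValueError("one bound pair per coordinate required")

    @property
    def k(self) -> int:
        return self.objectives[0].model.k

    @property
    def senses(self) -> tuple[str, ...]:
        return tuple(o.sense for o in self.objectives)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Objective values, shape (n, n_objectives), in natural units."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.column_stack([o.model.predict(pts) for o in self.objectives])


@dataclass(frozen=True)
class GaConfig:
    """NSGA-II settings.  Defaults: population 100 for 200 generations,
    SBX crossover (p=0.9, eta=15), polynomial mutation (p=1/k per gene,
    eta=20)."""

    pop_size: int = 100
    n_generations: int = 200
    crossover_prob: float = 0.9
    crossover_eta: float = 15.0
    mutation_prob: float | None = None  # default 1/k per gene
    mutation_eta: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4 or self.pop_size % 2:
            raise ValueError("population size must be even and >= 4")
        for p in (self.crossover_prob, self.mutation_prob):
            if p is not None and not 0 <= p <= 1:
                raise ValueError(f"probability out of [0, 1]: {p}")


@dataclass(frozen=True)
class ParetoFront:
    """Mutually nondominated solutions: coded points with objective values."""

    points: np.ndarray  # (n, k)
    values: np.ndarray  # (n, m) natural units
    senses: tuple[str, ...]
    labels: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.points)

    def is_mutually_nondominated(self) -> bool:
        vals = self.values
        for i in range(len(vals)):
            for j in range(len(vals)):
                if i != j and dominates(vals[i], vals[j], self.senses):
                    return False
        return True


def _signed(values: np.ndarray, senses) -> np.ndarray:
    """Flip minimized objectives so that larger is always better."""
    signs = np.array([1.0 if s == "max" else -1.0 for s in senses])
    return np.asarray(values, dtype=float) * signs


def dominates(a, b, senses) -> bool:
    """True iff a is at least as good as b everywhere and better somewhere."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) != len(senses):
        raise ValueError("objective vectors and senses must have equal length")
    sa, sb = _signed(a, senses), _signed(b, senses)
    return bool(np.all(sa >= sb) and np.any(sa > sb))


def nondominated_mask(values: np.ndarray, senses) -> np.ndarray:
    """Boolean mask of points not dominated by any other point.

    Uses an O(n log n) sort-and-scan for two objectives and a vectorized
    pairwise sweep otherwise.  Duplicate points do not dominate each other,
    so all copies of a nondominated point are retained.
    """
    V = _signed(np.atleast_2d(values), senses)
    n, m = V.shape
    if n == 0:
        raise ValueError("empty point set")
    if m == 2:
        # scan groups of equal obj1 in decreasing obj1 order.  A point is
        # dominated iff an earlier group reaches its obj2 (strictly better
        # obj1, >= obj2) or its own group strictly exceeds it in obj2.
        order = np.lexsort((-V[:, 1], -V[:, 0]))
        v0, v1 = V[order, 0], V[order, 1]
        starts = np.flatnonzero(np.r_[True, v0[1:] != v0[:-1]])  # group heads
        gmax2 = np.maximum.reduceat(v1, starts)  # max obj2 per group
        best2 = np.r_[-np.inf, np.maximum.accumulate(gmax2)[:-1]]  # before group
        group_id = np.cumsum(np.r_[False, v0[1:] != v0[:-1]])
        keep_sorted = (v1 == gmax2[group_id]) & (gmax2[group_id] > best2[group_id])
        keep = np.zeros(n, dtype=bool)
        keep[order] = keep_sorted
        return keep
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if not keep[i]:
            continue
        ge = np.all(V >= V[i], axis=1)
        gt = np.any(V > V[i], axis=1)
        dominators = ge & gt
        if dominators.any():
            keep[i] = False
        else:
            # i dominates these; prune to shrink later scans
            dominated = np.all(V <= V[i], axis=1) & np.any(V < V[i], axis=1)
            keep &= ~dominated
            keep[i] = True
    return keep


def nondominated_filter(points: np.ndarray, values: np.ndarray, senses,
                        labels: tuple[str, ...] = ()) -> ParetoFront:
    """Keep exactly the nondominated points; order-independent membership."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.atleast_2d(np.asarray(values, dtype=float))
    mask = nondominated_mask(values, senses)
    return ParetoFront(points[mask], values[mask], tuple(senses), tuple(labels))


MAX_LATTICE = 20_000_000


def grid_pareto_oracle(problem: MooProblem, resolution: int = 201) -> ParetoFront:
    """Brute-force Pareto front on a full lattice over the bounds.

    Deterministic; intended as the verification surface for the GA.
    Raises if the lattice would exceed ``MAX_LATTICE`` points.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if resolution**problem.k > MAX_LATTICE:
        raise ValueError(
            f"lattice of {resolution}^{problem.k} points exceeds the "
            f"{MAX_LATTICE:,}-point cap"
        )
    axes = [np.linspace(lo, hi, resolution) for lo, hi in problem.bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    vals = problem.evaluate(pts)
    labels = tuple(o.label for o in problem.objectives)
    if len(problem.objectives) == 1:
        best = np.argmax(_signed(vals, problem.senses)[:, 0])
        return ParetoFront(pts[[best]], vals[[best]], problem.senses, labels)
    return nondominated_filter(pts, vals, problem.senses, labels)


# ---------------------------------------------------------------------------
# NSGA-II


def fast_nondominated_sort(signed_vals: np.ndarray) -> np.ndarray:
    """Rank each point by nondominated front (0 = Pareto-optimal)."""
    n = len(signed_vals)
    ge = np.all(signed_vals[:, None, :] >= signed_vals[None, :, :], axis=2)
    gt = np.any(signed_vals[:, None, :] > signed_vals[None, :, :], axis=2)
    dom = ge & gt  # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    ranks = np.full(n, -1, dtype=int)
    current = np.flatnonzero(n_dominators == 0)
    r = 0
    remaining = n
    while remaining:
        ranks[current] = r
        remaining -= len(current)
        counts = n_dominators.copy()
        counts -= dom[current].sum(axis=0)
        n_dominators = counts
        nxt = np.flatnonzero((n_dominators == 0) & (ranks == -1))
        current = nxt
        r += 1
    return ranks


def crowding_distance(signed_vals: np.ndarray) -> np.ndarray:
    """Cuboid crowding distance within one front; extremes get +inf."""
    n, m = signed_vals.shape
    dist = np.zeros(n)
    for j in range(m):
        order = np.argsort(signed_vals[:, j], kind="stable")
        vj = signed_vals[order, j]
        span = vj[-1] - vj[0]
        dist[order[0]] = dist[order[-1]] = np.inf
        if n > 2 and span > 0:
            dist[order[1:-1]] += (vj[2:] - vj[:-2]) / span
    return dist


def _tournament(rng, ranks, crowd):
    n = len(ranks)
    a, b = rng.integers(0, n, 2)
    if ranks[a] < ranks[b]:
        return a
    if ranks[b] < ranks[a]:
        return b
    return a if crowd[a] >= crowd[b] else b


def _sbx(rng, p1, p2, lo, hi, prob, eta):
    """Simulated binary crossover with per-gene 0.5 exchange probability."""
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > prob:
        return c1, c2
    for i in range(len(p1)):
        if rng.random() > 0.5 or p1[i] == p2[i]:
            continue
        y1, y2 = min(p1[i], p2[i]), max(p1[i], p2[i])
        u = rng.random()
        beta = 1.0 + 2.0 * (y1 - lo[i]) / (y2 - y1)
        alpha = 2.0 - beta ** -(eta + 1.0)
        betaq = (u * alpha) ** (1.0 / (eta + 1.0)) if u <= 1.0 / alpha else (
            1.0 / (2.0 - u * alpha)) ** (1.0 / (eta + 1.0))
        ch1 = 0.5 * (y1 + y2 - betaq * (y2 - y1))
        beta = 1.0 + 2.0 * (hi[i] - y2) / (y2 - y1)
        alpha = 2.0 - beta ** -(eta + 1.0)
        betaq = (u * alpha) ** (1.0 / (eta + 1.0)) if u <= 1.0 / alpha else (
            1.0 / (2.0 - u * alpha)) ** (1.0 / (eta + 1.0))
        ch2 = 0.5 * (y1 + y2 + betaq * (y2 - y1))
        if rng.random() < 0.5:
            ch1, ch2 = ch2, ch1
        c1[i] = np.clip(ch1, lo[i], hi[i])
        c2[i] = np.clip(ch2, lo[i], hi[i])
    return c1, c2


def _polynomial_mutation(rng, x, lo, hi, prob, eta):
    y = x.copy()
    for i in range(len(x)):
        if rng.random() > prob:
            continue
        span = hi[i] - lo[i]
        u = rng.random()
        d1 = (y[i] - lo[i]) / span
        d2 = (hi[i] - y[i]) / span
        if u < 0.5:
            dq = (2 * u + (1 - 2 * u) * (1 - d1) ** (eta + 1)) ** (1 / (eta + 1)) - 1
        else:
            dq = 1 - (2 * (1 - u) + 2 * (u - 0.5) * (1 - d2) ** (eta + 1)) ** (1 / (eta + 1))
        y[i] = np.clip(y[i] + dq * span, lo[i], hi[i])
    return y


def nsga2(problem: MooProblem, config: GaConfig | None = None) -> ParetoFront:
    """Elitist NSGA-II over the coded box; returns the final rank-0 set.

    Reproducible for a fixed ``config.seed``.
    """
    config = config or GaConfig()
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in problem.bounds])
    hi = np.array([b[1] for b in problem.bounds])
    k = problem.k
    mut_prob = config.mutation_prob if config.mutation_prob is not None else 1.0 / k
    npop = config.pop_size

    pop = rng.uniform(lo, hi, size=(npop, k))
    vals = problem.evaluate(pop)
    signed = _signed(vals, problem.senses)
    ranks = fast_nondominated_sort(signed)
    crowd = np.zeros(npop)
    for r in np.unique(ranks):
        idx = np.flatnonzero(ranks == r)
        crowd[idx] = crowding_distance(signed[idx])

    for _ in range(config.n_generations):
        children = np.empty_like(pop)
        for c in range(0, npop, 2):
            p1 = pop[_tournament(rng, ranks, crowd)]
            p2 = pop[_tournament(rng, ranks, crowd)]
            c1, c2 = _sbx(rng, p1, p2, lo, hi, config.crossover_prob, config.crossover_eta)
            children[c] = _polynomial_mutation(rng, c1, lo, hi, mut_prob, config.mutation_eta)
            children[c + 1] = _polynomial_mutation(rng, c2, lo, hi, mut_prob, config.mutation_eta)
        union = np.vstack([pop, children])
        uvals = np.vstack([vals, problem.evaluate(children)])
        usigned = _signed(uvals, problem.senses)
        uranks = fast_nondominated_sort(usigned)
        ucrowd = np.zeros(len(union))
        for r in np.unique(uranks):
            idx = np.flatnonzero(uranks == r)
            ucrowd[idx] = crowding_distance(usigned[idx])
        # environmental selection: fill by rank, break the last front by crowding
        order = np.lexsort((-ucrowd, uranks))
        chosen = order[:npop]
        pop, vals = union[chosen], uvals[chosen]
        signed = usigned[chosen]
        ranks, crowd = uranks[chosen], ucrowd[chosen]

    final = np.flatnonzero(ranks == ranks.min())
    labels = tuple(o.label for o in problem.objectives)
    return nondominated_filter(pop[final], vals[final], problem.senses, labels)


# ---------------------------------------------------------------------------
# single-objective quadratic maximization


def _quadratic_parts(model: QuadraticModel):
    """Split a quadratic model into (c, b, B) with y = c + b'x + x'Bx."""
    k = model.k
    c = 0.0
    b = np.zeros(k)
    B = np.zeros((k, k))
    for t, coef in zip(model.terms, model.coefficients):
        deg = sum(t)
        if deg == 0:
            c = coef
        elif deg == 1:
            b[t.index(1)] = coef
        elif t.count(2) == 1:
            i = t.index(2)
            B[i, i] = coef
        else:
            i, j = [idx for idx, e in enumerate(t) if e == 1]
            B[i, j] += coef / 2.0
            B[j, i] += coef / 2.0
    return c, b, B


@dataclass(frozen=True)
class SingleOptimum:
    point: np.ndarray
    value: float
    interior: bool  # True if found as an interior stationary maximum


def maximize_single(model: QuadraticModel, bounds=None,
                    grid_resolution: int = 101) -> SingleOptimum:
    """Maximize one quadratic over a box.

    Solves the stationarity system grad y = b + 2Bx = 0; if the Hessian 2B is
    negative definite and the stationary point lies inside the box it is the
    global maximum.  Otherwise (or for a singular Hessian) falls back to a
    lattice search polished by L-BFGS-B.
    """
    k = model.k
    if bounds is None:
        bounds = tuple((-DEFAULT_BOUND, DEFAULT_BOUND) for _ in range(k))
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    _, b, B = _quadratic_parts(model)
    try:
        x_star = np.linalg.solve(-2.0 * B, b)
        eig = np.linalg.eigvalsh(2.0 * B)
        if np.all(eig < 0) and np.all(x_star >= lo) and np.all(x_star <= hi):
            return SingleOptimum(x_star, float(model.predict(x_star)), True)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular Hessian; falling back to grid search", stacklevel=2)
    from scipy.optimize import minimize

    axes = [np.linspace(l, h, grid_resolution) for l, h in zip(lo, hi)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    vals = np.asarray(model.predict(pts))
    x0 = pts[np.argmax(vals)]
    res = minimize(
        lambda x: -model.predict(x), x0, method="L-BFGS-B", bounds=list(zip(lo, hi))
    )
    return SingleOptimum(res.x, float(model.predict(res.x)), False)


def front_report(front: ParetoFront, spec: DesignSpec) -> pd.DataFrame:
    """Tabulate a front: coded coordinates, decoded real settings, objective
    values; rows sorted by the first objective."""
    if len(front) == 0:
        raise ValueError("empty Pareto front")
    coded = front.points
    reals = decode_point(coded, spec)
    data = {}
    for j in range(coded.shape[1]):
        data[f"x{j + 1}"] = coded[:, j]
    for j, f in enumerate(spec.factors):
        data[f.name] = reals[:, j]
    labels = front.labels or tuple(f"f{j + 1}" for j in range(front.values.shape[1]))
    for j, lab in enumerate(labels):
        data[lab] = front.values[:, j]
    df = pd.DataFrame(data)
    return df.sort_values(labels[0], ignore_index=True)
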