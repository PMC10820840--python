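"""End-to-end reproduction pipeline: load data, fit, reduce, optimize, report.

`run_reproduction` drives the whole study on the packaged 17-run
deacetylation table (or any table of the same shape): full quadratic fits
for DD and MM with ANOVA, reduction to the published keep-lists, the
analytic single-objective MM maximum, and both bi-objective Pareto problems
(max DD & max MM; max DD & min MM) solved by NSGA-II and verified against
the lattice oracle.  All numeric outputs land in a result bundle and,
optionally, as CSV/JSON files in an output directory.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignSpec, deacetylation_design
from .pareto import (
    GaConfig,
    MooProblem,
    Objective,
    ParetoFront,
    SingleOptimum,
    front_report,
    grid_pareto_oracle,
    maximize_single,
    nsga2,
)
from .rsm import DD_KEEP, MM_KEEP, FitResult, fit_ols, reduce_and_refit

log = logging.getLogger("chitopt")

REQUIRED_COLUMNS = ("x1", "x2", "x3")
RESPONSE_COLUMNS = ("dd_pct", "mm_kda")


def packaged_table2() -> pd.DataFrame:
    """The packaged 17-run deacetylation experiment table (read-only fixture)."""
    with importlib.resources.files("chitopt.data").joinpath("table2.csv").open() as fh:
        return load_experiment_csv(fh)


def load_experiment_csv(path_or_buffer) -> pd.DataFrame:
    """Read an experiment table; validates coded columns and numeric cells."""
    try:
        table = pd.read_csv(path_or_buffer)
    except pd.errors.EmptyDataError:
        raise ValueError(
            f"empty experiment file; expected a header with columns {REQUIRED_COLUMNS}"
        ) from None
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"experiment table is missing mandatory columns: {missing}")
    for col in table.columns:
        if col in REQUIRED_COLUMNS + RESPONSE_COLUMNS + ("yield_pct",):
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad = table.index[coerced.isna() & table[col].notna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric cell in column {col!r}, row(s) {list(bad + 2)} "
                    "(1-based file lines incl. header)"
                )
            table[col] = coerced
    return table


def write_front_csv(front_table: pd.DataFrame, path) -> None:
    front_table.to_csv(path, index=False, float_format="%.6g")


@dataclass
class ReproductionResult:
    """Everything `run_reproduction` computes, in memory."""

    dd_full: FitResult
    mm_full: FitResult
    dd_reduced: FitResult
    mm_reduced: FitResult
    mm_optimum: SingleOptimum
    front_max_max: ParetoFront
    front_max_min: ParetoFront
    oracle_max_max: ParetoFront
    oracle_max_min: ParetoFront
    spec: DesignSpec

    def summary(self) -> dict:
        from .design import decode_point

        real = decode_point(self.mm_optimum.point, self.spec)
        a = self.front_max_max.values
        b = self.front_max_min.values
        return {
            "dd_full": {"r_squared": self.dd_full.r_squared, "f_pvalue": self.dd_full.f_pvalue},
            "mm_full": {"r_squared": self.mm_full.r_squared, "f_pvalue": self.mm_full.f_pvalue},
            "dd_reduced": {
                "r_squared": self.dd_reduced.r_squared,
                "coefficients": dict(
                    zip(self.dd_reduced.model.term_strings(), self.dd_reduced.model.coefficients)
                ),
            },
            "mm_reduced": {
                "r_squared": self.mm_reduced.r_squared,
                "coefficients": dict(
                    zip(self.mm_reduced.model.term_strings(), self.mm_reduced.model.coefficients)
                ),
            },
            "mm_optimum": {
                "coded": list(self.mm_optimum.point),
                "real": list(real),
                "mm_kda": self.mm_optimum.value,
                "interior": self.mm_optimum.interior,
            },
            "front_max_max": {
                "n": len(self.front_max_max),
                "dd_range": [float(a[:, 0].min()), float(a[:, 0].max())],
                "mm_range": [float(a[:, 1].min()), float(a[:, 1].max())],
            },
            "front_max_min": {
                "n": len(self.front_max_min),
                "dd_range": [float(b[:, 0].min()), float(b[:, 0].max())],
                "mm_range": [float(b[:, 1].min()), float(b[:, 1].max())],
            },
        }


def run_reproduction(
    table: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    seed: int = 1,
    ga_generations: int = 200,
    oracle_resolution: int = 201,
    spec: DesignSpec | None = None,
) -> ReproductionResult:
    """Run the full analysis on ``table`` (default: the packaged fixture)."""
    if table is None:
        table = packaged_table2()
    spec = spec or deacetylation_design()

    log.info("fitting full quadratic models (n=%d runs)", len(table))
    dd_full = fit_ols(table, "dd_pct", units="%")
    mm_full = fit_ols(table, "mm_kda", units="kDa")
    dd_red = reduce_and_refit(table, dd_full, list(DD_KEEP))
    mm_red = reduce_and_refit(table, mm_full, list(MM_KEEP))
    log.info(
        "R² full DD=%.4f MM=%.4f; reduced DD=%.4f MM=%.4f",
        dd_full.r_squared, mm_full.r_squared, dd_red.r_squared, mm_red.r_squared,
    )

    mm_opt = maximize_single(mm_red.model)
    log.info("MM maximum %.2f kDa at coded %s", mm_opt.value, np.round(mm_opt.point, 4))

    ga = GaConfig(n_generations=ga_generations, seed=seed)
    prob_a = MooProblem(
        (Objective(dd_red.model, "max", "dd_pct"), Objective(mm_red.model, "max", "mm_kda"))
    )
    prob_b = MooProblem(
        (Objective(dd_red.model, "max", "dd_pct"), Objective(mm_red.model, "min", "mm_kda"))
    )
    front_a = nsga2(prob_a, ga)
    front_b = nsga2(prob_b, ga)
    oracle_a = grid_pareto_oracle(prob_a, oracle_resolution)
    oracle_b = grid_pareto_oracle(prob_b, oracle_resolution)
    log.info("fronts: GA %d/%d solutions, oracle %d/%d", len(front_a), len(front_b),
             len(oracle_a), len(oracle_b))

    result = ReproductionResult(
        dd_full, mm_full, dd_red, mm_red, mm_opt, front_a, front_b, oracle_a, oracle_b, spec
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dd_full.anova_table().to_csv(out / "anova_dd_full.csv", index=False)
        mm_full.anova_table().to_csv(out / "anova_mm_full.csv", index=False)
        for name, fit in [("dd_reduced", dd_red), ("mm_reduced", mm_red),
                          ("dd_full", dd_full), ("mm_full", mm_full)]:
            payload = fit.model.to_dict() | {
                "r_squared": fit.r_squared,
                "f_statistic": fit.f_statistic,
                "f_pvalue": fit.f_pvalue,
            }
            (out / f"model_{name}.json").write_text(json.dumps(payload, indent=2))
        write_front_csv(front_report(front_a, spec), out / "front_max_dd_max_mm.csv")
        write_front_csv(front_report(front_b, spec), out / "front_max_dd_min_mm.csv")
        write_front_csv(front_report(oracle_a, spec), out / "oracle_max_dd_max_mm.csv")
        write_front_csv(front_report(oracle_b, spec), out / "oracle_max_dd_min_mm.csv")
        (out / "summary.json").write_text(json.dumps(result.summary(), indent=2))
        log.info("wrote result bundle to %s", out)
    return result
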