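#!/usr/bin/env python
"""Fit the full quadratic response surfaces for DD and MM and reduce them.

Fits the 10-term second-order model to both responses of the 17-run table,
prints the ANOVA (coefficient, SE, p), then refits with the study's
keep-lists: the DD model keeps {1, x1, x2, x3, x1x3, x1^2, x3^2} (x2 is
retained despite p=0.41 so the liquid:solid ratio keeps a voice), the MM
model keeps {1, x1, x3, x1x3, x1^2, x2^2, x3^2}.  Writes ANOVA CSVs and
model JSONs under results/.
"""

import json
from pathlib import Path

import chitopt as c

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

table = c.packaged_table2()

for resp, units, keep in [
    ("dd_pct", "%", c.DD_KEEP),
    ("mm_kda", "kDa", c.MM_KEEP),
]:
    full = c.fit_ols(table, resp, units=units)
    red = c.reduce_and_refit(table, full, list(keep))
    print(f"\n=== {resp} ===")
    print(full.anova_table().to_string(index=False,
                                       float_format=lambda v: f"{v:.4f}"))
    print(f"full model: R^2 = {full.r_squared:.4f}, "
          f"F({len(full.model.terms)-1},{full.df_residual}) p = {full.f_pvalue:.4f}")
    terms = " + ".join(
        f"{b:+.3f}*{t}" for t, b in zip(red.model.term_strings(), red.model.coefficients)
    )
    print(f"reduced ({len(red.model.terms)} terms): R^2 = {red.r_squared:.4f}")
    print(f"  {resp} = {terms}")
    full.anova_table().to_csv(OUT / f"anova_{resp}_full.csv", index=False)
    for tag, fit in [("full", full), ("reduced", red)]:
        payload = fit.model.to_dict() | {
            "r_squared": fit.r_squared,
            "f_statistic": fit.f_statistic,
            "f_pvalue": fit.f_pvalue,
        }
        (OUT / f"model_{resp}_{tag}.json").write_text(json.dumps(payload, indent=2))

print(f"\nwrote ANOVA tables and model JSONs to {OUT}")
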