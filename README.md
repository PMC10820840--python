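# chitopt

Response-surface modelling and multiobjective optimization of the chitin
deacetylation step that turns shrimp-waste chitin into chitosan.

Chitosan quality is set by two conflicting characteristics: the degree of
deacetylation (DD, % of glucosamine units — higher is better for almost every
application) and the viscometric molar mass (MM, kDa — some applications want
high-MM chains, others want low). Both depend on the deacetylation operating
conditions. This package models and optimizes that trade-off for a
three-factor experiment: NaOH concentration (x₁), liquid:solid ratio (x₂) and
process duration (x₃).

The pipeline, each stage usable on its own:

1. **Design** (`chitopt.design`) — a rotatable central composite design:
   2³ factorial corners at coded ±1, axial runs at ±1.68, replicated centre
   points; affine coded⇄real mapping (centres 45 %, 18, 120 min; steps 10, 5,
   30).
2. **Characterization** (`chitopt.characterization`) — bench measurements to
   responses: DD% = 100·203Q/(1 + 42Q) with Q = C_M·ΔV/m from potentiometric
   titration; M_v = ([η]/K)^(1/α) from the Mark–Houwink–Sakurada equation
   (K = 13.8·10⁻³ mL/g, α = 0.85); gravimetric yield.
3. **RSM fitting** (`chitopt.rsm`) — OLS fits of the full second-order
   polynomial y = b₀ + Σbᵢxᵢ + Σbᵢⱼxᵢxⱼ + Σbᵢᵢxᵢ², with per-coefficient
   standard errors and p-values, R², the overall F-test, and judgment-based
   model reduction (exploiting CCD column orthogonality).
4. **Optimization** (`chitopt.pareto`) — the analytic interior maximum of a
   single quadratic (stationarity system + Hessian check), and Pareto fronts
   of two objectives by NSGA-II (fast nondominated sorting, crowding
   distance, SBX crossover, polynomial mutation), cross-checked against a
   deterministic full-lattice oracle.
5. **Synthetic data** (`chitopt.simulate`) — CCD tables from known quadratic
   surfaces plus Gaussian noise, for coefficient-recovery and coverage
   experiments with known ground truth.

A 17-run experiment table (coded factors, yield, DD, MM) ships as the
packaged fixture `chitopt/data/table2.csv`; `analysis/01…05` are the numbered
drivers that run the whole study over it and write tables under `results/`.

## Worked example

```python
import chitopt as c

table = c.packaged_table2()                      # 17-run experiment table
full  = c.fit_ols(table, "mm_kda", units="kDa")  # 10-term quadratic
red   = c.reduce_and_refit(table, full, list(c.MM_KEEP))
print(round(red.r_squared, 4))                   # 0.9329
opt = c.maximize_single(red.model)               # analytic interior maximum
print(opt.point.round(4), round(opt.value, 2))   # [0.8583 0.     0.268 ] 865.73
print(c.decode_point(opt.point, c.deacetylation_design()).round(2))
                                                 # [ 53.58  18.   128.04]
```

The molar mass peaks at 865.7 kDa for NaOH 53.6 %, liquid:solid ratio 18 and
a 128-minute treatment. Running `python analysis/04_pareto_fronts.py` then
shows the two trade-off fronts: maximizing DD and MM together, solutions
with DD between 97.5 and 98.5 % still reach over 840 kDa; maximizing DD
while minimizing MM, chains below 200 kDa are only available below ≈97.5 %
DD.

There is also a CLI mirror of the stages:

```sh
chitopt design --out design.csv
chitopt fit --response dd_pct --keep "1,x1,x2,x3,x1:x3,x1^2,x3^2" --out dd.json
chitopt optimize --models dd.json mm.json --senses max,max --seed 1 --out front.csv
chitopt reproduce --out-dir results
```

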