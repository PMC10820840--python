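# Methods

## Experimental design and coding

The design is a rotatable central composite design (CCD) in k = 3 factors:
a 2³ full factorial block at coded ±1, one axial pair per factor at coded
±α, and replicated centre runs, giving 2³ + 2·3 + 3 = 17 runs. Coded and
real values are related affinely, coded = (real − centre)/step, with

| factor | symbol | unit | centre | step | coded −1.68 … +1.68 |
|---|---|---|---|---|---|
| NaOH concentration | x₁ | % | 45 | 10 | 28.2 … 61.8 |
| liquid:solid ratio | x₂ | — | 18 | 5 | 9.6 … 26.4 |
| duration | x₃ | min | 120 | 30 | 69.6 … 170.4 |

α is taken as exactly 1.68 rather than the rotatable 2^(3/4) ≈ 1.6818: the
experiment tables record the axial runs at ±1.68, and the fitted
coefficients must correspond to the coded values actually used. Axial real
values are conventionally reported rounded (28, 62, 9.5, 26.5, 70, 170);
the linear map is authoritative, and table-matching allows one printing
unit of slack. The same convention resolves the decoded optimum: coded
x₁ = 0.8583 decodes to 45 + 8.583 = 53.58 % NaOH.

Runs are constructed in canonical order (factorial block in Yates order,
axial pairs per factor, centres last); externally supplied tables are
matched by run set, not by order.

## Response definitions

* **Degree of deacetylation.** From potentiometric titration, the acetyl
  quotient Q = C_M·ΔV/m (mol/g) with C_M the titrant molarity, ΔV the
  volume between the two inflection points (litres; the CSV reader accepts
  mL with an explicit unit column) and m the sample mass. Then
  DD% = 100·203·Q/(1 + 42·Q), with 203 g/mol the chitin monomer and
  42 g/mol the acetyl group. The ×100 placement is fixed by dimensional
  analysis: typical Q ≈ 0.004 mol/g must give DD in the observed 60–97 %
  range. DD is monotone in Q with asymptote 100·203/42 ≈ 483 %, so
  physically impossible values (> 100 %) can arise from bad inputs; they
  are flagged with a warning, never silently capped.
* **Molar mass.** Mark–Houwink–Sakurada: [η] = K·M_v^α with K =
  13.8·10⁻³ mL/g and α = 0.85 for chitosan in the study's solvent system;
  inverted as M_v = ([η]/K)^(1/α), stored in kDa (g/mol ÷ 1000). The
  inversion round-trips to 1e−10 relative by construction.
* **Yield.** 100 · (extracted chitosan g)/(extracted chitin g).

## Response-surface models

Both responses are modelled as full second-order polynomials in the coded
factors (10 terms for k = 3), fit by ordinary least squares. Standard
errors come from the residual variance times the inverse normal-equations
diagonal, p-values are two-sided t with n − p degrees of freedom, and the
model F statistic is the simultaneous regression-vs-residual test,
F = (SSM/(p−1))/(SSE/(n−p)) on (9, 7) df for the full models. Replicated
centre points are treated as ordinary runs; no pure-error/lack-of-fit
split is reported (three centre replicates are too few for it to carry
weight).

Model reduction is judgment-based, driven by explicit keep-lists rather
than an automatic threshold: the DD model keeps
{1, x₁, x₂, x₃, x₁x₃, x₁², x₃²} — x₂ (p = 0.41) is retained deliberately so
the liquid:solid ratio keeps any influence at all — and the MM model keeps
{1, x₁, x₃, x₁x₃, x₁², x₂², x₃²}. `reduction_by_pvalue` exists as an
advisory screen (p ≤ threshold plus protected terms). Because the CCD's
linear and interaction columns are mutually orthogonal and orthogonal to
the quadratic columns, dropping only linear/interaction terms leaves the
retained non-intercept estimates unchanged — the MM reduction exhibits
this exactly; the DD intercept shifts (from 90.34 to 90.90) because the
dropped pure-quadratic x₂² is not orthogonal to the intercept.

On the packaged table the full fits give R² = 0.915 (DD) and 0.945 (MM)
with F-test p = 0.0053 and 0.0013; the reduced fits give R² = 0.907 and
0.933. statsmodels provides the OLS engine; tests cross-check every
estimate against a direct normal-equations solve.

## Optimization

The feasible region is the coded cube [−1.68, 1.68]³ — the cube, not the
rotatable sphere, since trade-off solutions are sought out to the axial
extremes of each factor independently.

**Single objective.** A quadratic y = c + b'x + x'Bx (B symmetric, built
from the fitted coefficients with off-diagonals bᵢⱼ/2) has gradient
b + 2Bx; the stationary point solves −2Bx = b. If 2B is negative definite
and the point is inside the box it is the global maximum and is returned
exactly; otherwise a lattice search polished by L-BFGS-B handles
boundary/saddle cases, and a singular Hessian falls back to the lattice
with a warning. The reduced MM surface has an interior maximum at coded
(0.8583, 0, 0.268) — NaOH 53.58 %, ratio 18, 128 min — of 865.7 kDa.

**Two objectives.** Dominance respects each objective's sense
(minimization is sign-flipped internally; reports are in natural units).
Two Pareto solvers are implemented and cross-checked:

* a deterministic lattice oracle: evaluate both surfaces on a full grid
  (default 201 points per axis, 8.1M points; hard cap 2·10⁷) and keep the
  nondominated set with an O(n log n) sort-and-scan (two objectives; ties
  grouped so duplicates survive) or a vectorized pairwise sweep (≥3);
* NSGA-II: fast nondominated sorting, crowding distance (boundary
  solutions get infinite crowding), binary tournament on (rank, crowding),
  simulated binary crossover (p = 0.9, η = 15), polynomial mutation
  (p = 1/k per gene, η = 20), population 100 for 200 generations, all
  randomness through one seeded `numpy` generator. Only the population
  size is a study-prescribed setting; the rest are standard NSGA-II
  defaults, and correctness is asserted against the lattice oracle rather
  than against GA internals.

For the max-DD/max-MM problem the GA front is required to lie within the
oracle's dominance hull to (0.05 DD, 1 kDa), and across five seeds the
symmetric front distance stays below 1 % of each objective's range. For
the max-DD/min-MM problem the front spans a far larger objective range
(the quadratic extrapolates to negative MM near the corners — the model
is a local approximation, and predictions there are extrapolation, not
chemistry), so absolute-kDa hull tolerances are not meaningful; that
problem is verified through its substantive property — MM below 200 kDa
occurs only where DD ≲ 97.5 % — on both the GA and oracle fronts, plus
mutual nondominance and nondominance of the reference trade-off points.

## Synthetic data

`simulate_responses` draws response = true-surface(run) + N(0, σ²) per
design run, homoscedastic per response: with only three centre replicates
there is no basis for a richer error model, although the centre spread of
the MM response (820/804/670 kDa) hints at larger error for that response
— noted, not modelled. Default σ are calibrated to the reduced fits'
residual standard errors, 7.6 % (DD) and 98.7 kDa (MM). Percentage
responses outside [0, 100] are flagged, not truncated. One named
`numpy.random.Generator` carries all randomness; a fixed config seed gives
bitwise-identical tables. `recovery_experiment` wraps the
simulate-fit loop and reports per-coefficient bias, empirical sd and 95 %
t-interval coverage; at 500 replicates coverage sits within ±0.03 of
nominal and bias within a tenth of the noise sd.

What passing these checks shows — and does not. They validate the
estimator and the optimization machinery on data that truly follow a
quadratic surface with i.i.d. Gaussian error; they cannot validate the
quadratic approximation itself, heteroscedastic or drifting experimental
error, or any wet-lab step upstream of the response table.

## Numerical and scope choices

* Fits use the coded values exactly as recorded (±1, ±1.68, 0).
* Rank deficiency raises with the offending term list; n ≤ p is rejected.
* The lattice oracle's grid includes the box corners exactly (linspace).
* Problem sizes in the shipped drivers and tests — 201 points per axis for
  oracle verification, 500 Monte-Carlo replicates, 5 GA seeds — were chosen
  as the smallest sizes at which the verified properties are stable.
* Yield is carried through tables but never modelled.
* 3-D surface rendering is out of scope; all outputs are numeric tables.

## Known limitations

* One reference trade-off row of the max-DD/min-MM study (coded 1.07,
  −1.48, −1.21 → DD 94.9, MM 72.5) is mutually inconsistent with the
  reduced surfaces, which predict DD 91.0 and MM 165.7 there; it is
  excluded from verification as a recording error. The other eight
  reference rows reproduce within 0.05 % DD / 2.7 kDa.
* The reduced DD surface exceeds 100 % DD near the most favorable corner
  of the box (up to ≈ 101 %); optimization treats the polynomial as given,
  so front segments beyond 100 % DD are model artifacts to be read as
  "essentially complete deacetylation".
* The GA returns a finite sample of the continuous front (≤ population
  size); the lattice oracle resolves the front only to its grid spacing.
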