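# Methods

## Life-table model

The package analyses single-sex (parthenogenetic) cohorts censused at a
fixed 24-h cadence. Age `x` is an integer number of days with `x = 0` at
hatch, so `l_0 = 1` exactly and generation time `T` is in days since hatch.
The discrete schedules are

- survivorship `l_x = n_x / n0`,
- fecundity `m_x = b_x / n_x` (offspring · female⁻¹ · day⁻¹),

and the scalars `R0 = Σ l_x m_x`, `T = Σ x l_x m_x / R0` and
`r ≈ ln(R0)/T`. Assumptions: no immigration; all founders are censused on
day 0; neonates recorded on day `x` are attributed to mothers alive at that
census. Females lost during plate transfers are treated as deaths on the
day of loss in life-table mode; the optional per-day `censored` column is
honoured only by the Kaplan–Meier utilities (the classical life-table sums
have no censoring concept).

Conventions at the edges:

- `m_x := 0` where `n_x = 0`. Such ages contribute nothing to `R0` or `T`,
  and a positive `b_x` at an extinct age is rejected as a data-integrity
  error rather than silently divided.
- `R0 = 0` makes `T` and `r` undefined; results carry an explicit
  `undefined_T_r` flag, never a bare NaN. `R0 ∈ (0, 1)` gives a negative
  `r`, which is a legal value (declining cohort), flagged `negative_growth`.
- Report rounding is half-up (ties away from zero): 1 decimal for days and
  percentages, 2 decimals for `r`, matching the precision of standard
  life-history tables.

## Exact intrinsic rate

Alongside the `ln(R0)/T` approximation the package solves the Euler–Lotka
equation `Σ_x e^(−r x) l_x m_x = 1`. The left side is strictly decreasing
in `r` whenever reproduction occurs at a positive age, so the root is
unique; it is bracketed by geometric expansion from `[−1, 1]` and solved
with Brent's method (`xtol = 1e−14`, residual checked below `1e−10`). When
`R0 = 1` the root is exactly 0 and is returned without iteration. The exact
rate is an internal cross-check: summaries and contrasts that mirror the
published tables always use the approximation, with `r_exact` reported
side by side. The two coincide exactly when reproduction is concentrated at
a single age, which the tests exploit.

Cell means can be formed two ways when replicates are nonlinear functions
of each other (per-replicate `r` averaged, vs. `r` of averaged `R0`/`T`).
The aggregation layer averages per-replicate values — the convention that
reproduces the published fed-high mean, where `ln(mean R0)/mean T` does
not — and the replicate check derives `r` from printed `R0`/`T` only for
the control cell where both conventions agree at printed precision.

## Aggregation and contrasts

Cells are (generation × treatment × feeding); cell statistics are the mean
and sample SD (ddof = 1) over replicate cohorts. "Mean F_k" rows are the
unweighted average of the fed and starved cell means, with their SD
recomputed across those two means (descriptive only — it is not a pooled
SD). Cohorts with undefined `T`/`r` are excluded from those two metrics
only. Empty design cells are rendered `ND`, never zero.

Percent change is `100·(focal − baseline)/baseline`, rounded half-up to
1 decimal in reports. Two families are emitted: each UVB level vs. the
same-generation control, and F5 vs. F1 within treatment. The baseline
feeding scope is selectable (`fed`, `starved` or `mean`, default `mean`)
because published analyses mix scopes: the high-UVB F1 lifespan decline
(−33.0%) reproduces only from the fed rows, while the low/mid percentages
reproduce from the mean rows. The replicate check therefore pins that one
contrast to the fed scope and flags rather than hides the inconsistency.
Two published F5-vs-F1 lifespan percentages (28.6%, 31.0%) are not
derivable from any printed row pair and are excluded from the check.

## Inference layer

- **Two-way ANOVA** on exposure survival uses the proportion alive per
  replicate dish as the response (the published residual mean square,
  0.02, is on the proportion scale); an arcsine-square-root option exists
  but is off by default. Sums of squares are sequential (Type I) via
  nested least-squares fits, identical to Type III on the balanced
  4 × 3 × 16 design, whose residual df is 180.
- **Tukey HSD** uses the residual mean square and df of the full two-way
  model with the studentized-range distribution, and the Tukey–Kramer
  standard error for unequal group sizes. No additional multiplicity
  correction is layered on top.
- **Kaplan–Meier / log-rank** are product-limit and observed-vs-expected
  computations from first principles (hypergeometric variance, ties
  handled by the standard formula); `lifelines` appears in the test suite
  only as an oracle. With no censoring the KM estimate equals the
  empirical survival function exactly. These stand in for proportional-
  hazards machinery deliberately left out of scope.
- **Bootstrap** CIs resample founding females with replacement within a
  cohort (the natural exchangeable unit), rebuild the census and recompute
  the metric; percentile intervals, mandatory seed, B ≥ 200. Resamples
  with undefined metrics are dropped; if they exceed half of B the
  interval is flagged wide. Percentile intervals are asymptotic, so
  near-nominal coverage is verified at 50 founders per cohort; at the
  experimental plate size (9 founders) they should be read as rough
  uncertainty summaries.

## Synthetic cohorts

The simulator reproduces the study *design*, not rotifer physiology:

- **Exposure survival**: `n_alive ~ Binomial(50, p(generation, treatment))`
  per dish, 16 dishes per cell, 4 treatments × 3 exposed generations. The
  default `p` table encodes near-complete control survival and
  dose-dependent mortality steepening across generations (F4 declines of
  22/50/59% vs. control at low/mid/high), the qualitative pattern the
  published design shows.
- **Life-table cohorts** are individual-based: founders die by a daily
  Bernoulli trial with discrete Gompertz hazard `h(x) = h0·e^(g·x)` clipped
  to [0, 1] (terminal hazard forced to 1 at a 400-day horizon), and while
  alive produce `Poisson(λ(x))` neonates per day with a trapezoidal
  `λ(x)`: zero before maturation age `a_m`, plateau `λ_max`, then a linear
  senescent decline. These are the simplest forms able to span the
  observed ranges (lifespans ~20–70 d, T ~1–21 d, R0 ~0.1–35). Closed
  forms follow directly: `S(x) = Π_{u<x}(1−h(u))`, `E[lifespan] = Σ S(x)`,
  `E[R0] = Σ S(x)λ(x)`.
- **Calibration** (`study_scenario`): per design cell, `h0` is solved by
  geometric bisection so `E[lifespan]` matches the published cell mean
  (with `g = 0.10 day⁻¹` fixed); the trapezoid's plateau and decline are
  fixed at 0.6·T and 0.8·T and the integer maturation age chosen so the
  expected `T` is closest to the published mean (exact for lifespan and
  R0, within the half-day granularity of an integer `a_m` for `T`);
  `λ_max` then scales `E[R0]` onto the published mean exactly. Starved and
  F5 cells need no separate effect multipliers because each cell is
  calibrated to its own published mean; explicit multipliers on `λ_max`
  and the hazard remain available through `CellParams` for effect-direction
  experiments.
- **Replicate structure** follows the study: plates of 9 founders; 5 fed
  plates for F1-low and F5-low/mid, 3 otherwise; 3 starved plates per
  cell; no F5 × high cell (ND). Each replicate is a 9-founder plate — the
  reading of the design under which a per-cohort census is well defined —
  and the founder count is configurable.

What the simulator does **not** emulate: pigment kinetics or any
mechanistic UV damage/repair, correlations between survival and fecundity
beyond those the shared hazard induces, day-to-day environmental variation
(food, temperature), overdispersed clutches, or measurement error in the
census. Passing tests therefore demonstrate the pipeline's correctness on
data with the assumed independence structure, not the biological fidelity
of those assumptions.

## Determinism and problem sizes

Every stochastic stage consumes an explicit seed; the design iterates
cells in sorted order with per-cell child seeds (`SeedSequence.spawn`), so
identical scenario + seed give byte-identical CSVs. Tests and the
acceptance script use deliberately modest sizes — 200 cohorts of 500
founders for parameter recovery, 1000 replicates for the log-rank null
calibration, 200 bootstrap cohorts of 50 founders — chosen as the smallest
designs whose Monte-Carlo error (3·SE bands, ±2 points on a rejection
rate) is still decisive for the property being checked.

## Known limitations

- Life-table sums ignore right-censoring; heavy censoring would bias
  `l_x` downward relative to a KM-based analysis.
- The exposure ANOVA treats dish proportions as approximately normal;
  with proportions near 0 or 1 the arcsine option (or a GLM, out of
  scope) is more appropriate.
- Sequential SS differ from Type III on unbalanced designs; the package
  documents and tests the balanced case the design prescribes.
- The calibrated scenario matches first moments per cell; published SDs
  are not targeted, so simulated between-replicate variance need not
  match the study's.
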