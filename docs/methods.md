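# Methods

## Accounting model

The demand side follows the classical ecological-footprint account. Each
consumption item occupies biologically productive area:

- biological items: `area [hm²] = production [t] × 1000 / global average
  yield [kg/hm²]` (the tonnes→kg factor is fixed at 1000);
- energy items: `area [hm²] = consumption [GJ] / global average energy
  footprint [GJ/hm²]`. Fuels occupy fossil-energy (CO₂-absorption) land;
  secondary energy (electricity, heat) is attributed to built-up land via
  the coal-equivalent footprint. Accounts are accepted directly in GJ; a
  `convert_coefficient` (GJ/t) column is carried as metadata for accounts
  kept in physical units.

Item areas are summed per land type, divided by the resident population,
weighted by equivalence factors `w_j` and summed to `ef`. Yield factors do
**not** enter the demand side: although some presentations write the demand
formula with `y_j` in the denominator, published balance tables (including
the packaged study) are computed without it, and capacity is where local
productivity matters. An account item can be flagged
`in_demand_aggregate=false` to keep its per-item footprint in
reconstructions while excluding it from the land-type aggregation; the
packaged study needs this for exactly one item (see below).

The supply side is `EC = Σ_j w_j · y_j · A_j`, `ec = EC/N`. The
biodiversity deduction is multiplicative: `available = (1 − b)·ec` with
`b = 0.12` by default (configurable in the factor table). Fossil-energy
land has `y = 0`: no land is actually reserved for CO₂ absorption, so it
contributes demand but never capacity. The deficit is
`ED = ef − available`; its sign distinguishes deficit from surplus.

Default factors (equivalence: arable 2.51, forest 1.26, pasture 0.46,
water 0.37, fossil-energy 1.26, built-up 2.51; yield: arable/built-up 1.66,
pasture 0.19, forest 0.91, water 1.0, fossil-energy 0) are the constants of
the packaged study region; both sets are plain configuration and carry no
internal normalisation.

## GM(1,1)

For a positive series `x⁽⁰⁾(1..n)`, `n ≥ 4`, the accumulated series
`x⁽¹⁾ = cumsum(x⁽⁰⁾)` is modelled by `dx⁽¹⁾/dt + a·x⁽¹⁾ = u`. The
discretisation uses background values
`z(k) = w·x⁽¹⁾(k) + (1−w)·x⁽¹⁾(k−1)` with `w = 0.5` by default (the
half-sum construction; configurable). `(a, u)` solve the ordinary least
squares problem `x⁽⁰⁾(k) ≈ −a·z(k) + u`, k = 2..n, via `numpy.linalg.lstsq`
on the 2-column design matrix. The time response is anchored at the first
observation, `x̂⁽¹⁾(t+1) = (x⁽⁰⁾(1) − u/a)·e^(−a·t) + u/a`, and restored
values are first differences, so `x̂⁽¹⁾(1) = x⁽⁰⁾(1)` exactly and restored
values for k ≥ 2 form a geometric sequence with ratio `e^(−a)`.

Numerical choices:

- `|a| < 1e-10` switches to the flat-series limit (`x̂⁽⁰⁾ ≡ u`, flagged
  `degenerate`) to avoid the `u/a` blow-up on constant input;
- a rank-deficient design raises `FitError` rather than returning noise;
- accuracy grading uses the mean relative error of one-step restored values
  over k = 2..n, with an inclusive ladder ≤1% excellent, ≤3% good,
  ≤5% qualified, else unqualified (thresholds configurable). On a tie the
  better grade wins.
- with n observed years the first forecast step is year n+1 (time index
  t = n in the response).

A series generated from the *discrete* recursion
`x⁽⁰⁾(k) = (u − a·x⁽¹⁾(k−1)) / (1 + a/2)` makes the least-squares system
exact, so the fitter recovers `(a, u)` to machine precision — this is the
oracle used throughout the tests. Restored values still differ from such a
series by the discrete-vs-continuous gap (order `a²`), which is why the
mean relative error on oracle series is tiny but not zero.

## Pipeline

`build_annual_table` runs both account sides per year;
`run_balance_forecast` fits GM(1,1) to the demand column and one supply
column and differences the forecasts into a deficit path.

- `ec_series_mode` selects the supply series: `raw_ec` (default) fits the
  undeducted `ec` column and uses its forecasts directly as the available
  supply; `available_ec` fits the 0.88-deducted column. The default mirrors
  the packaged study, whose published supply model is anchored at the
  undeducted 2013 value even though it is labelled "available"; the
  self-consistent alternative is one flag away and both are emitted by the
  reporting layer without guessing intent.
- `round_decimals` optionally rounds the fitted series to report precision
  first. The study-reproduction path passes 4 because the published model
  coefficients derive from the published 4-decimal table; fitting the
  full-precision recomputed 2017 row instead shifts the supply asymptote by
  ~0.2%.
- Reports round per-capita values to 4 decimals and totals to 0.1 hm²;
  all internal arithmetic is full precision. Writers are deterministic
  (stable column order, no timestamps), so re-running on emitted CSVs is
  byte-identical.

## Packaged study fixtures

The fixtures transcribe the published five-year account of an eight-city
lower-Yangtze urban agglomeration: item-level biological (17 items) and
energy (14 items) accounts and land areas for 2017, the published annual
per-capita series 2013–2017, and the factor configuration. 2013–2016 have
no published item-level data, so the balance table carries their published
per-capita ef/ec directly and recomputes the derived columns; 2017 is
recomputed from the item level.

Three calibrations were unavoidable, each solved from published (total,
per-capita) pairs rather than guessed:

- the resident population is not published; `N = 43,344,500` is the value
  (feasible interval ≈ 43,344,250–43,344,550) for which every reproducible
  published per-capita cell rounds correctly at its printed precision;
- the tea item's published yield (566 kg/hm²) contradicts its own published
  production and footprint total; the fixture carries the implied yield
  826.1377 kg/hm² so the total and all downstream cells reproduce;
- the melon-and-fruit item is published in the account but excluded from
  the published arable aggregation (the arable sum matches only without
  it); the fixture flags it `in_demand_aggregate=false`.

Two published cells are internally inconsistent beyond repair and are
asserted only at the attainable precision: the 2016 deficit (printed
1.5710, exact arithmetic gives 1.5709) and the water equivalence area
(printed 0.6615, exact 0.6614).

## Synthetic data

The generator emulates the structure the pipeline assumes: per-capita
demand/supply trajectories satisfying the grey recursion (defaults: demand
near 1.5 hm²/person decaying ~5%/year, supply flat near 0.36 hm²/person —
the scale of a densely populated urban region), optional multiplicative
lognormal noise (mean-1 factors; lognormal keeps the series positive, which
GM(1,1) requires), and item-level accounts solved back from the
trajectories: footprint shares per land type are fixed, split across items,
and scattered across cities by seeded Dirichlet draws. Every stochastic
output is a pure function of (spec, seed).

What synthetic data does not emulate: reporting gaps and interpolation,
heterogeneous per-item yields, correlated shocks across land types, and
population change. Passing tests therefore demonstrate correctness of the
accounting arithmetic and the estimator on well-formed inputs, not
robustness to messy yearbook data.

A Monte-Carlo envelope for noisy recovery (median `|â − a|` ≈ 0.014 at
5% noise, n = 5, 200 replicates) was computed once with an independent
generic least-squares oracle and frozen into the test (bound 0.02).

## Limitations

- GM(1,1) only: no GM(1,N), Verhulst or rolling variants, and no
  posterior-variance-ratio test; forecasts are monotone by construction and
  cannot reproduce turning points.
- Cities exist only as account columns; no per-city footprints.
- Equivalence/yield factors are taken as configuration constants, not
  derived from calorific-value data.
- The published model-checking "relative error" figures for the study
  (1.51%/3.10%) do not correspond to any standard metric on the published
  series; the accuracy report exposes the standard one-step relative errors
  instead.
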