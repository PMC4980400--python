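# Methods

## Model

`ecea` implements a single-period, static disease model over a stratified
population.  Stratum *k* has *N_k* persons with mean income *y_k*, disease
incidence *i_k* (events per person-year), case fatality *CFR_k*, a fraction
*u_k* of cases that seek care and pay out of pocket, and per-case
out-of-pocket costs *c_DM,k* (direct medical) and *c_DNM,k* (direct
non-medical).  Indirect costs *c_I,k* are carried as data but excluded from
all expenditure arithmetic unless `include_indirect=True`; productivity
losses are a different accounting perspective and most published analyses
restrict to out-of-pocket costs.

A policy raises coverage from `cov_baseline` to `cov_policy` with
effectiveness `Eff`, at `unit_cost` per covered case, and displaces a
fraction `crowd_out` of out-of-pocket payment among paying cases.  There is
no disease transmission, no discounting, and no multi-year horizon: all
quantities are annual expected values, carried as exact reals and rounded
only at the reporting layer.

### Coverage semantics

Three distinct coverage roles are deliberately kept separate, because the
canonical worked example uses them differently:

* **Health gains** scale with the coverage *increment*
  ΔCov = cov_policy − cov_baseline (default `coverage_basis="incremental"`;
  a `"total"` basis using cov_policy is exposed for sensitivity analysis —
  the two are not equivalent and the incremental reading is the one that
  matches intervention-scale-up questions).
* **Implementer costs** price `cov_costing × caseload` cases; `cov_costing`
  defaults to cov_policy but can be set independently (the Land fixture
  prices 50% of cases while post-policy treatment coverage is 60%).
* **Private-expenditure aversion** defaults to the crowd-out convention
  `PE_av = crowd_out × PE` (public finance displaces the payment of every
  paying case); the alternative coverage convention
  `PE_av = cov_policy × PE` is a named switch.

### FRP metrics

All three metrics compare the population before and after the policy, where
"after" multiplies each paying case's out-of-pocket cost by
`(1 − crowd_out)`; event probabilities are unchanged (treatment financing
does not prevent disease).  Thresholds are strict, so boundary cases — a
payment exactly at `y × Th`, or a payer landing exactly on the poverty
line — are *not* counted; ties break toward "not a case".  Counting metrics
return expected (real-valued) counts: a stratum's paying caseload is spread
uniformly over its income grid and the indicator integrated, so fractional
counts are meaningful and are rounded only when printed.

The poverty metric takes an explicit *affected-case fraction* — the share of
the stratum's caseload exposed to impoverishment.  By default it falls back
to the stratum's paying fraction *u_k*; the Land fixture sets it to 0.8, the
documented reading that reproduces the canonical 3,200 poverty cases averted
(0.8 × 4,000 middle-quintile cases) and the $313 FRP ICER, whereas the
*u_k* = 0.40 reading yields 1,600.  Both readings are asserted in the test
suite; the package takes no position beyond parameterizing the choice.

The insurance metric uses CRRA utility `w(y) = y^(1−r)/(1−r)`.  The default
`r = 3` is the conventional "high risk aversion" value in this literature,
exposed in `FrpConfig` because opinions on *r* diverge.  `r = 1` is handled
by the logarithmic limit (the CRRA family is continuous there; a test checks
that the power form at `r = 1 ± 1e−4` brackets the log-form premium).  The
premium requires positive net income, so `income > cost` is validated at the
gamble level and per grid point at the population level, with the stratum
named in the error.  Degenerate gambles (`p ∈ {0, 1}` or `c = 0`) return a
premium of exactly 0.0 rather than a rounding-error residual.  Post-policy,
the gamble's cost shrinks by crowd-out (default), optionally by
`crowd_out × cov_policy` (`convention="coverage"`), and an optional
`prevention` mode additionally shrinks the event probability by
`Eff × ΔCov` for preventive interventions.

### Income model

Incomes are per-capita annual; household aggregation is the caller's
responsibility.  Three families:

* **point** — every individual at the stratum mean (the worked example);
* **gamma** — calibrated from (mean, Gini) via the closed form
  `G(a) = Γ(a+½)/(Γ(a+1)√π)`, which is scale-free and strictly decreasing in
  the shape *a*, inverted with Brent's method on `a ∈ [1e−8, 1e8]`
  (`xtol=1e−12`); the scale is then `mean/a`.  Calibration round-trips to
  1e−8 in Gini across `gini ∈ [0.2, 0.7]` and means spanning 10–10⁵;
* **empirical** — a sorted sample, loadable from a single-column CSV.

Population integrals use *n* equal-probability representative incomes, each
the distribution's conditional mean within its probability slice, computed
from the Gamma partial-expectation identity (the partial expectation below
*x* is `mean × F_{a+1}(x)`) or, for empirical samples, by exact
fractional-mass slicing.  Conditional means — unlike quantile midpoints —
preserve the distribution's total expectation, which the
expenditure-weighted counts rely on.  The default resolution
`income_grid_n = 10,000` makes discretization error in the counting metrics
~10⁻⁴ relative, far below the 1% Monte-Carlo comparison bands used in the
tests; it is a config knob, not a calibrated constant.

### Ratios and scalings

`ICER = C_total / B_total` with a status field instead of infinities: a zero
denominator reports `"undefined"`, a negative ratio `"dominated"`.  Rounding
to the nearest currency unit is half-away-from-zero (312.5 → 313), with the
unrounded value retained in JSON output.  Per-budget scaling multiplies
every panel by `budget / C_total` and requires a strictly positive total
cost; it is linear, so per-$100,000 values are exactly one tenth of
per-$1-million values.

## Synthetic scenarios

`generate_synthetic_scenario(seed, n_strata, gradients)` emulates the
structure of real ECEA inputs: strictly increasing stratum incomes around a
drawn mean, a disease burden gradient (pro-poor by default — incidence
declining with income, the typical social gradient of infectious disease;
pro-rich and uniform variants available), shared case fatality and
care-seeking, and a policy whose coverage gain, effectiveness, and unit cost
fall in ranges typical of treatment-financing analyses.  Out-of-pocket costs
are capped below the poorest stratum's income so the CRRA metric is always
defined.  What it does **not** emulate: correlated parameter uncertainty,
household structure, survey weights, multi-disease interactions, or
behavioural responses to financing — so green tests demonstrate the
arithmetic and its invariances (linearity, permutation invariance,
zero-burden propagation), not calibration to any real country.

## Numerical and design notes

* All panel arithmetic is exact elementwise algebra on float64; no
  stochastic step exists anywhere in the pipeline, so `run_ecea` is
  bit-reproducible and output files are byte-stable.
* Scenario validation is eager and named: every invariant violation reports
  the field and the stratum label.  Disinvestment (coverage decrease) warns
  rather than errors and produces negative health gains.
* Incidence may be declared per 100,000/yr (`incidence_per_100k`) or as a
  probability (`incidence`); it is stored canonically per person-year.
  Scalar policy parameters broadcast to all strata.
* Problem sizes in the test suite — 200,000-draw Monte-Carlo Gini and
  counting oracles, a 10,000-point random premium sweep — were chosen so
  each check's sampling error sits well inside its assertion band while the
  whole suite completes in seconds.

## Known limitations

Single period, no discounting, no herd effects; FRP metrics ignore coping
mechanisms (borrowing, asset sales, consumption smoothing); the money-metric
insurance value assumes a single CRRA coefficient for everyone; competing
accounting between health gains and FRP (deaths removed from the paying
pool) is not modelled; no probabilistic sensitivity analysis beyond what the
caller scripts over scenarios.
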