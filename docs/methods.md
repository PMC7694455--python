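# Methods

This note records the statistical models phenokit implements, the
assumptions behind them, the defaults and why, and the choices made where
the design was genuinely open. Nothing here states an empirical result the
test suite or `scripts/acceptance.py` does not itself compute.

## Thermal time

Daily units are `max(0, (T_max + T_min)/2 − T_base)` with `T_base = 1 °C`
by default, appropriate for winter-annual grasses and winter wheat; a day
whose mean is at or below the base contributes exactly zero. The sowing
day's own units are included in the cumulative sum, so the value the day
before sowing is zero — "time from sowing" should count growth on the
sowing day. Series carry a source tag (`air`/`soil`) because emergence is
driven by soil temperature and above-ground development by air
temperature; downstream code can check the tag but does not hard-fail on
it. Gaps in the daily record are an error by default; with
`allow_gap_fill=True` isolated single-day gaps (only) are linearly
interpolated. Hourly integration and per-species base temperatures are
out of scope.

## Emergence (grouped time-to-event)

Quadrat inspections yield interval-censored emergence times: `d_j`
seedlings first seen at inspection `j` emerged in `(t_{j−1}, t_j]` and
contribute `d_j · ln[E(t_j) − E(t_{j−1})]` to a multinomial
log-likelihood, where `E` is the two-parameter log-logistic CDF on the
thermal-time axis. Two censoring conventions are supported:

* **conditional-on-emergence** (default): the final observed count is the
  emerging population; this reproduces curves normalized to 0–100% of
  final emergence and needs no knowledge of viable seed numbers;
* **right-censored** (`use_censoring=True` with `n_sown`): seeds never
  observed emerged add `(N − n_k) · ln[1 − E(t_k)]`. Simulation code uses
  this form since the generator knows the sown population; the
  conditional fit is mildly biased when a nontrivial fraction of seeds has
  not emerged by the last inspection.

Optimization is over `(b, ln GERM50)` (BFGS with a Nelder–Mead polish,
objective tolerance 1e-8), started from a logit-linear regression of
empirical cumulative proportions on `ln t`. The covariance is the inverse
observed information (numerical Hessian); a non-positive-definite Hessian
clears the `converged` flag. The slope is stored with the convention that
`b < 0` gives an increasing curve, matching how such fits are tabulated;
a positive fitted slope sets a `sign_flipped` warning flag rather than
being silently negated.

Quantiles use the closed form `t_p = GERM50·((1−p)/p)^{1/b}`, with
confidence intervals by the delta method on `ln t_p`
(gradient `(−ln((1−p)/p)/b², 1)` against the `(b, ln GERM50)`
covariance). Whether the original analyses used the delta method or a
reparameterized refit is not stated anywhere; the delta method is adopted
and labelled. Identifiability requires occupied counts in at least two
distinct interval cells; all emergence inside a single interval raises an
error rather than returning a ridge solution. Pairwise comparisons are
two-sided Wald t-tests with a normal reference, on the degree-day scale
for `GERM50` and quantiles.

Note on reproducing printed tables: published parameters are rounded
(slopes to 2 significant figures), so recomputed quantiles occasionally
miss a printed integer by one; the identity `GERM10·GERM90 = GERM50²`
holds exactly for any parameters.

## Growth curves

Per-plant dry matter over thermal time is fitted by ordinary least squares
on the original scale (no variance model was specified in the source
analyses; a heteroscedasticity-robust or log-response variant is easy to
add but deliberately not a default). Families:

* **Weibull/Gompertz-type** `Y = d·exp(−exp(−|c|(ln t − ln e)))`. Summary
  tables in this literature print positive `c` while the curve increases;
  the implementation applies the rate as `−|c|` inside so the curve is
  increasing for either sign, and reports `|c|`.
* **log-logistic** `Y = d/(1 + exp(c(ln t − ln TIME50)))`, increasing for
  `c < 0`, slope reported as fitted (negative).

The year-specific family choice (Weibull for a drought-compressed season,
log-logistic for a normal one) is configuration (`family_by_year`), not
code. `TIME50` is the fitted location for the log-logistic and
`e·(ln 2)^{−1/|c|}` for the Weibull; because the printed "TIME50" column
for Weibull fits is ambiguous between the scale parameter and the computed
half-time, reports emit both (`timing` and `time50`). Starting values pin
`d` at 1.05·max(y), locate the half-rise from the per-time mean profile,
and profile the rate over a coarse grid — with only six sampling times the
rate's objective surface is nearly flat and a poor start can drift to
meaninglessly large `|c|` without affecting `d` or the half-time.

Lack of fit is the classical F-test of the 3-parameter curve against the
saturated one-mean-per-time model (needs replication; `p > 0.05` read as
adequacy). The suppression ratio is `d₊/d₋` with first-order delta SE
`r·√((se₊/d₊)² + (se₋/d₋)²)` and a two-sided Wald test of ratio = 1 —
the null the published `p < 0.001` values implicitly test.

## Interval-censored phenology

BBCH attainment is only known to the interval between consecutive
inspections. Rather than fixing a point in each interval (results would
depend heavily on the convention), exact times are integrated out by
Monte Carlo: per iteration, one `Uniform(t_lo, t_hi]` draw per plant,
statistic `S_i = |mean_A − mean_B|`, then one label permutation of the
imputed values giving `S*_i`, and
`p = (1 + #{S*_i ≥ S_i}) / (1 + n_iter)` (add-one estimator; unbiased
conservative under the null). How imputation and permutation interleave
was an open choice; one imputation + one permutation per iteration is the
adopted contract and is recorded in the result object. The reported
statistic is the imputation-average of `S_i`. Ties — permutations that
reproduce the observed grouping — are counted as "at least as extreme"
with a 1e-9 relative tolerance; without it, summation-order float noise
silently drops half the tie mass and deflates p by several percent at
small n (found against an enumeration oracle).

Bootstrap CIs resample plants with replacement and re-impute within each
resample; the interval is the percentile interval and the point estimate
the mean of resampled means. Resampling indices and imputation draws come
from independent substreams (`Generator.spawn`), so with degenerate point
intervals the procedures coincide *exactly* with the textbook permutation
test and percentile bootstrap driven by the resampling stream — the test
suite asserts this bitwise. Pairwise species comparisons are emitted
without multiplicity adjustment, mirroring post-hoc reporting style.
Plants that never reached a stage are simply absent from the input;
parametric interval-censored survival models (Turnbull/AFT) are out of
scope.

## Fecundity

Seeds-per-panicle is regressed on panicle length by straight-line OLS
(intercept included; the source describes only a "correlation", and a
line with intercept is the weakest assumption that yields one). Negative
per-panicle predictions clamp to zero; plant totals round to the nearest
seed. Calibration pools crop treatments by default (the crop effect on
the relation was reported nonsignificant). The suppression ratio is the
ratio of group means — the ratio-of-means and mean-of-ratios readings of
published tables differ for one season's ryegrass row (printed 0.20
versus 0.18 from the printed means); ratio-of-means is primary here.
Inference: permutation test on the absolute mean difference (1000
permutations default) plus a percentile-bootstrap CI of the ratio (10,000
resamples default), again on independent substreams.

## Competition

The rectangular hyperbola `Y = a/(1 + x/DENS50)` is fitted by least
squares with `DENS50` parameterized on the log scale to enforce
positivity; `se(DENS50) = DENS50·se(ln DENS50)` by the delta method.
Starting values: `a` from the zero-density cell mean, `DENS50` from the
density whose mean response is nearest `a/2`. A flat response drives
`ln DENS50` into its (very wide) upper bound and is flagged
non-converged instead of returning an arbitrary huge estimate. The fitted
`DENS50` is invariant to rescaling the response; comparisons are Wald
t-tests.

## Synthetic data

The generator emulates the six input streams with exactly the
distributional structure the models assume, so round-trip tests verify
the fitters against known truth:

* weather: sinusoidal annual mean (coldest mid-January, Danish coastal
  magnitudes: mean 8.5 °C, amplitude 7.5 °C) with Gaussian daily noise;
  soil series damped 0.75× and offset +0.8 °C;
* emergence: i.i.d. log-logistic event times
  (`ln T ~ Logistic(ln GERM50, −1/b)`), tallied at the inspection
  schedule; 6 quadrats × 500 seeds by default (the scale at which the
  recovery guarantees are stated);
* biomass: family curve + Gaussian noise (10% of `d`), truncated at zero,
  6 thermal times × 3 plots;
* phenology: latent Normal(stage mean, 40 °C) attainment bracketed by a
  100 °C inspection grid;
* fecundity: log-normal panicle lengths, Poisson seed counts with mean
  `slope·length`, crop presence thinning expected panicle number by the
  configured suppression ratio; 30 calibration panicles and 15 plants per
  treatment (5 collected plants × 3 blocks of the field design);
* competition: hyperbolic mean + Gaussian noise (10% of `a`) on the
  0–576 plants/m² six-density design, 4 replicates.

Named scenarios bundle published estimates as generating truth
(emergence and Weibull-growth parameters for 2017/18, log-logistic for
2018/19, DENS50 values for the pot experiment; per-harvest `a` values and
pre-seed-shedding stage means are plausible inventions at field
magnitudes since they were published only graphically or not at all).
What the generator does **not** emulate: spatial correlation within
plots, overdispersion beyond Poisson/Gaussian noise, dormancy or
staggered cohorts, weather autocorrelation, and observation error in
thermal time itself. Passing round-trip tests therefore demonstrates
correctness of the estimators under the assumed data-generating
mechanisms, not robustness to real-field violations of them.

## Numerical choices and degenerate inputs

* Optimizer tolerances: 1e-8 objective (emergence), scipy `curve_fit`
  defaults with bounded positivity (growth), 1e-12 ftol/xtol
  (competition).
* Interval probabilities are floored at 1e-300 before logs.
* Degenerate inputs raise typed errors rather than returning garbage:
  inverted temperature records, date gaps, mixed sources, single-interval
  emergence, all-zero biomass, fewer than four sampling times, a single
  pot density, empty resampling groups. A single-plant bootstrap warns
  (the between-plant component is zero-width).
* All stochastic procedures require an explicit seed or Generator and
  record the seed in their result objects; reports regenerate bit-for-bit
  from (config, seed).

## Problem sizes

Defaults mirror the field designs: 1000 permutations and 10,000 bootstrap
resamples for inference. The test suite's simulation studies use 200
replicates per recovery check and 200–500 replicates for error-rate
checks, sizes at which the asserted tolerances (2% bias on GERM50, 5%
median error on `d`, 15% median error on `DENS50`, binomial agreement
with enumeration oracles) are comfortably resolved.

## Known limitations

* Homoscedastic least squares for growth/competition; biomass noise in
  real trials typically scales with the mean.
* The conditional emergence fit ignores seeds that never emerge; use the
  censored variant when sown numbers are known.
* Quadrat counts are pooled within species × year before fitting
  (treatment pooling is configuration); no mixed-effects structure over
  plots.
* Pairwise tests are unadjusted for multiplicity by design (post-hoc
  reporting style); a Holm correction is a one-liner on the report frame
  but is not applied.
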