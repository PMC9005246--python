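# Methods

## Stage 1: time-varying DLNM and attributable fractions

### Model

Daily death counts `Y_t` over the May–September season are modelled as
overdispersed Poisson with

    log E[Y_t] = α + w(tmean, t) + w'(tmean, t)·s(t)
               + weekday(t) + trend(t) + season(t)

where `w` is the cross-basis of a distributed lag nonlinear model: a tensor
product of a quadratic B-spline in temperature (two interior knots at the
pooled whole-period 50th and 90th percentiles, boundary knots at the
observed range, no intercept) and a natural cubic spline over lags 0–10
days (two interior knots equally spaced on the log-lag scale, i.e. at
10^(1/3) ≈ 2.15 and 10^(2/3) ≈ 4.64 days, intercept kept). The resulting
4 × 4 = 16 cross-basis columns enter once directly and once multiplied by
`s(t)`, calendar date scaled affinely to [−0.5, 0.5] over the study period;
this linear-in-date interaction lets the exposure-response surface drift
(long-term adaptation) and is exactly zero at the recorded centring date.
Controls: a 6-dummy day-of-week factor, a natural cubic spline of date with
one degree of freedom per decade (ceiling, so 4 df for 38 years), and a
natural cubic spline of day-of-season with 4 df. Spline arguments are
rescaled to O(1) before basis construction because the truncated-power
natural basis cubes its argument.

Estimation is iteratively reweighted least squares for the Poisson
likelihood (via statsmodels); the quasi-Poisson dispersion is the Pearson
χ²/(n − p) statistic and scales the coefficient covariance — point
estimates are unaffected. A hand-written IRLS recursion serves as the
independent oracle in the test suite.

### Season boundaries

Exposure histories never cross the September → May gap. The first ten days
of each season have incomplete within-season histories; missing lagged
temperatures are replaced by the season's first observed value (constant
extrapolation) and the affected rows are flagged. Dropping them instead
would discard 6.5 % of the data for little gain; the alternative is
switchable by passing a trimmed series.

### MMT and attribution

The overall cumulative exposure-response curve is retrieved at the first of
July of each year by summing the fitted surface over lags 0–10 on a 0.1 °C
grid spanning the observed temperature range. The minimum mortality
temperature (MMT) is the constrained argmin of that curve between the
pooled 10th and 90th temperature percentiles, with ties broken toward the
lower temperature. Whole-period (not year-specific) percentile bounds are
used, consistent with how the heat-day thresholds are defined.

Daily attributable fractions take the backward perspective:
`AF_t = 1 − exp(−Σ_l η(tmean_{t−l}, l; t))` with the fitted lag-specific
log relative risk `η` under day *t*'s effective (time-varying) coefficients,
referenced to the year's MMT. Annual aggregation keeps only *heat days* —
days with mean temperature strictly above the threshold — for four
definitions: the year-specific MMT itself and the constant whole-period
95th/97.5th/99th percentiles. The AF denominator is total May–September
deaths of the year (so the numbers read as "x % of summer mortality"); the
reference temperature is always the year's MMT, percentile thresholds only
select which days count. Heat-day sets are nested once all thresholds
exceed the MMT, so point-estimate AFs decrease in the percentile — asserted
in the tests.

Empirical confidence intervals redraw the cross-basis and interaction
coefficients from N(coef, vcov) (eigenvalue-floored if needed), recompute
the year-specific MMTs — the percentile constraint is re-solved per draw —
and all AFs, and report 2.5/97.5 percentiles; 1000 draws by default. The
implementation precomputes every coefficient-independent matrix so one draw
costs two matrix-vector products, which is what makes the coverage tests
affordable.

## Stage 2: scalar-on-function regression by boosting

The annual AF is modelled as
`AF_i = Σ_j ∫₀¹⁶ β_j(l) x_ijl dl + s_i + ε_i` over a 17-point monthly lag
grid running from May of year *i* (lag 0) back to January of year *i−1*
(lag 16). The window nominally spans "16 months" but covers 17 calendar
months; the integral bound 0..16 is taken at face value with 17 nodes and
trapezoidal quadrature (exact for linear curves). Each index is z-scored
over all design cells, so coefficient curves are per-SD effects; the
scaling is recorded and reversible.

Each functional coefficient is expanded in a cubic B-spline basis on the
lag grid (5 interior knots, 9 columns) built on uniform *extended* knots
with a second-order difference penalty — the Eilers–Marx P-spline
construction, whose penalty null space contains exact linears (clamped
boundary knots break that property and were rejected). The year smooth is
a dense cubic P-spline with 20 interior knots over the year range. Each
base learner's ridge scale is calibrated by bisection (via a generalized
eigenvalue identity, so no ill-conditioned solves) so that the hat-matrix
trace equals a common effective df. Equal-df learners keep the selection
step of component-wise boosting unbiased toward flexibility.

The common df is 2.5. With n = 38 years and realistic signal
(out-of-sample R² around 0.3) a df-4 learner leaves enough unpenalized
wiggle that the recovered coefficient curve matches the generating shape in
under half of simulated replicates, purely through estimator variance —
noiseless recovery is near-perfect either way. 2.5 df trades a little bias
for a large variance reduction at this sample size.

Boosting is plain L2: at each iteration every learner is fitted by
penalized least squares to the current residuals, the one with the lowest
residual sum of squares is added with step length ν = 0.1, and the stopping
iteration minimises the mean squared prediction error of a seeded 10-fold
cross-validation over iterations 0..m_max (m_max = 1000 by default; fold
counts are capped so folds keep at least two observations). Learners never
selected before the stop have identically zero coefficients. Two known
properties are worth stating plainly:

* the fixed point of single-learner L2 boosting is the *unpenalized*
  least-squares projection onto the learner span — the penalty shapes the
  path, not the limit — and the tests assert exactly that;
* argmin-CV stopping over-selects: inactive indices enter the model in
  roughly a quarter of replicates at moderate signal. Heavier CV averaging
  does not help (the expected CV argmin genuinely sits a few iterations past
  signal exhaustion) and a one-standard-error rule suppresses false
  positives only at the cost of missing the active index. Controlling the
  false-selection rate properly requires stability selection, which is out
  of scope; selection results should be read accordingly.

Pointwise confidence bands for the coefficient curves come from a
nonparametric bootstrap over years with the stopping iteration held fixed.

## Evaluation

Predictive skill is a repeated (default 20×) 10-fold cross-validated skill
score: `R² = 1 − SSE_model / SSE_offset`, both out-of-fold, where the
offset predictor is the training-fold mean. This choice centres the
statistic at zero for signal-free responses; normalising by the total sum
of squares about the overall mean instead would penalise even the
offset-only model by order 1/n_fold out of fold, which at n = 38 is a bias
of about −0.06. Within every training split the boosting re-runs in full,
inner stopping CV included, with seeds independent of the evaluation fold
assignment; held-out years therefore never touch any fitting step (enforced
by a poisoning test). R² can be negative and is reported as-is. The
reported SD is across CV repeats. A sensitivity variant adds the yearly
mean summer temperature as a 1-df linear base learner.

Stage-1 AF point estimates (not eCI draws) feed stage 2; propagating
stage-1 uncertainty into stage 2 is out of scope.

## Synthetic data generator

The generator defines the study conditions all tests run under.

* **Indices**: seven independent stationary AR(1) monthly series,
  standardized; lag-1 autocorrelation 0.9 for the active index (a slow,
  AMO-like oscillation), 0.3 otherwise. Coverage from January of the year
  before the first study year.
* **Temperature**: an annual sinusoid (level 8 °C, amplitude 12 °C, peak at
  day 200) plus AR(1) daily noise (ρ = 0.7, SD 3.5 °C), plus γ times the
  active index's January–May mean added uniformly to the year's days
  (γ = 1.5 °C per index SD). Summer means land around 17 °C with single-day
  extremes near 30 °C — a humid-continental metropolitan profile. A 10-day
  pre-season burn-in gives the mortality model complete lag histories on
  May 1.
* **Mortality**: negative-binomial counts (variance = overdispersion × mean,
  default 1.2; exactly Poisson at 1) around a log-mean with baseline 60
  deaths/day, a −0.10 log-linear trend across the period, a mild
  within-season seasonal bump, weekday effects, and the cumulative lagged
  temperature term.
* **Exposure-response truth**: a piecewise-smooth hockey stick in the
  cumulative log relative risk — flat at the 18 °C minimum, rising through a
  4 °C-wide quadratic ramp to a linear asymptote of 0.03 per °C above, with
  a gentler arm (0.012 per °C, same ramp) below. The C¹ quadratic joins
  keep the truth inside the function class that low-order spline regression
  can represent, which is the premise of a parameter-recovery simulation (a
  hard kink produces an irreducible approximation bias of order 20 % in the
  AF no matter the implementation); the mild cold arm makes the risk
  minimum identifiable, and mildly U-shaped curves are what
  temperature-mortality studies observe. Risk decays geometrically over
  lags (ratio 0.7, normalised). The implied true annual AF above the MMT is
  about 2 %, the magnitude such analyses report.
* **Stage-2 truth**: the functional coefficient linking the active index to
  the AF is a half-cosine over monthly lags 0–5 (recent winter/spring
  matter, the previous year does not). A direct stage-2 response generator
  (`simulate_af_from_indices`) produces AF series with exactly known β and
  noise, decoupling stage-2 tests from stage-1 estimation error.

The `truth_implied_af` oracle computes the generator-implied annual AF in
the forward direction — expected deaths with and without the excess-risk
term — which is the infinite-replicate limit of a with/without forward
simulation.

What the generator does **not** emulate: spatial temperature fields and
their averaging, cause-specific mortality, within-season adaptation (the
true surface is constant over the summer), harvesting/displacement, data
gaps, or cross-index correlation (real teleconnection indices are not
independent). Passing tests demonstrate the estimators recover the truth
under these idealised conditions, not that real mortality data satisfy
them.

## Numerical choices and problem sizes

Tie-breaks: the MMT argmin takes the lowest qualifying grid temperature;
the boosting selection takes the first learner at the minimal RSS.
Degenerate inputs raise informative errors (zero season deaths, constant
index, rank-deficient stage-1 design with the collinear block named,
unattainable learner df). Determinism: every random quantity is driven by
an explicit seed; derived sub-seeds come from `numpy.random.SeedSequence`
spawns and stay below 2³¹.

The statistical test battery uses 50 full-scale stage-1 replicates
(38 years × 153 days, shared across the curve-recovery, AF-calibration and
monotonicity checks), 100 replicates at 500 coefficient draws for eCI
coverage, 50 replicates for stage-2 selection, and 50 permutations at 2 CV
repeats and m_max = 150 for the null-skill check; `scripts/acceptance.py`
uses 1000 eCI draws, 10 CV repeats and a 20-replicate selection experiment.
These sizes keep the full battery at a few minutes on one core while
leaving Monte-Carlo errors well inside the asserted margins.

## Known limitations

* The cross-basis knots are computed per-area on the pooled whole-period
  temperature distribution; the convention is stated, not estimated.
* Whether the date interaction should be linear or spline-in-date is an
  open modelling question; linear is implemented.
* The stage-2 selection false-positive behaviour discussed above.
* Negative out-of-fold R² values are reported as-is; at n = 38 the CV skill
  estimate itself is noisy (single-dataset values scatter widely around the
  oracle skill).
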