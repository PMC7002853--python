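# Methods

## Model and estimands

All estimators assume two independent normal populations
N(μ₁, σ₁²), N(μ₂, σ₂²) (or one normal population and a known constant C)
and independent observations within groups.  Three population effect
sizes are implemented:

* δ = (μ₁−μ₂)/σ — the classical standardized mean difference, defined
  only under a common variance σ²;
* ϵ_r = (μ₁−μ₂)/√((σ₁²+rσ₂²)/(r+1)) — the heteroscedastic effect size,
  indexed by the sample-size ratio r = n₁/n₂.  It reduces to δ when
  σ₁ = σ₂ and, at r = 1, weights the two variances equally.  Because r
  enters the parameter, two values of ϵ are comparable only at the same
  design ratio — the Behrens–Fisher problem reappears as a restriction on
  comparability, not as a defect of the estimator;
* γ = (μ−C)/σ₁ — the one-sample effect size against a known constant.

A fourth parameter, δ′_q with q = (n₁−1)/(n₂−1), is provided to describe
what the pooled statistic actually estimates when variances differ.

## Estimators and bias correction

The pooled statistic g, Welch-based statistic e_biased = t_w/√ñ and
one-sample statistic c_biased = (Ȳ−C)/s are each, after multiplication by
√k (k = ñ, ñ, n−1 respectively), noncentral-t variates — exactly for the
pooled and one-sample cases, approximately (via Satterthwaite moment
matching) for the Welch case.  A noncentral-t variate T with m df
satisfies E(T) = ncp/J(m) with

    J(m) = Γ(m/2) / ( √(m/2) · Γ((m−1)/2) ),

so multiplying the statistic by J removes the small-sample bias:
d = J(n₁+n₂−2)·g, e = J(f)·e_biased, c = J(n−1)·c_biased.

Numerical notes on J:

* evaluated as exp(lnΓ(m/2) − lnΓ((m−1)/2) − ½ln(m/2)); the direct gamma
  ratio would overflow double precision near m ≈ 342, the log-space form
  is exact at any df (the test suite cross-checks it against the direct
  ratio up to m = 300);
* above m = 342 the classical approximation 1 − 3/(4m−1) is used instead,
  matching the exact branch to better than 1e-5 from m ≈ 100 onward, so
  the switch is invisible at the precision reported anywhere;
* the Welch df f is kept fractional throughout.  Rounding f to an integer
  before applying J changes the third decimal of e at n ≈ 5 and would
  break the reference values the tests pin down.

For e, the bias correction treats f as the df of the noncentral-t
distribution of t_w; since f is itself data-dependent, exact finite-sample
unbiasedness is approximate.  The Monte Carlo tests therefore assert
parameter recovery within three Monte Carlo standard errors rather than
exactly; at n₁ = n₂ = 10 and a 4:1 SD ratio the residual bias is below
0.002 on an effect of 0.343.

## Variances

Writing ν for the df and k for the scale (k = ñ two-sample, n−1
one-sample), the second moment of the noncentral t gives, for the
corrected estimator θ = J(ν)·T/√k with parameter θ₀:

    var(θ) = ν/(ν−2) · J²(ν) · (1/k + θ₀²) − θ₀²

and for the uncorrected statistic (whose expectation is θ₀/J(ν)):

    var = ν/(ν−2) · (1/k + θ₀²) − θ₀²/J²(ν).

The unknown parameter θ₀ is always replaced by the **biased** point
estimate (g, e_biased, c_biased).  This plug-in convention is pinned down
by the reference outputs to fifteen digits; substituting the corrected
estimate instead shifts the reported variance by ~4% and does not
reproduce them.

One-sample convention: the statistic is treated as scaled by √(n−1) (its
pivot is (Ȳ−C)/√(s²/(n−1)) on n−1 df), so both ν and k equal n−1.  This
differs from the textbook one-sample t, which scales by √n; the
convention is inherited from the estimator's derivation and is confirmed
by the reference variance 0.9292037.  Its distributional correctness is a
property of that derivation and is verified here empirically (Monte Carlo
variance agreement within 10%), not re-derived.

## Confidence intervals

The CI inverts the noncentral-t CDF in its noncentrality parameter:
ncp_L solves P(T ≤ t_obs; df, ncp) = 1−α/2 and ncp_H solves the α/2
analogue; the interval on the effect-size scale is [ncp_L/√k, ncp_H/√k],
multiplied by J(df) when the corrected estimator is reported.  Coverage is
exact for the pooled and one-sample families and approximate for the
Welch family (measured 0.948 at nominal 0.95, n₁ = n₂ = 15, 3:1 SD
ratio, 10,000 replicates).

The root is unique because the CDF is strictly decreasing in the ncp.  It
is found by geometric bracket expansion from [t_obs−1, t_obs+1] followed
by bisection to an absolute tolerance of 1e-8 (configurable via
`NcpSearchConfig`); the solver is vectorised over replicates, and scipy's
`nctdtrinc` serves as an independent oracle in the tests, never as the
implementation.  The CDF routine accepts fractional df, which the Welch
family requires.  Reference CI endpoints from the original console
outputs are matched to about 3–4 decimals, not 15: those outputs were
produced by a binary search of unpublished (visibly coarser) granularity,
e.g. a printed bound of exactly −325/128.  This implementation converges
tighter; the tests therefore compare endpoints at 5e-3 while requiring
the solver's own root residual |CDF − target| < 1e-6.

## Monte Carlo harness

`run_cell` draws `reps` independent replicate pairs from N(μ₁, σ₁²) and
N(μ₂, σ₂²) and averages d, e, Bonett's δ̂ and the corrected 95% CI widths
of d and e.  Defaults are μ₁ = 1, μ₂ = 0, σ₁ = 1 — the grid varies σ₂
(1–10) and the sample sizes (10–30).  Bonett's statistic is reported with
the same J(n₁+n₂−2) correction applied, the convention used by standard
meta-analysis software for this estimator (and the convention under which
it equals d exactly when n₁ = n₂).  Its parameter column is marked U.D.
(undefined — the statistic has no formulated estimand) and its interval
column N.P. (its separate approximate CI construction is out of scope
here).  δ is marked N.C. when σ₁ ≠ σ₂.

`reps` defaults to 20,000: the Monte Carlo SE of every point-estimate
column is then below 0.005, sufficient to resolve the estimator-bias
effects of interest (which are an order of magnitude larger), while a
36-cell grid completes in minutes on one CPU.  Raise `reps` to 100,000
for survey-grade tables.  Cells use independent `default_rng` streams
seeded `seed + cell index`, so any cell is reproducible in isolation.
Replicates with a zero within-group variance (probability zero under
continuous draws; a guard for degenerate user specs) are redrawn.

What the generator emulates — and does not: draws are exactly normal,
independent, with known σ ratios.  It does not emulate skewness, heavy
tails, dependence or contamination; passing tests demonstrate correctness
of the estimators *under the normal model they are derived for*, not
robustness to its violation (robust/trimmed variants are deliberately out
of scope).

## Embedded data

The package embeds Fisher's (1936) Iris measurements (50 flowers × 3
species × 4 lengths, in cm) as its worked heteroscedastic example.  The
embedded copy follows Fisher's printed table; it differs from the R/UCI
variant in three setosa cells (a long-documented transcription
discrepancy).  The reference comparison table (d, e, d/e, SD ratio per
species pair) reproduces to six decimals only with the printed-table
variant, which is why it is the one embedded.

## Design choices and limitations

* Parameter-based entry points build `SampleSummary` objects directly and
  share every downstream code path with raw-data entry, so the two routes
  are numerically identical by construction.
* Glass's Δ requires the caller to name the control group; there is no
  heuristic ordering.  Group order everywhere is group1 − group2.
* The variance formula for d mirrors the e formula at m = n₁+n₂−2; both
  reported reference variances confirm it to fifteen digits.
* Only the two-group specialization of Bonett's general contrast
  statistic is implemented; k-group contrasts, correlated-pairs effect
  sizes, robust/trimmed variants and power analysis are out of scope.
* Under σ₁ ≠ σ₂ *and* n₁ ≠ n₂ no implemented estimator has a
  design-independent estimand; the package surfaces the SD ratio as an
  advisory (`--sd-ratio`) but never alters output based on it.
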