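# Methods

## Model and estimands

All computations assume the normal-normal random-effects model
`y_i = x_i' beta + u_i + e_i` with `u_i ~ N(0, tau^2)`, `e_i ~ N(0, s_i^2)`,
all independent, and the within-study variances `s_i^2` treated as known.
The intercept-only design gives the meta-analysis of an average effect mu;
adding moderator columns gives meta-regression, where `tau^2` is the
*residual* between-study variance and is estimated under the full covariate
model before being frozen into the weights `w_i* = 1/(s_i^2 + tau^2)`.

Two inference methods share the weighted-least-squares point estimate
`beta_hat = (X'WX)^-1 X'Wy`:

* **conventional** — `Var(beta_hat) = (X'WX)^-1`, normal reference. Exactly
  the WLS model in which the error variances are known constants.
* **Hartung-Knapp** — `Var(beta_hat) = k_hat (X'WX)^-1` with
  `k_hat = e'We/(n - p)` (the weighted mean squared error; `H*^2` in the
  meta-analysis notation, where fitted values reduce to the pooled mean),
  t reference with n - p degrees of freedom. Exactly the WLS model in which
  the error variances are known only up to a proportionality constant k —
  the weaker and more standard regression assumption, which is the
  conceptual reason to prefer this method when variance components are
  estimated rather than known.

The package computes both routes and `equivalence_report` diffs every
reported quantity (estimates, SEs, statistics, p-values, CIs, k_hat) between
the meta-analytic formulas implemented here and a generic statsmodels `WLS`
fit. The agreement is an algebraic identity, so the default tolerance is
1e-8 and the test suite enforces it on randomized designs with 0-2
moderators.

## Between-study variance

* **REML** (default): `tau^2` maximizing the restricted log-likelihood
  `-2 llR = sum log(s_i^2 + t) + log det(X'W X) + r'W r` over t in [0, B],
  B = 10 (max y - min y)^2 + max s_i^2. The maximizer is bracketed on a
  65-point grid (closed-form vectorized evaluation for the intercept-only
  design) and refined by bounded Brent iteration with absolute tolerance
  1e-8 and at most 200 evaluations; the boundary t = 0 is compared
  explicitly, so negative estimates cannot occur. Convergence status and the
  evaluation count are reported on the `Tau2Estimate` rather than silently
  ignored. Any maximizer of the same likelihood is equivalent; tests require
  agreement with a 1e-5-step grid search within 1e-4 and with metafor's
  Fisher-scoring REML within 5e-4.
* **DerSimonian-Laird**: `max(0, (Q - (n - p)) / tr(P))` with fixed-effect
  weights `W = diag(1/s_i^2)`, `Q = r'Wr` and
  `P = W - WX(X'WX)^-1X'W`; reduces to the familiar
  `(Q - (n-1))/(S1 - S2/S1)` for the intercept-only design.
* A fixed value (`fixed:<value>`) is accepted everywhere, which also yields
  fixed-effect meta-analysis via `fixed:0`.

## Effect sizes

Cohen's d with group sizes converts to Hedges' g by the exact gamma-ratio
correction `J(m) = Gamma(m/2) / (sqrt(m/2) Gamma((m-1)/2))`, m = n1 + n2 - 2,
evaluated through log-gamma differences for numerical stability; above
m = 2000 the asymptotic series for the gamma ratio is used instead, because
the log-gamma difference cancels to ~1e-9 accuracy there while the series is
exact to ~1e-15, keeping J strictly increasing over the whole supported
range (the usual `1 - 3/(4m-1)` shortcut agrees to ~1e-4 already at m = 18);
`var(d) = (n1+n2)/(n1 n2) + d^2/(2(n1+n2))`, `g = J d`, `var(g) = J^2 var(d)`.
2x2 tables convert to log odds ratios `ln(ad/bc)` with variance
`1/a + 1/b + 1/c + 1/d`; if any cell is zero, 0.5 is added to all four cells
of that table (only then), the standard continuity convention. Tables with a
zero margin that the correction cannot repair are rejected. Other effect
scales (risk ratios, correlations, raw mean differences) are out of scope.

## Inference details

* p-values are two-sided throughout; default alpha = 0.05.
* Constrained Hartung-Knapp variants replace `H*^2` by `max(H*^2, 1)`
  (`unit`) or `max(H*^2, (z_{a/2}/t_{df,a/2})^2)` (`zt`). Because the
  conventional and HK interval half-widths are `z sqrt(V)` and
  `H* t sqrt(V)`, the `zt` floor makes the reported interval exactly the
  wider of the two — the tests assert this width identity exactly — while
  `unit` is the more conservative bound (`z < t` always). Neither constraint
  is applied by default; they are explicit options.
* `H*^2 = 0` (every estimate equal to the fitted value) yields a zero-width
  interval flagged `degenerate=True` instead of an exception, so simulation
  loops survive; degenerate replications are counted in coverage results,
  never dropped.
* n = 2 studies is allowed for HK inference (df = 1); expect very wide
  intervals.
* Design matrices are checked for rank with a 1e-10 relative threshold on
  the smallest singular value. Categorical moderators must arrive as 0/1
  dummy columns; the readers perform no automatic encoding.
* Per-coefficient tests only; omnibus F-tests, robust/sandwich variances,
  permutation tests and prediction intervals are out of scope.

## Simulation harness

`generate_meta_dataset` draws `y_i = mu + N(0, tau2) + N(0, s_i^2)` and
hands the true `s_i^2` to the analysis as known, mirroring the model's own
assumption. Each replication's RNG stream derives from `(seed, rep_index)`
through a `SeedSequence` spawn key, so runs are bit-reproducible and
different inference methods can be compared on identical data (paired
comparisons). `coverage_study` records per-replication coverage of the true
mu and interval width; `compare_methods` tabulates several methods on shared
streams.

Defaults (10 studies per meta-analysis, mu = 0, tau^2 = 0.1, equal
within-study variances of 0.1, 10^4 replications, alpha = 0.05) describe the
benchmark cell in which the HK pivot is exactly one-sample t, so empirical
coverage should equal the nominal level up to Monte-Carlo noise; at 10^4
replications, 3 Monte-Carlo standard errors at 95% nominal is about
+/- 0.65 percentage points. A second analytic benchmark: with tau^2 known
and supplied as fixed, the conventional z interval is exact. The acceptance
script re-runs the first benchmark at these sizes; they keep the full run
comfortably under a minute while leaving Monte-Carlo error well below the
effects of interest.

What the generator does *not* emulate about real data: estimated (noisy)
within-study variances, correlation between `y_i` and `s_i^2`, non-normal
random effects, and small-sample non-normality of the within-study errors.
Passing coverage tests therefore certify the methods under the model's own
assumptions, not robustness to their violation — which is precisely the
regime in which the exactness claims are stated.

## Known limitations

* The two published worked-example datasets (open-education creativity;
  pneumococcal vaccine trials) are distributed with external archives, not
  bundled here; the test suite substitutes synthetic data from the same
  model plus an independent cross-check against R's metafor.
* REML is fit marginally per dataset; no confidence interval for tau^2 is
  produced.
* Multivariate meta-analysis and generalized linear mixed models for binary
  outcomes are out of scope, as are forest plots and other graphics.
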