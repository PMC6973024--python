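# hkmeta

Random-effects meta-analysis and meta-regression with both the conventional
(normal-pivot) and the Hartung-Knapp (scaled-variance, t-pivot) inference
methods, built on their exact equivalence to weighted least squares (WLS)
regression.

## The problem and the model

A meta-analysis pools effect estimates `y_i` (i = 1..n) with within-study
sampling variances `s_i^2` under the random-effects model

    y_i = mu + u_i + e_i,     u_i ~ N(0, tau^2),  e_i ~ N(0, s_i^2),

where `tau^2` is the between-study variance. With weights
`w_i* = 1/(s_i^2 + tau^2)` (tau^2 estimated by REML by default), the pooled
estimate and its conventional variance are

    mu_hat = sum(w_i* y_i) / sum(w_i*),     V = 1 / sum(w_i*).

The **conventional** method treats all variances as known and uses the normal
pivot `(mu_hat - mu)/sqrt(V) ~ N(0, 1)`. The **Hartung-Knapp** method scales
the variance by the weighted mean squared error

    H*^2 = sum w_i* (y_i - mu_hat)^2 / (n - 1),     V_HK = H*^2 * V,

and uses a t pivot with n - 1 degrees of freedom. The same construction with
a design matrix X (intercept plus moderators) gives random-effects
meta-regression: `beta_hat = (X'WX)^-1 X'Wy`, conventional covariance
`(X'WX)^-1` with a normal reference, Hartung-Knapp covariance
`k_hat (X'WX)^-1` with a t(n - p) reference, where
`k_hat = e'We/(n - p) = H*^2` is exactly the proportionality-constant
estimate of a WLS regression whose error variances are known only up to a
constant. That identity — conventional inference = WLS with known variances,
Hartung-Knapp inference = WLS with variances known up to proportionality —
is checked numerically by `equivalence_report`, which diffs this package's
meta-analytic formulas against a generic statsmodels WLS fit.

Because the Hartung-Knapp interval can come out *narrower* than the
conventional one when `H*^2` is small, two constrained variants bound the
scale factor from below: `unit` enforces `H*^2 >= 1`, and `zt` enforces
`H* >= z_{a/2}/t_{n-1,a/2}`, which makes the reported interval exactly the
wider of the two methods' intervals.

The package is for biostatisticians and evidence-synthesis practitioners who
want these methods, their WLS interpretation, and a simulation harness for
interval coverage, in one place. Inputs are per-study CSV/TSV tables of
either precomputed `yi, vi`, Cohen's *d* with group sizes (converted to
Hedges' *g* with the exact gamma-ratio bias correction), or 2x2 counts
(converted to log odds ratios).

## Worked example

An 8-trial synthetic dataset (standardized mean differences, generated from
the random-effects model with mu = 0.4, tau^2 = 0.05; shipped in
`examples/example.csv`):

```sh
hkmeta meta examples/example.csv
```

```
Random-effects meta-analysis
n = 8 studies, tau2 (REML) = 0.176, k_hat = H*2 = 0.986

method        term         estimate      se    stat       p  95% CI
conventional  intercept       0.404   0.186   2.170   0.030  (0.039; 0.768) [z]
hk            intercept       0.404   0.185   2.185   0.065  (-0.033; 0.841) [t]
```

Both methods report the same pooled effect (0.404) — Hartung-Knapp never
moves the point estimate. The HK standard error is the conventional one
times `sqrt(k_hat)` = sqrt(0.986), but its interval is wider and its p-value
larger because it uses t(7) instead of normal quantiles: here the
conventional method calls the effect significant at the 5% level and
Hartung-Knapp does not, the typical small-n disagreement. `k_hat` near 1
says the total variances `s_i^2 + tau^2` describe the observed dispersion
well.

The same interface handles meta-regression
(`hkmeta metareg data.csv --covariates severity,region`), effect-size
conversion (`hkmeta es raw.csv --kind fourfold --out effects.csv`), and
coverage simulations from a YAML config (`hkmeta simulate cells.yaml --out
coverage.csv`). In Python, the model/results API mirrors statsmodels:

```python
from hkmeta import RandomEffectsMeta
res = RandomEffectsMeta.from_dataframe(df, covariates=("severity",)).fit()
print(res.summary())
res.inference("hk", constraint="zt")
```

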