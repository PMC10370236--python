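# Methods

## The estimand and its assumptions

The unit of analysis is a *study pair*: a randomized trial and a
non-randomized database study designed to emulate it, each summarised by a
log hazard ratio and its standard error. Everything downstream assumes the
two estimators are approximately normal on the log scale and independent of
each other, so the difference $d_i$ has standard error
$se_{d,i} = (se_{RCT,i}^2 + se_{RWE,i}^2)^{1/2}$. Differences are oriented
**trial minus emulation**, matching the convention for the continuous
covariates (difference in mean age and in percent female are also trial
minus emulation), so a positive coefficient means the design difference
pushes the trial's estimate above the emulation's.

When an emulation was implemented in several claims databases, the
database estimates are pooled by inverse-variance fixed-effects
meta-analysis. Fixed effects is a modelling commitment, not a default: the
pooled value is only meaningful if the databases estimate a common effect,
which is why pooling is gated on Cochran's Q. Trials whose database
results are heterogeneous (Q-test p-value below `alpha`, default 0.05) are
excluded from the pair-level analysis rather than pooled anyway; the
exclusion is recorded on the dataset and in the run manifest.

## Heterogeneity tests

Under pairwise agreement the standardized difference $z_i = d_i/se_{d,i}$
is standard normal and $Q_i = z_i^2 \sim \chi^2_1$. Each pair gets its own
Q-test; the sum over pairs is referred to a $\chi^2_n$ distribution with
$n$ (not $n-1$) degrees of freedom because no common mean is estimated —
the null hypothesis is exact agreement within each pair, under which the
$n$ statistics are independent $\chi^2_1$ draws. The calibration export
pairs sorted observed $z_i$ with standard-normal quantiles and sorted
p-values with uniform quantiles at plotting positions $(i - 0.5)/n$.

## Multiplicative heterogeneity and meta-regression

Overdispersion is modelled multiplicatively: $d_i \sim N(x_i'\beta,
\phi^2 se_{d,i}^2)$. The fit is weighted least squares with fixed, known
weights $w_i = se_{d,i}^{-2}$, and

$$\hat\phi_{raw} = \sqrt{\tfrac{1}{n-p}\textstyle\sum_i w_i r_i^2}$$

with response-scale residuals $r_i$ — i.e. the residual standard error of
the weighted regression. Estimates below 1 are floored at 1: the model
never claims the pairs agree *better* than their standard errors allow,
and a sub-1 value is sampling noise around homogeneity.

Inference choices, where more than one defensible option existed:

- **Coefficient standard errors** are $\hat\phi \cdot
  \sqrt{\mathrm{diag}\,(X'WX)^{-1}}$ using the **floored** $\hat\phi$, so
  intervals never shrink below the homoskedastic baseline.
- **Confidence intervals** use t quantiles with $n - p$ degrees of
  freedom (not normal quantiles): with a few dozen pairs the difference is
  material and the t reference is the one exact under the model.
- **Continuous covariates** are mean-centered on the analysis sample, so
  the intercept is the expected trial-minus-emulation difference at
  reference design levels and average population overlap. Binary flags
  enter as 0/1 against their reference level and are not centered.

The composite **close emulation** flag is derived, never user-supplied: a
pair is close when at least one of the comparator/outcome emulations was
rated good and none of the four disqualifying design differences
(in-hospital start, one-arm run-in selection, discontinuation of baseline
therapy without washout, delayed effect) is present. The two quality
covariates are recorded only as good vs. moderate/poor, so the finer
"at least moderate with at least one good" reading collapses to "at least
one good"; the moderate/poor distinction is not recoverable from binary
flags.

## Subset selection

All $2^p$ subsets of the ten candidate covariates are fitted and scored by
leave-one-out cross-validated mean squared error on the raw difference
scale (an inverse-variance-weighted variant is available behind
`weighted_loo`; unweighted is the default reading of "mean squared
error"). The standard error of the score is
$\mathrm{sd}(e_i^2)/\sqrt{n}$, taken from the minimum-MSE model, and the
one-standard-error rule selects the smallest model with score at most
(min MSE + 1 SE); ties on size break by smaller MSE, then subset order.

LOO scores are computed via the leverage identity
$e_{(-i)} = r_i/(1 - h_{ii})$, $h_{ii} = w_i x_i'(X'WX)^{-1}x_i$, which is
algebraically exact for a weighted linear fit with fixed weights.
Per-fold recentering of continuous covariates does not alter fold
predictions (predictions of a linear model containing an intercept are
invariant to shifting a column), so the shortcut equals the literal
per-fold refit; the test suite verifies this against an explicit
refit-per-fold oracle to 1e-10. A fold whose design becomes singular —
in practice a binary flag carried by a single trial, which gives that
trial leverage 1 — makes the model infeasible; infeasible models are
excluded from selection with a logged warning rather than scored
optimistically.

The selection path (best model per size, with its full-data coefficients
and residual $\hat\phi$) is exported alongside the selected model so the
trade-off between complexity, predictive error, and explained
heterogeneity is inspectable.

## Prediction intervals

For a covariate pattern $x$ observed in the data, the 95% interval is

$$x'\hat\beta \pm t_{n-p}\,\hat\phi\,\sqrt{x'(X'WX)^{-1}x + \mathrm{med}(se_{d}^2)}$$

combining coefficient uncertainty with observation-level noise. The
observation-variance term uses the median squared difference-SE of the
pattern's observed trials — a group-typical precision rather than any
single trial's. Only observed patterns are emitted; extrapolated patterns
raise an error. This construction is a package choice among several
defensible ones and is deliberately configurable at the call site via the
`patterns` argument.

## Synthetic data

The generator draws directly from the pair-level model: covariates, then
$se_{RCT}$ and $se_{RWE}$ log-uniformly (creating realistic weight
spread), then $d_i \sim N(x_i'\beta, (\phi\,se_{d,i})^2)$, split
symmetrically around a baseline log HR (default 0, which cancels in every
downstream statistic). Generating at the level of the difference — rather
than inventing patient-level survival data — makes parameter recovery a
sharp test: the estimator is consistent exactly under this model. Binary
flags are independent Bernoulli draws except within an optional mutually
exclusive group (single multinomial with a "none" cell), mirroring design
differences that cannot co-occur in one trial. With `n_databases > 1`,
per-database estimates are constructed with log-spaced relative precisions
rescaled so their fixed-effects pool reproduces the pair's pooled estimate
and SE exactly.

What the generator does **not** emulate: confounding mechanisms,
informative censoring, correlated standard errors between arms, non-normal
small-sample behaviour of hazard-ratio estimators, or covariate
measurement error. Passing tests therefore demonstrate that the pipeline's
statistics behave as advertised *under the model it assumes*, not that the
model captures every feature of a real trial-emulation collection.

Fixture defaults: the analysis-scale fixture uses 29 pairs, ten candidate
covariates with prevalences plausible for a portfolio of cardiometabolic
claims-data emulations, three mutually exclusive active flags with effects
0.20–0.37 on the log-HR-difference scale, and three databases per trial.
The recovery fixture uses 200 pairs with the same three active effects and
pair-level standard errors of 0.02–0.06, keeping each effect at least
three times the noise scale so that recovery failures indicate bugs rather
than an under-powered design. All randomness flows through numpy's PCG64
(`default_rng`), recorded in the truth manifest; identical seeds give
bit-identical datasets.

## Problem sizes and numerical choices

The test suite and acceptance script use: oracle-equivalence checks at
n ≤ 12 (tolerance 1e-10 against explicit normal equations and per-fold
refits); null calibration with 2,000 replications of 29 pairs; coverage
with 2,000 replications of 100 pairs at φ = 1.3; overdispersion recovery
over 20 seeds at n = 500; selection recovery over 50 seeds at n = 200; and
the full 1,024-model enumeration at n = 29. Rank deficiency is detected
via `numpy.linalg.matrix_rank`'s default tolerance, fold singularity at
leverage within 1e-8 of 1, and the WLS solve goes through `lstsq` on the
square-root-weighted system for numerical stability. CSV floats are read
with round-trip precision so write-then-read reproduces values exactly.

## Limitations

- With rare binary flags and small n, many candidate models are LOO
  infeasible; selection then searches a reduced space, and the warning
  count should be checked before interpreting the selected model.
- The multiplicative model rescales *all* standard errors by one factor;
  it cannot express heterogeneity concentrated in a subset of pairs.
- The one-SE rule's SE is estimated from squared LOO errors, which are
  heavy-tailed at small n; the selected size is accordingly conservative.
- Exact agreement of interval endpoints with other implementations depends
  on choices (floored vs raw φ in SEs, t vs normal quantiles, LOO error
  weighting) that are documented above and configurable where reasonable.
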