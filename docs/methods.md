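# Methods

## The model families

The package implements a two-family construction for lifetime and count
data.

**Continuous (MKM-G).**  Given a baseline CDF `G(x; ϑ)` on (0, ∞) and an
extra shape parameter θ > 0, the modified Kavya–Manoharan family has

```
F(x; θ, ϑ) = ψ (1 − exp(−G(x; ϑ)^θ)),      ψ = e/(e−1),
f(x; θ, ϑ) = ψ θ g(x; ϑ) G(x; ϑ)^{θ−1} exp(−G(x; ϑ)^θ).
```

ψ is a fixed normalizing constant (as G → 1, F → ψ(1 − e⁻¹) = 1), never a
free parameter.  θ = 1 recovers the original one-parameter
Kavya–Manoharan transformation.  The quantile function is closed form,
`Q(u) = G⁻¹([−log(1 − u/ψ)]^{1/θ})`, so sampling is by inverse transform.
Four baselines are provided: exponential (rate λ), Burr XII, Burr X and
log-logistic.  For the Burr X sub-model only the product η = θ·β is
identifiable, so that model is exposed as (η, λ).

**Discrete (DMKM-G).**  The discrete counterpart is obtained by survival
discretization: `p(x) = S_c(x) − S_c(x+1)` on {0, 1, 2, …}, giving
`p(x) = ψ(q^{G(x)^θ} − q^{G(x+1)^θ})` with q = e⁻¹ and
`F(x) = ψ(1 − q^{G(x+1)^θ})`.  Two consequences are used throughout:
the PMF telescopes to one exactly, and the discrete CDF at integer x
equals the continuous CDF at x + 1 — hence the sampler takes the floor
of a continuous draw, which is distributionally exact and O(1) per
variate.  The survival function convention is `S(x) = P(X ≥ x+1) = 1 −
F(x)`; the discrete hazard is `h(x) = p(x)/P(X ≥ x)` and lies in [0, 1].

## Moments: quadrature and series

Raw moments are computed by adaptive quadrature of `x^r f(x)` over
(0, Q(1 − 10⁻¹²)), split at the median because the density is unbounded
at the origin when θ < 1.  For the MKM-exponential (MKME) model the
density also admits an exponential-mixture expansion
`f = Σ_m v_m g_{m+1}` (g_{m+1} the exponential density with rate
(m+1)λ), giving the series

```
μ'_r = r! Σ_m v_m [(m+1)λ]^{−r},
v_m  = Σ_k ψ k θ (−1)^{k+m+1} / ((m+1) k!) · C(kθ−1, m).
```

The generalized binomial coefficient `C(a, m)` uses the falling-factorial
product `a(a−1)⋯(a−m+1)/m!`, which is the continuation the binomial
series requires and is exact at negative-integer `a` where Gamma-ratio
forms have poles.

**Truncation convention.**  By default both sums are truncated at the
same order: m = 0..M and k = 1..M.  Tying the truncations is what
produces the characteristic convergence pattern of the series — from
below for θ < 1, with an undershoot at small M for θ > 1 — and the
truncated values then converge to the quadrature value by M ≈ 50.
Passing `inner="converged"` runs the k-sum until terms fall below 1e−14
instead, which is the better choice when only the limit matters.

Other properties (incomplete moments, Bonferroni/Lorenz curves, mean
deviations, mean residual life and mean inactivity time, Rényi and
Shannon entropy, probability weighted moments, order-statistic
densities) are evaluated by the same split quadrature.  The mean
residual life is implemented as `(μ − δ₁(t))/S(t) − t`, the standard
identity with δ₁ the first incomplete moment; a Monte-Carlo oracle in
the test-suite arbitrates this form.  The Rényi integral diverges at the
origin when φ(θ−1) ≤ −1; that case raises a domain error rather than
returning a quadrature artifact.

## Estimation

Eight classical estimators are provided for the MKME model: maximum
likelihood, ordinary/weighted least squares on the CDF, maximum product
of spacings, percentiles, and the Cramér–von Mises, Anderson–Darling and
right-tail Anderson–Darling minimum-distance criteria.  All optimize on
the log-parameter scale with Nelder–Mead (tolerances 1e−10 in x, 1e−12
in the objective), starting from (θ, λ) = (1, 1/x̄).  The profile
criterion in θ can be very flat — real datasets put the optimum anywhere
from θ ≈ 1 to θ ≈ 47 — so the returned optimum is screened against a
5×5 log-grid over θ ∈ [0.1, 50], λ ∈ [0.1/x̄, 10/x̄] and re-polished from
any grid point that beats it.  Ties in the sample produce zero spacings
in the MPS criterion; the Cheng–Amin convention replaces a tied spacing
with the density at that point (needed for count-like data fitted as
continuous).  Logs of distribution functions are floored at 1e−300.

Standard errors (ML only) come from the inverse observed information,
with the Hessian of the negative log-likelihood formed by central finite
differences at the MLE using relative steps of 1e−4; a
non-positive-definite Hessian yields no SEs and a warning.

Maximum likelihood is also provided for the discrete DMKME model (sum of
log PMFs, 30-point multistart because count likelihoods are flatter) and
generically for the Burr XII / Burr X / log-logistic sub-models.  The
plain exponential (λ̂ = 1/x̄) and geometric (p̂ = 1/(1 + x̄)) fits are
included as sanity baselines for model comparison.

## Goodness of fit

With sorted PIT values `z_i = F̂(x_(i))` the report carries the plain
Cramér–von Mises `W²` and Anderson–Darling `A²` statistics and the
Chen–Balakrishnan corrected variants `W*`, `A*`: the z_i are pushed
through the normal quantile transform, standardized, mapped back to the
unit interval, and the corrected statistics `W²(1 + 0.5/n)` and
`A²(1 + 0.75/n + 2.25/n²)` are computed on the transformed values.  The
Kolmogorov–Smirnov statistic uses the standard one-sample form, with the
asymptotic Kolmogorov p-value at √n·KS; estimated-parameter effects are
deliberately ignored, matching common reporting practice for these
statistics (a parametric bootstrap would be needed for calibrated
p-values, and is out of scope).  Discrete models are scored on
`z_i = F̂(x_i)` exactly like continuous ones, with ties kept in stable
order; PIT values of exactly 0 or 1 are clipped at 1e−12 with a warning
since `A²` would diverge.

## Monte-Carlo harness

`run_cell` draws samples of size n from MKME(θ, λ) by inverse transform,
fits each with one estimator, and reports the average estimate and mean
squared error per parameter.  The default grid covers
θ ∈ {0.25, 0.5, 0.75, 1.5, 2}, λ ∈ {0.5, 0.85, 1.3, 1.5, 2.5},
n ∈ {20, 50, 100, 250} and all eight methods.  Replicate streams are
derived from a master seed plus a CRC32 hash of the cell key and the
replicate index, so every cell is individually reproducible and
independent of execution order.  Non-convergent fits are excluded from
the summaries and counted in `failure_count` (in practice the rescue
multistart makes failures rare).  The default is 500 replicates — at
that scale AE values carry a Monte-Carlo standard error of roughly
√(MSE/500), which is the yardstick the tests use — with `reps=5000`
available for a publication-scale run.  The desk-scale defaults keep the
full test-suite in the low minutes on one core.

## What the generator emulates — and what it does not

The sampler produces exact i.i.d. draws from the model, so simulation
results measure pure estimator behavior under correct specification.
Real lifetime data bring censoring, rounding/ties, covariates and model
misspecification; none of these are simulated, so passing the
Monte-Carlo checks says nothing about robustness to them.  Ties do occur
in the bundled count-valued datasets and are handled in estimation (MPS
tie rule) and GoF (stable sort), but tie-aware KS distribution theory is
not attempted.

## Numerical choices and edge cases

- `1 − u/ψ` in the quantile function is evaluated with `log1p`, keeping
  the inversion accurate to u = 1 − 10⁻¹².
- The survival function is evaluated as `ψ(exp(−G^θ) − e⁻¹)` rather than
  `1 − F`, which preserves relative accuracy deep in the right tail;
  where it still underflows to zero the hazard returns +∞ with a
  warning, never NaN.
- For θ < 1 the density is unbounded at the origin; `pdf` returns the
  (finite, huge) value at any x > 0 and likelihood code uses `logpdf`.
- Between equally good optima the smallest θ is reported, determined by
  the fixed start order; all fits are deterministic given the sample.

## Known limitations

- The failure-times benchmark table in the source literature is
  internally inconsistent with its own printed data listing (its
  exponential-fit row implies a different sample mean than the listed
  values); on the listed data this package's MLE strictly dominates the
  tabulated estimates in likelihood, so the tabulated row is not
  reproducible and the package reports the true optimum.
- Only the exponential baseline has a named, tested discrete sub-model.
- No censoring, covariates, or Bayesian estimation.
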