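# mkmg

Lifetime and count modeling with the **modified Kavya–Manoharan (MKM-G)**
family of distributions and its discrete counterpart (**DMKM-G**).

Survival analysts, reliability engineers and epidemiologists routinely
need distributions whose hazard can be decreasing, increasing, bathtub
or unimodal while staying cheap to fit.  The MKM-G construction adds a
single shape parameter θ to any baseline CDF `G` on (0, ∞):

```
F(x; θ, ϑ) = ψ (1 − exp(−G(x; ϑ)^θ)),      ψ = e/(e−1),  θ > 0,
```

and its discrete analogue on {0, 1, 2, …} follows by survival
discretization, `p(x) = S(x) − S(x+1)`.  The package provides

- the exponential (**MKME**), Burr XII, Burr X and log-logistic
  sub-models, plus the discrete **DMKME**, with CDF/PDF(PMF)/SF/HRF,
  closed-form quantiles and exact inverse-transform sampling;
- distributional properties: moments (adaptive quadrature and the
  exponential-mixture series for MKME), incomplete moments,
  Bonferroni/Lorenz curves, mean deviations, mean residual life and mean
  inactivity time, Rényi/Shannon entropy, Galton/Moors quantile shape
  measures, probability weighted moments, order-statistic densities;
- eight classical estimators for MKME — ML, LS, weighted LS, maximum
  product of spacings, percentiles, Cramér–von Mises, Anderson–Darling
  and right-tail Anderson–Darling — with ML standard errors, plus ML for
  the discrete and the other continuous sub-models;
- goodness-of-fit reporting (Chen–Balakrishnan W\*/A\*, plain W²/A², KS
  with asymptotic p-value) and ranked model-comparison tables;
- a reproducible Monte-Carlo harness comparing the estimators over a
  grid of (θ, λ, n);
- seven classic benchmark datasets bundled as plain-text fixtures.

## Worked example

Fit the MKME model to the classic bank waiting-times data (n = 100) and
compare it with a plain exponential fit:

```python
>>> from mkmg import load, fit, fit_exponential, comparison_table
>>> x = load("waiting_times").values
>>> fr = fit(x, method="mle")
>>> {k: round(v, 5) for k, v in fr.estimates.items()}
{'theta': 2.33587, 'lam': 0.1357}
>>> {k: round(v, 5) for k, v in fr.ses.items()}
{'theta': 0.33, 'lam': 0.01616}
>>> print(comparison_table(x, [fr, fit_exponential(x)])[["model", "Wstar", "Astar", "KS", "pvalue"]])
         model     Wstar     Astar        KS    pvalue
0         mkme  0.017214  0.127878  0.036691  0.999285
1  exponential  0.027094  0.179432  0.173038  0.005015
```

The extra shape parameter θ̂ ≈ 2.34 bends the exponential hazard into the
unimodal shape this data wants: the sup-distance between the fitted and
empirical CDFs drops from 0.173 to 0.037, and the corrected
Cramér–von Mises and Anderson–Darling distances fall by a third or more.

The same interface drives the discrete family for count data:

```python
>>> from mkmg import fit, load
>>> marks = load("exam_marks").values       # 48 exam scores
>>> fit(marks, method="mle", family="dmkme").estimates
{'theta': 2.864224..., 'lam': 0.057464...}
```

A command-line front end mirrors the library
(`mkmg fit --dataset waiting_times`, `mkmg moments --theta 0.5 --lam 0.2`,
`mkmg sample`, `mkmg gof --compare`, `mkmg simulate`).

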