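"""Goodness-of-fit statistics and model-comparison tables.

Given a fitted model with CDF ``F_hat`` and a sample x_1..x_n with sorted
PIT values z_i = F_hat(x_(i)), the module reports

* the plain Cramér–von Mises and Anderson–Darling statistics
  W^2 = 1/(12n) + sum (z_i - (2i-1)/(2n))^2 and
  A^2 = -n - (1/n) sum (2i-1)[ln z_i + ln(1 - z_(n+1-i))],
* the Chen–Balakrishnan corrected statistics W* and A*: the z_i are
  pushed through the normal quantile transform, standardized, and mapped
  back to the unit interval (u_i = Phi((Phi^{-1}(z_i) - ybar)/s_y));
  W* = W^2(u)(1 + 0.5/n) and A* = A^2(u)(1 + 0.75/n + 2.25/n^2),
* the Kolmogorov–Smirnov statistic KS = max_i max(i/n - z_i, z_i - (i-1)/n)
  with its asymptotic p-value (Kolmogorov distribution at sqrt(n) KS,
  ignoring estimated-parameter effects).

Discrete models are scored on z_i = F_hat(x_i) exactly like continuous
ones, with ties handled by a stable sort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = ["GoFReport", "gof_statistics", "gof_report", "comparison_table", "table_to_tsv", "table_to_json"]

_CLIP = 1e-12


@dataclass(frozen=True)
class GoFReport:
    """GoF statistics for one fitted model on one sample."""

    model: str
    n: int
    W2: float
    A2: float
    Wstar: float
    Astar: float
    KS: float
    pvalue: float


def _plain_w2_a2(z: np.ndarray) -> tuple[float, float]:
    n = z.size
    i = np.arange(1, n + 1)
    W2 = 1 / (12 * n) + ((z - (2 * i - 1) / (2 * n)) ** 2).sum()
    A2 = -n - ((2 * i - 1) * (np.log(z) + np.log(1 - z[::-1]))).sum() / n
    return float(W2), float(A2)


def gof_statistics(z, model: str = "model") -> GoFReport:
    """Compute all statistics from PIT values z_i (any order; sorted internally)."""
    z = np.sort(np.asarray(z, dtype=float))
    n = z.size
    if np.any((z <= 0) | (z >= 1)):
        warnings.warn("PIT values at 0 or 1 clipped to avoid divergent A^2", RuntimeWarning)
        z = np.clip(z, _CLIP, 1 - _CLIP)
    i = np.arange(1, n + 1)
    W2, A2 = _plain_w2_a2(z)
    # Chen–Balakrishnan: normal transform, standardize, back to (0,1)
    y = stats.norm.ppf(z)
    u = np.sort(stats.norm.cdf((y - y.mean()) / y.std(ddof=1)))
    u = np.clip(u, _CLIP, 1 - _CLIP)
    W2u, A2u = _plain_w2_a2(u)
    Wstar = W2u * (1 + 0.5 / n)
    Astar = A2u * (1 + 0.75 / n + 2.25 / n**2)
    KS = float(max((i / n - z).max(), (z - (i - 1) / n).max()))
    pvalue = float(special.kolmogorov(np.sqrt(n) * KS))
    return GoFReport(model=model, n=n, W2=W2, A2=A2, Wstar=float(Wstar), Astar=float(Astar), KS=KS, pvalue=pvalue)


def gof_report(model, sample, name: str | None = None) -> GoFReport:
    """GoF report for a fitted model exposing ``cdf`` on the sample's support."""
    x = np.sort(np.asarray(sample, dtype=float), kind="stable")
    z = np.asarray(model.cdf(x), dtype=float)
    tag = name if name is not None else type(model).__name__
    return gof_statistics(z, model=tag)


def comparison_table(sample, fits, names=None) -> pd.DataFrame:
    """One row per fitted model, ranked by ascending KS.

    ``fits`` is a sequence of :class:`mkmg.estimation.FitResult`; estimates
    and (where available) standard errors are carried into the table.
    """
    from .estimation import model_from_fit

    rows = []
    for k, fr in enumerate(fits):
        tag = names[k] if names is not None else fr.family
        rep = gof_report(model_from_fit(fr), sample, name=tag)
        row = {
            "model": tag,
            "estimates": "; ".join(f"{p}={v:.5f}" for p, v in fr.estimates.items()),
            "ses": "; ".join(f"{p}={v:.5f}" for p, v in (fr.ses or {}).items()),
            "Wstar": rep.Wstar,
            "Astar": rep.Astar,
            "KS": rep.KS,
            "pvalue": rep.pvalue,
        }
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("KS", kind="stable").reset_index(drop=True)
    return df


def table_to_tsv(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", index=False, float_format="%.5f")


def table_to_json(df: pd.DataFrame) -> str:
    return json.dumps(df.to_dict(orient="records"), indent=2)
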