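"""The DMKM-G family of discrete distributions on {0, 1, 2, ...}.

The discrete family is obtained from the continuous MKM-G family by
survival discretization: with the continuous survival function S_c, the
PMF is p(x) = S_c(x) - S_c(x+1), which gives

    p(x)   = psi * (q^{G(x)^theta} - q^{G(x+1)^theta}),     q = e^{-1},
    F(x)   = psi * (1 - q^{G(x+1)^theta}),
    S(x)   = P(X >= x+1) = 1 - F(x).

The PMF telescopes to 1 exactly, and the discrete CDF at integer x equals
the continuous CDF at x+1, which makes flooring a continuous variate an
exact sampler.

The survival function convention here returns S(x) = P(X >= x+1) (equal
to 1 - F(x)); the hazard is h(x) = p(x)/P(X >= x) = p(x)/(1 - F(x-1)).

:func:`DMKME` is the named sub-model with exponential baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .baselines import Baseline, Exponential
from .family import PSI, MKM

__all__ = ["Q_DISC", "DMKM", "DMKME"]

#: The discretization base q = e^{-1}.
Q_DISC: float = math.exp(-1.0)


def _check_counts(x):
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.number):
        raise ValueError("x must be numeric")
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("x must consist of nonnegative integers")
    return x.astype(float)


@dataclass(frozen=True)
class DMKM:
    """A discrete MKM-G model: shape ``theta`` over a :class:`Baseline`."""

    theta: float
    baseline: Baseline
    q: float = field(default=Q_DISC, init=False, repr=False)
    psi: float = field(default=PSI, init=False, repr=False)

    def __post_init__(self):
        if not np.isfinite(self.theta) or self.theta <= 0:
            raise ValueError(f"parameter 'theta' must be a positive real, got {self.theta!r}")

    @property
    def continuous(self) -> MKM:
        """The continuous MKM model this distribution discretizes."""
        return MKM(self.theta, self.baseline)

    def _expGt(self, x):
        # q^{G(x)^theta} = exp(-G(x)^theta), with G(0) = 0
        x = np.asarray(x, dtype=float)
        out = np.ones_like(x)
        pos = x > 0
        if np.any(pos):
            g = self.baseline.cdf(x[pos])
            out[pos] = np.exp(-(g**self.theta))
        return out

    def pmf(self, x):
        """p(x) = psi*(q^{G(x)^theta} - q^{G(x+1)^theta})."""
        x = _check_counts(x)
        out = PSI * (self._expGt(x) - self._expGt(x + 1))
        return out if out.ndim else float(out)

    def logpmf(self, x):
        with np.errstate(divide="ignore"):
            out = np.log(self.pmf(x))
        return out

    def cdf(self, x):
        """F(x) = psi*(1 - q^{G(x+1)^theta}) = P(X <= x)."""
        x = _check_counts(x)
        out = PSI * (1.0 - self._expGt(x + 1))
        return out if out.ndim else float(out)

    def sf(self, x):
        """S(x) = P(X >= x+1) = 1 - F(x)."""
        return 1.0 - self.cdf(x)

    def hrf(self, x):
        """Discrete hazard h(x) = p(x)/P(X >= x), in [0, 1]."""
        x = _check_counts(x)
        denom = PSI * self._expGt(x)  # 1 - F(x-1), with F(-1) = 0
        out = np.asarray(self.pmf(x)) / denom
        return out if out.ndim else float(out)

    def rvs(self, n: int, seed=None):
        """Draw ``n`` variates as the floor of continuous MKM draws.

        Exact: P(floor(Y) = x) = F_c(x+1) - F_c(x) = p(x), where Y follows
        the matching continuous model.
        """
        y = self.continuous.rvs(n, seed=seed)
        return np.floor(y).astype(np.int64)


def DMKME(theta: float, lam: float) -> DMKM:
    """Discrete MKM-exponential model with shape ``theta`` and rate ``lam``."""
    return DMKM(theta, Exponential(rate=lam))
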