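"""The MKM-G family of continuous lifetime distributions.

A random variable X follows the modified Kavya–Manoharan (MKM-G) family
when its CDF is

    F(x; theta) = psi * (1 - exp(-G(x)^theta)),      psi = e/(e-1),

where G is a baseline CDF on (0, inf) and theta > 0 an extra shape
parameter.  theta = 1 recovers the original Kavya–Manoharan (KM-G)
transformation.  The constant psi makes F a proper CDF: as G -> 1,
F -> psi*(1 - e^{-1}) = 1.

Named sub-models:

* :func:`MKME` — exponential baseline (shape ``theta``, rate ``lam``),
* :func:`MKMBXII` — Burr XII baseline,
* :func:`MKMBx` — Burr X baseline, exposed through ``eta = theta*beta``
  (the pair (theta, beta) is not separately identifiable, so the model is
  parameterized by ``(eta, lam)``),
* :func:`MKMLL` — log-logistic baseline.

The support convention is half-open (0, inf); the CDF is 0 for x <= 0.
For theta < 1 the density is unbounded at the origin: ``pdf`` returns
+inf there, and likelihood-based code should use :meth:`MKM.logpdf`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .baselines import Baseline, BurrX, BurrXII, Exponential, LogLogistic

__all__ = ["PSI", "MKM", "MKME", "MKMBXII", "MKMBx", "MKMLL"]

#: The normalizing constant psi = e/(e-1) of the family.  Fixed, never user-set.
PSI: float = math.e / (math.e - 1.0)


@dataclass(frozen=True)
class MKM:
    """A continuous MKM-G model: shape ``theta`` over a :class:`Baseline`."""

    theta: float
    baseline: Baseline
    psi: float = field(default=PSI, init=False, repr=False)

    def __post_init__(self):
        if not np.isfinite(self.theta) or self.theta <= 0:
            raise ValueError(f"parameter 'theta' must be a positive real, got {self.theta!r}")

    # -- distribution functions -------------------------------------------------

    def cdf(self, x):
        """F(x) = psi*(1 - exp(-G(x)^theta)); 0 for x <= 0."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("x must be nonnegative")
        out = np.zeros_like(x)
        pos = x > 0
        if np.any(pos):
            g = self.baseline.cdf(x[pos])
            out[pos] = PSI * -np.expm1(-(g**self.theta))
        return out if out.ndim else float(out)

    def sf(self, x):
        """Survival function 1 - F(x).

        Evaluated directly as psi*(exp(-G^theta) - e^{-1}), which stays
        accurate deep in the right tail where 1 - F loses all digits.
        """
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("x must be nonnegative")
        out = np.ones_like(x)
        pos = x > 0
        if np.any(pos):
            g = self.baseline.cdf(x[pos])
            out[pos] = PSI * (np.exp(-(g**self.theta)) - np.exp(-1.0))
        return out if out.ndim else float(out)

    def pdf(self, x):
        """f(x) = psi*theta*g(x)*G(x)^(theta-1)*exp(-G(x)^theta)."""
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("x must be positive")
        g = self.baseline.pdf(x)
        G = self.baseline.cdf(x)
        with np.errstate(divide="ignore"):
            out = PSI * self.theta * g * G ** (self.theta - 1) * np.exp(-(G**self.theta))
        return out if out.ndim else float(out)

    def logpdf(self, x):
        """log f(x), finite wherever f is positive and finite.

        Works directly in log space so that theta < 1 boundary behaviour
        and deep right tails do not overflow.
        """
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("x must be positive")
        g = self.baseline.pdf(x)
        G = self.baseline.cdf(x)
        with np.errstate(divide="ignore"):
            out = (
                np.log(PSI)
                + np.log(self.theta)
                + np.log(g)
                + (self.theta - 1) * np.log(G)
                - G**self.theta
            )
        return out if out.ndim else float(out)

    def hrf(self, x):
        """Hazard rate f(x)/S(x).

        Where S underflows to zero in the far right tail the hazard is
        reported as +inf (with a warning), never NaN.
        """
        x = np.asarray(x, dtype=float)
        f = np.asarray(self.pdf(x), dtype=float)
        s = np.asarray(self.sf(x), dtype=float)
        out = np.empty_like(f)
        ok = s > 0
        out[ok] = f[ok] / s[ok]
        if np.any(~ok):
            warnings.warn("survival function underflowed; hazard reported as +inf", RuntimeWarning)
            out[~ok] = np.inf
        return out if out.ndim else float(out)

    def ppf(self, u):
        """Quantile function Q(u) = G^{-1}([-log(1 - u/psi)]^{1/theta}).

        ``1 - u/psi`` is evaluated with ``log1p`` so the inversion stays
        accurate up to u = 1 - 1e-12.
        """
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0) | (u >= 1)):
            raise ValueError("u must lie in the open interval (0, 1)")
        t = (-np.log1p(-u / PSI)) ** (1.0 / self.theta)
        return self.baseline.ppf(t)

    def rvs(self, n: int, seed=None):
        """Draw ``n`` variates by inverse-transform sampling.

        ``seed`` may be an int, a :class:`numpy.random.SeedSequence`, or a
        :class:`numpy.random.Generator`; the same seed yields the same
        sample.
        """
        if n < 1:
            raise ValueError("n must be a positive integer")
        rng = np.random.default_rng(seed)
        u = rng.uniform(0.0, 1.0, size=n)
        # keep u strictly inside (0, 1); P(u == 0) is zero in double precision anyway
        u = np.clip(u, 1e-16, 1 - 1e-16)
        return self.ppf(u)


# -- named sub-models ----------------------------------------------------------


def MKME(theta: float, lam: float) -> MKM:
    """MKM-exponential model with shape ``theta`` and rate ``lam``."""
    return MKM(theta, Exponential(rate=lam))


def MKMBXII(theta: float, beta: float, lam: float) -> MKM:
    """MKM-Burr XII model with shapes ``theta``, ``beta``, ``lam``."""
    return MKM(theta, BurrXII(beta=beta, lam=lam))


def MKMBx(eta: float, lam: float) -> MKM:
    """MKM-Burr X model parameterized by ``eta = theta*beta`` and ``lam``.

    Because G^theta = (1-exp(-(lam x)^2))^(theta*beta), only the product
    ``eta`` is identifiable; the baseline is carried with beta = 1 and the
    family shape set to ``eta``.
    """
    return MKM(eta, BurrX(beta=1.0, lam=lam))


def MKMLL(theta: float, beta: float, lam: float) -> MKM:
    """MKM-log-logistic model with shape ``theta``, ``beta`` and scale ``lam``."""
    return MKM(theta, LogLogistic(beta=beta, lam=lam))
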