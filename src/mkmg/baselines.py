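"""Baseline lifetime distributions on (0, inf).

The generated families in :mod:`mkmg.family` and :mod:`mkmg.discrete` are
built on top of a baseline CDF ``G``.  Four baselines are provided —
exponential, Burr XII, Burr X, and log-logistic — each exposing the CDF
``G``, the density ``g``, and the closed-form inverse CDF ``G^{-1}``.

All parameters are strictly positive and validated at construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Baseline",
    "Exponential",
    "BurrXII",
    "BurrX",
    "LogLogistic",
    "make_baseline",
]


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"parameter {name!r} must be a positive real, got {value!r}")


def _check_support(x, what: str = "x"):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError(f"{what} must be positive")
    return x


def _check_unit(u):
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie in the open interval (0, 1)")
    return u


@dataclass(frozen=True)
class Baseline:
    """Abstract baseline distribution with support (0, inf)."""

    name = "baseline"

    @property
    def params(self) -> dict:
        return dict(self.__dict__)

    def cdf(self, x):
        raise NotImplementedError

    def pdf(self, x):
        raise NotImplementedError

    def ppf(self, u):
        raise NotImplementedError


@dataclass(frozen=True)
class Exponential(Baseline):
    """Exponential baseline, G(x) = 1 - exp(-rate*x)."""

    rate: float
    name = "exponential"

    def __post_init__(self):
        _require_positive(rate=self.rate)

    def cdf(self, x):
        x = _check_support(x)
        return -np.expm1(-self.rate * x)

    def pdf(self, x):
        x = _check_support(x)
        return self.rate * np.exp(-self.rate * x)

    def ppf(self, u):
        u = _check_unit(u)
        return -np.log1p(-u) / self.rate


@dataclass(frozen=True)
class BurrXII(Baseline):
    """Burr XII baseline, G(x) = 1 - (1 + x^lam)^(-beta)."""

    beta: float
    lam: float
    name = "burr12"

    def __post_init__(self):
        _require_positive(beta=self.beta, lam=self.lam)

    def cdf(self, x):
        x = _check_support(x)
        return -np.expm1(-self.beta * np.log1p(x**self.lam))

    def pdf(self, x):
        x = _check_support(x)
        return (
            self.beta
            * self.lam
            * x ** (self.lam - 1)
            * (1 + x**self.lam) ** (-self.beta - 1)
        )

    def ppf(self, u):
        u = _check_unit(u)
        return np.expm1(-np.log1p(-u) / self.beta) ** (1 / self.lam)


@dataclass(frozen=True)
class BurrX(Baseline):
    """Burr X baseline, G(x) = (1 - exp(-(lam*x)^2))^beta."""

    beta: float
    lam: float
    name = "burrx"

    def __post_init__(self):
        _require_positive(beta=self.beta, lam=self.lam)

    def cdf(self, x):
        x = _check_support(x)
        return (-np.expm1(-((self.lam * x) ** 2))) ** self.beta

    def pdf(self, x):
        x = _check_support(x)
        z = (self.lam * x) ** 2
        return (
            2
            * self.beta
            * self.lam**2
            * x
            * np.exp(-z)
            * (-np.expm1(-z)) ** (self.beta - 1)
        )

    def ppf(self, u):
        u = _check_unit(u)
        return np.sqrt(-np.log1p(-(u ** (1 / self.beta)))) / self.lam


@dataclass(frozen=True)
class LogLogistic(Baseline):
    """Log-logistic baseline, G(x) = 1 - [1 + (x/lam)^beta]^(-1).

    ``lam`` is a scale, ``beta`` a shape.
    """

    beta: float
    lam: float
    name = "loglogistic"

    def __post_init__(self):
        _require_positive(beta=self.beta, lam=self.lam)

    def cdf(self, x):
        x = _check_support(x)
        z = (x / self.lam) ** self.beta
        return z / (1 + z)

    def pdf(self, x):
        x = _check_support(x)
        z = (x / self.lam) ** self.beta
        return (self.beta / self.lam) * (x / self.lam) ** (self.beta - 1) / (1 + z) ** 2

    def ppf(self, u):
        u = _check_unit(u)
        return self.lam * (u / (1 - u)) ** (1 / self.beta)


_REGISTRY = {
    "exponential": Exponential,
    "burr12": BurrXII,
    "burrx": BurrX,
    "loglogistic": LogLogistic,
}


def make_baseline(name: str, **params: float) -> Baseline:
    """Construct a baseline by registry name.

    Parameters
    ----------
    name:
        One of ``exponential``, ``burr12``, ``burrx``, ``loglogistic``.
    params:
        Named positive parameters (``rate`` for the exponential; ``beta``
        and ``lam`` for the others).
    """
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise ValueError(f"unknown baseline {name!r}; choose from {sorted(_REGISTRY)}") from None
    return cls(**params)
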