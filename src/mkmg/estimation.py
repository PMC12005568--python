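"""Classical estimators for MKM models.

Eight estimation methods are provided for the MKM-exponential (MKME)
model: maximum likelihood (``mle``), ordinary and weighted least squares
on the distribution function (``lse``/``wlse``), maximum product of
spacings (``mpse``), percentiles (``pce``), and the minimum-distance
Cramér–von Mises, Anderson–Darling and right-tail Anderson–Darling
estimators (``cvme``/``ade``/``rtade``).  Maximum likelihood is also
available for the discrete DMKME model and, generically, for the Burr
XII, Burr X, and log-logistic sub-models.

All methods optimize on the log-parameter scale with Nelder–Mead.  The
default start is (theta, lam) = (1, 1/mean(x)); because the profile
objective in theta can be extremely flat (real datasets can put the
optimum near theta = 50), the returned optimum is always screened
against a 5x5 log-spaced grid over theta in [0.1, 50] and
lam in [0.1/mean, 10/mean], and re-polished from any grid point that
beats it.

Ties in the sample give zero spacings in the MPS criterion; following
the Cheng–Amin convention a tied spacing is replaced by the density at
the tied point.

Standard errors (ML only) are square roots of the diagonal of the
inverse observed information, with the Hessian formed by central finite
differences using relative steps of 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .discrete import DMKM, DMKME
from .family import PSI, MKM, MKMBXII, MKMBx, MKME, MKMLL

__all__ = [
    "METHODS",
    "FitResult",
    "loglik_mkme",
    "fit",
    "standard_errors",
    "fit_exponential",
    "fit_geometric",
    "model_from_fit",
    "delta1",
    "delta2",
    "objective_gradient",
]

METHODS = ("mle", "lse", "wlse", "mpse", "pce", "cvme", "ade", "rtade")

_LOG_FLOOR = 1e-300


@dataclass
class FitResult:
    """Outcome of a parameter fit.

    ``objective`` stores the criterion actually optimized: the maximized
    log-likelihood for ``mle``, the maximized mean log-spacing for
    ``mpse``, and the minimized distance for the remaining methods.
    """

    method: str
    family: str
    estimates: dict
    objective: float
    converged: bool
    n_iter: int
    starts_used: int
    ses: dict | None = None
    n: int = 0

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "family": self.family,
            "estimates": dict(self.estimates),
            "objective": self.objective,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "starts_used": self.starts_used,
            "n": self.n,
        }
        if self.ses is not None:
            out["ses"] = dict(self.ses)
        return out


# -- MKME criteria -------------------------------------------------------------


def _check_sample(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("sample must be one-dimensional with at least 3 observations")
    if np.all(x == x[0]):
        raise ValueError("degenerate sample: all observations equal")
    return x


def loglik_mkme(theta: float, lam: float, x) -> float:
    """MKME log-likelihood.

    l = n log psi + n log theta + n log lam - sum p_i^theta - lam sum x_i
        + (theta-1) sum log p_i,  with p_i = 1 - exp(-lam x_i).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("observations must be positive")
    if theta <= 0 or lam <= 0:
        raise ValueError("theta and lam must be positive")
    n = x.size
    p = -np.expm1(-lam * x)
    return float(
        n * np.log(PSI)
        + n * np.log(theta)
        + n * np.log(lam)
        - (p**theta).sum()
        - lam * x.sum()
        + (theta - 1) * np.log(p).sum()
    )


def _mkme_cdf_sorted(theta, lam, xs):
    p = -np.expm1(-lam * xs)
    return PSI * -np.expm1(-(p**theta))


def _mkme_pdf_sorted(theta, lam, xs):
    p = -np.expm1(-lam * xs)
    return PSI * theta * lam * np.exp(-lam * xs) * p ** (theta - 1) * np.exp(-(p**theta))


def _wls_weights(n: int) -> np.ndarray:
    i = np.arange(1, n + 1)
    return (n + 1) ** 2 * (n + 2) / (i * (n - i + 1))


def _mkme_objective(method: str, theta: float, lam: float, xs: np.ndarray) -> float:
    """Minimized criterion for MKME; xs must be sorted ascending."""
    n = xs.size
    i = np.arange(1, n + 1)
    if method == "mle":
        return -loglik_mkme(theta, lam, xs)
    if method in ("lse", "wlse"):
        F = _mkme_cdf_sorted(theta, lam, xs)
        d = 1.0 if method == "lse" else _wls_weights(n)
        return float((d * (F - i / (n + 1)) ** 2).sum())
    if method == "mpse":
        F = _mkme_cdf_sorted(theta, lam, xs)
        D = np.diff(np.concatenate(([0.0], F, [1.0])))
        tied = np.concatenate(([False], np.diff(xs) == 0))
        if tied.any():
            # Cheng–Amin: a zero spacing from a tie is replaced by the density
            D[:n][tied] = _mkme_pdf_sorted(theta, lam, xs[tied])
        return float(-np.log(np.maximum(D, _LOG_FLOOR)).mean())
    if method == "pce":
        p = i / (n + 1)
        q = -np.log1p(-((-np.log1p(-p / PSI)) ** (1 / theta))) / lam
        return float(((xs - q) ** 2).sum())
    if method == "cvme":
        F = _mkme_cdf_sorted(theta, lam, xs)
        return float(1 / (12 * n) + ((F - (2 * i - 1) / (2 * n)) ** 2).sum())
    if method == "ade":
        F = _mkme_cdf_sorted(theta, lam, xs)
        S = 1.0 - F
        lo = np.log(np.maximum(F, _LOG_FLOOR))
        ls = np.log(np.maximum(S[::-1], _LOG_FLOOR))
        return float(-n - ((2 * i - 1) * (lo + ls)).sum() / n)
    if method == "rtade":
        F = _mkme_cdf_sorted(theta, lam, xs)
        S = 1.0 - F
        ls = np.log(np.maximum(S[::-1], _LOG_FLOOR))
        return float(n / 2 - 2 * F.sum() - ((2 * i - 1) * ls).sum() / n)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


# -- analytic gradients of the distance criteria -------------------------------


def delta1(theta: float, lam: float, x) -> np.ndarray:
    """dF/dtheta = psi p^theta exp(-p^theta) log p, p = 1 - exp(-lam x)."""
    x = np.asarray(x, dtype=float)
    p = -np.expm1(-lam * x)
    return PSI * p**theta * np.exp(-(p**theta)) * np.log(p)


def delta2(theta: float, lam: float, x) -> np.ndarray:
    """dF/dlam = psi theta x exp(-lam x) p^(theta-1) exp(-p^theta)."""
    x = np.asarray(x, dtype=float)
    p = -np.expm1(-lam * x)
    return PSI * theta * x * np.exp(-lam * x) * p ** (theta - 1) * np.exp(-(p**theta))


def objective_gradient(method: str, theta: float, lam: float, xs) -> np.ndarray:
    """Analytic (d/dtheta, d/dlam) of the distance criteria.

    Available for ``lse``, ``wlse``, ``cvme``, ``ade`` and ``rtade``.
    """
    xs = np.sort(np.asarray(xs, dtype=float))
    n = xs.size
    i = np.arange(1, n + 1)
    D1, D2 = delta1(theta, lam, xs), delta2(theta, lam, xs)
    F = _mkme_cdf_sorted(theta, lam, xs)
    if method in ("lse", "wlse"):
        d = 1.0 if method == "lse" else _wls_weights(n)
        r = d * (F - i / (n + 1))
        return np.array([2 * (r * D1).sum(), 2 * (r * D2).sum()])
    if method == "cvme":
        r = F - (2 * i - 1) / (2 * n)
        return np.array([2 * (r * D1).sum(), 2 * (r * D2).sum()])
    if method == "ade":
        S = 1.0 - F
        w = 2 * i - 1
        g1 = -(w * (D1 / F - D1[::-1] / S[::-1])).sum() / n
        g2 = -(w * (D2 / F - D2[::-1] / S[::-1])).sum() / n
        return np.array([g1, g2])
    if method == "rtade":
        S = 1.0 - F
        w = 2 * i - 1
        g1 = -2 * D1.sum() + (w * D1[::-1] / S[::-1]).sum() / n
        g2 = -2 * D2.sum() + (w * D2[::-1] / S[::-1]).sum() / n
        return np.array([g1, g2])
    raise ValueError("analytic gradient available for lse/wlse/cvme/ade/rtade only")


# -- optimizer drivers ---------------------------------------------------------

_NM_OPTS = dict(xatol=1e-10, fatol=1e-12, maxiter=4000, maxfev=4000)


def _minimize(fun, start_log):
    return optimize.minimize(fun, start_log, method="Nelder-Mead", options=_NM_OPTS)


def _grid_starts(xbar: float):
    for t0 in np.geomspace(0.1, 50, 5):
        for l0 in np.geomspace(0.1 / xbar, 10 / xbar, 5):
            yield (t0, l0)


def _fit_two_param(obj, xbar: float):
    """Minimize obj(log-params) from the default start, with grid rescue.

    The returned optimum is screened against a 5x5 log-grid of raw
    objective values; a re-polish is launched only when a grid point beats
    the optimum found (flat-ridge insurance) or the first run failed.
    """
    best = _minimize(obj, np.log([1.0, 1.0 / xbar]))
    starts_used = 1
    grid = [np.log(s) for s in _grid_starts(xbar)]
    vals = np.array([obj(g) for g in grid])
    order = np.argsort(vals)
    rescue = list(order[:3]) if not best.success else [
        idx for idx in order[:3] if vals[idx] < best.fun
    ]
    for idx in rescue:
        r = _minimize(obj, grid[idx])
        starts_used += 1
        if r.fun < best.fun:
            best = r
    return best, starts_used


def _nll_family(family: str):
    if family == "mkme":
        return (("theta", "lam"), lambda p, x: -loglik_mkme(p[0], p[1], x))
    if family == "dmkme":

        def nll(p, x):
            return -float(DMKME(p[0], p[1]).logpmf(x).sum())

        return (("theta", "lam"), nll)
    if family == "mkmbx12":
        return (
            ("theta", "beta", "lam"),
            lambda p, x: -float(MKMBXII(*p).logpdf(x).sum()),
        )
    if family == "mkmbx":
        return (("eta", "lam"), lambda p, x: -float(MKMBx(*p).logpdf(x).sum()))
    if family == "mkmll":
        return (
            ("theta", "beta", "lam"),
            lambda p, x: -float(MKMLL(*p).logpdf(x).sum()),
        )
    raise ValueError(f"unknown family {family!r}")


def fit(sample, method: str = "mle", family: str = "mkme") -> FitResult:
    """Fit a model to a univariate sample.

    Parameters
    ----------
    sample:
        Positive reals (continuous families) or nonnegative integers
        (``dmkme``).
    method:
        One of :data:`METHODS` for ``family="mkme"``; only ``"mle"`` is
        supported for the other families.
    family:
        ``mkme`` (default), ``dmkme``, ``mkmbx12``, ``mkmbx`` or ``mkmll``.
    """
    if family == "mkme":
        x = _check_sample(sample)
        if np.any(x <= 0):
            raise ValueError("observations must be positive")
        xs = np.sort(x)
        xbar = float(x.mean())
        sign = -1.0 if method in ("mle", "mpse") else 1.0

        def obj(lp):
            th, lam = np.exp(lp)
            with np.errstate(all="ignore"):
                v = _mkme_objective(method, th, lam, xs)
            return v if np.isfinite(v) else 1e12

        best, starts = _fit_two_param(obj, xbar)
        th, lam = np.exp(best.x)
        res = FitResult(
            method=method,
            family=family,
            estimates={"theta": float(th), "lam": float(lam)},
            objective=float(-best.fun if sign < 0 else best.fun),
            converged=bool(best.success),
            n_iter=int(best.nit),
            starts_used=starts,
            n=xs.size,
        )
        if method == "mle" and res.converged:
            res.ses = standard_errors(sample, res.estimates, family="mkme")
        return res

    if method != "mle":
        raise ValueError(f"family {family!r} supports only method='mle'")

    names, nll = _nll_family(family)
    if family == "dmkme":
        x = np.asarray(sample)
        if np.any(x < 0) or np.any(np.floor(x) != x):
            raise ValueError("dmkme requires nonnegative integer observations")
        x = x.astype(float)
        if x.size < 3 or np.all(x == x[0]):
            raise ValueError("sample must hold at least 3 non-identical observations")
        xbar = max(float(x.mean()), 0.5)

        def obj(lp):
            with np.errstate(all="ignore"):
                v = nll(np.exp(lp), x)
            return v if np.isfinite(v) else 1e12

        best = None
        starts = 0
        for t0 in np.geomspace(0.1, 50, 5):
            for l0 in np.geomspace(0.01 / xbar, 10 / xbar, 6):
                r = _minimize(obj, np.log([t0, l0]))
                starts += 1
                if best is None or r.fun < best.fun:
                    best = r
        est = dict(zip(names, np.exp(best.x).tolist()))
        res = FitResult(
            method="mle",
            family=family,
            estimates=est,
            objective=float(-best.fun),
            converged=bool(best.success),
            n_iter=int(best.nit),
            starts_used=starts,
            n=x.size,
        )
        if res.converged:
            res.ses = standard_errors(sample, est, family=family)
        return res

    # generic continuous three/two-parameter sub-models
    x = _check_sample(sample)
    if np.any(x <= 0):
        raise ValueError("observations must be positive")

    def obj(lp):
        with np.errstate(all="ignore"):
            v = nll(np.exp(lp), x)
        return v if np.isfinite(v) else 1e12

    scale = float(np.median(x))
    best = None
    starts = 0
    shape_grid = (0.5, 1.0, 2.0, 5.0)
    for t0 in shape_grid:
        for b0 in (0.5, 1.0, 2.0):
            if family == "mkmbx":
                s0 = np.log([t0 * b0, 1.0 / scale])
            elif family == "mkmll":
                s0 = np.log([t0, b0 + 1.0, scale])
            else:  # mkmbx12: lam is a power shape, start near 1
                s0 = np.log([t0, b0, 1.0])
            r = _minimize(obj, s0)
            starts += 1
            if best is None or r.fun < best.fun:
                best = r
    est = dict(zip(names, np.exp(best.x).tolist()))
    res = FitResult(
        method="mle",
        family=family,
        estimates=est,
        objective=float(-best.fun),
        converged=bool(best.success),
        n_iter=int(best.nit),
        starts_used=starts,
        n=x.size,
    )
    if res.converged:
        try:
            res.ses = standard_errors(sample, est, family=family)
        except np.linalg.LinAlgError:
            res.ses = None
    return res


def standard_errors(sample, estimates: dict, family: str = "mkme") -> dict | None:
    """ML standard errors from the inverse observed information.

    The Hessian of the negative log-likelihood is formed by central finite
    differences at the MLE with relative steps 1e-4; a non-positive-definite
    Hessian yields ``None`` with a warning.
    """
    names, nll = _nll_family(family)
    x = np.asarray(sample, dtype=float)
    p0 = np.array([estimates[k] for k in names], dtype=float)
    h = 1e-4 * p0
    k = p0.size
    H = np.zeros((k, k))

    def f(v):
        with np.errstate(all="ignore"):
            return nll(v, x)

    for a in range(k):
        for b in range(k):
            vpp = p0.copy(); vpp[a] += h[a]; vpp[b] += h[b]
            vpm = p0.copy(); vpm[a] += h[a]; vpm[b] -= h[b]
            vmp = p0.copy(); vmp[a] -= h[a]; vmp[b] += h[b]
            vmm = p0.copy(); vmm[a] -= h[a]; vmm[b] -= h[b]
            H[a, b] = (f(vpp) - f(vpm) - f(vmp) + f(vmm)) / (4 * h[a] * h[b])
    H = (H + H.T) / 2
    eig = np.linalg.eigvalsh(H)
    if np.any(eig <= 0):
        import warnings

        warnings.warn("observed information is not positive definite; no SEs", RuntimeWarning)
        return None
    cov = np.linalg.inv(H)
    return {k_: float(np.sqrt(cov[ii, ii])) for ii, k_ in enumerate(names)}


# -- sanity baselines ----------------------------------------------------------


@dataclass(frozen=True)
class _ExpModel:
    lam: float

    def cdf(self, x):
        return -np.expm1(-self.lam * np.asarray(x, dtype=float))

    def pdf(self, x):
        return self.lam * np.exp(-self.lam * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class _GeomModel:
    """Geometric on {0, 1, 2, ...} with success probability p."""

    p: float

    def cdf(self, x):
        x = np.floor(np.asarray(x, dtype=float))
        return -np.expm1((x + 1) * np.log1p(-self.p))

    def pmf(self, x):
        x = np.asarray(x, dtype=float)
        return self.p * (1 - self.p) ** x


def fit_exponential(sample) -> FitResult:
    """Plain exponential ML fit: lam = 1/mean, SE = lam/sqrt(n)."""
    x = _check_sample(sample)
    lam = 1.0 / float(x.mean())
    ll = float(x.size * np.log(lam) - lam * x.sum())
    return FitResult(
        method="mle",
        family="exponential",
        estimates={"lam": lam},
        ses={"lam": lam / np.sqrt(x.size)},
        objective=ll,
        converged=True,
        n_iter=0,
        starts_used=1,
        n=x.size,
    )


def fit_geometric(sample) -> FitResult:
    """Geometric (support {0,1,...}) ML fit: p = 1/(1 + mean)."""
    x = np.asarray(sample, dtype=float)
    if np.any(x < 0) or np.any(np.floor(x) != x):
        raise ValueError("geometric requires nonnegative integer observations")
    n = x.size
    p = 1.0 / (1.0 + float(x.mean()))
    ll = float(n * np.log(p) + x.sum() * np.log1p(-p))
    # observed information for p: n/p^2 + sum(x)/(1-p)^2
    info = n / p**2 + x.sum() / (1 - p) ** 2
    return FitResult(
        method="mle",
        family="geometric",
        estimates={"p": p},
        ses={"p": float(1 / np.sqrt(info))},
        objective=ll,
        converged=True,
        n_iter=0,
        starts_used=1,
        n=n,
    )


def model_from_fit(result: FitResult):
    """Reconstruct a distribution object from a :class:`FitResult`."""
    e = result.estimates
    if result.family == "mkme":
        return MKME(e["theta"], e["lam"])
    if result.family == "dmkme":
        return DMKME(e["theta"], e["lam"])
    if result.family == "mkmbx12":
        return MKMBXII(e["theta"], e["beta"], e["lam"])
    if result.family == "mkmbx":
        return MKMBx(e["eta"], e["lam"])
    if result.family == "mkmll":
        return MKMLL(e["theta"], e["beta"], e["lam"])
    if result.family == "exponential":
        return _ExpModel(e["lam"])
    if result.family == "geometric":
        return _GeomModel(e["p"])
    raise ValueError(f"unknown family {result.family!r}")
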