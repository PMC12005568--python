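"""Moments, series expansion, entropy, curves and order statistics."""

import numpy as np
import pytest
from scipy import integrate, special

from mkmg import (
    MKME,
    PSI,
    bonferroni_lorenz,
    incomplete_moment,
    mean_deviations,
    mit,
    mkme_moment_series,
    moment_numeric,
    moment_summary,
    mrl,
    order_stat_pdf,
    pwm,
    quantile_shape,
    renyi_entropy,
    shannon_entropy,
)
from mkmg.properties import _gen_binom

# -- published moment table (rate, shape) -> mean, variance, SK, KU ------------

MOMENT_TABLE = [
    (0.2, 0.5, 2.1863, 12.4411, 3.2662, 18.6635),
    (0.2, 0.75, 3.0696, 16.0281, 2.7305, 14.1281),
    (0.2, 10, 13.0473, 31.9048, 1.4482, 6.6978),
    (0.5, 0.5, 0.8745, 1.9906, 3.2662, 18.6635),
    (1.5, 5, 1.3172, 0.5284, 1.5725, 7.1999),
]


@pytest.mark.parametrize("lam,theta,mean,var,sk,ku", MOMENT_TABLE)
def test_moment_summary_reproduces_reference_values(lam, theta, mean, var, sk, ku):
    s = moment_summary(MKME(theta, lam))
    assert s.mean == pytest.approx(mean, abs=1.5e-4)
    assert s.variance == pytest.approx(var, abs=1.5e-4)
    assert s.skewness == pytest.approx(sk, abs=1.5e-4)
    assert s.kurtosis == pytest.approx(ku, abs=1.5e-4)
    # Pearson inequality
    assert s.kurtosis >= s.skewness**2 + 1


def test_standardized_moments_are_scale_free():
    a = moment_summary(MKME(0.75, 0.2))
    b = moment_summary(MKME(0.75, 2.0))
    assert a.skewness == pytest.approx(b.skewness, rel=1e-7)
    assert a.kurtosis == pytest.approx(b.kurtosis, rel=1e-7)


def test_moment_numeric_basics():
    m = MKME(0.8, 0.9)
    assert moment_numeric(m, 0) == 1.0
    assert moment_numeric(m, 1) == pytest.approx(0.7181, abs=1e-4)
    with pytest.raises(ValueError):
        moment_numeric(m, -1)


# -- truncated series ----------------------------------------------------------

SERIES_TABLE = [
    # lam, theta, M, printed partial sum
    (0.5, 0.5, 10, 0.8592), (0.5, 0.5, 15, 0.8656), (0.5, 0.5, 25, 0.8702), (0.5, 0.5, 50, 0.8729),
    (0.5, 0.8, 10, 1.2880), (0.5, 0.8, 50, 1.2922),
    (0.5, 2.5, 10, 2.7412), (0.5, 2.5, 15, 2.7893), (0.5, 2.5, 25, 2.7898), (0.5, 2.5, 50, 2.7898),
    (0.9, 0.5, 10, 0.4773), (0.9, 0.8, 10, 0.7156), (0.9, 2.5, 50, 1.5499),
    (1.5, 0.5, 10, 0.2864), (1.5, 0.8, 50, 0.4308), (1.5, 2.5, 10, 0.9137),
]


@pytest.mark.parametrize("lam,theta,M,expected", SERIES_TABLE)
def test_series_partial_sums_reproduce_reference(lam, theta, M, expected):
    assert mkme_moment_series(theta, lam, 1, M) == pytest.approx(expected, abs=1.5e-4)


@pytest.mark.parametrize("lam,theta", [(0.5, 0.5), (0.5, 0.8), (0.5, 2.5), (0.9, 0.8)])
def test_series_converges_to_quadrature(lam, theta):
    quad = moment_numeric(MKME(theta, lam), 1)
    assert abs(mkme_moment_series(theta, lam, 1, 50) - quad) <= 2e-3
    # converged inner sum at high outer order nails the quadrature value
    assert mkme_moment_series(theta, lam, 1, 120, inner="converged") == pytest.approx(quad, abs=5e-4)


def test_series_scale_law():
    assert mkme_moment_series(1.5, 2.0, 1, 30) == pytest.approx(
        mkme_moment_series(1.5, 1.0, 1, 30) / 2.0, rel=1e-12
    )


def test_series_rejects_bad_arguments():
    with pytest.raises(ValueError):
        mkme_moment_series(1.0, 1.0, 0, 10)
    with pytest.raises(ValueError):
        mkme_moment_series(-1.0, 1.0, 1, 10)


def test_generalized_binomial_matches_falling_factorial():
    for a in (2.7, -0.3, 4.0, -2.0):
        for m in range(6):
            prod = np.prod([a - j for j in range(m)]) / special.factorial(m)
            assert float(_gen_binom(a, m)) == pytest.approx(prod, rel=1e-12, abs=1e-12)


def test_mixture_representation_partial_sums_converge():
    # F = psi - sum_k a_k G^{k theta},  a_k = psi (-1)^k / k!
    theta, lam = 1.7, 0.6
    m = MKME(theta, lam)
    x = np.linspace(0.2, 6.0, 30)
    G = -np.expm1(-lam * x)
    prev_err = None
    for K in (2, 5, 10, 20):
        k = np.arange(0, K + 1)
        ak = PSI * (-1.0) ** k / special.factorial(k)
        approx = PSI - (ak[:, None] * G[None, :] ** (k[:, None] * theta)).sum(axis=0)
        err = np.max(np.abs(approx - m.cdf(x)))
        if prev_err is not None:
            assert err < prev_err
        prev_err = err
    assert prev_err < 1e-10


# -- incomplete moments, curves, deviations ------------------------------------


def test_incomplete_moment_limits_and_mc():
    m = MKME(1.5, 0.8)
    mu = moment_numeric(m, 1)
    assert incomplete_moment(m, 1, 1e6) == pytest.approx(mu, rel=1e-8)
    t = float(m.ppf(0.5))
    assert incomplete_moment(m, 1, t) < mu
    draws = m.rvs(200_000, seed=31)
    est = np.mean(draws * (draws <= t))
    se = np.std(draws * (draws <= t)) / np.sqrt(draws.size)
    assert abs(incomplete_moment(m, 1, t) - est) < 3 * se


def test_bonferroni_lorenz_shape():
    m = MKME(0.9, 0.4)
    B, L = bonferroni_lorenz(m, 1 - 1e-9)
    assert B == pytest.approx(1.0, abs=1e-6)
    assert L == pytest.approx(1.0, abs=1e-6)
    for tau in (0.1, 0.3, 0.5, 0.8):
        B, L = bonferroni_lorenz(m, tau)
        assert L <= tau + 1e-12
        assert 0 < B <= 1 + 1e-12


def test_mean_deviations_match_monte_carlo():
    m = MKME(1.2, 0.7)
    phi1, phi2 = mean_deviations(m)
    assert phi1 >= 0 and phi2 >= 0
    draws = m.rvs(200_000, seed=13)
    mu, med = moment_numeric(m, 1), float(m.ppf(0.5))
    for phi, ref in [(phi1, np.abs(draws - mu)), (phi2, np.abs(draws - med))]:
        se = ref.std() / np.sqrt(ref.size)
        assert abs(phi - ref.mean()) < 3 * se


def test_mrl_and_mit():
    m = MKME(1.5, 0.8)
    mu = moment_numeric(m, 1)
    assert mrl(m, 1e-9) == pytest.approx(mu, rel=1e-6)
    t = float(m.ppf(0.7))
    assert 0 <= mit(m, t) <= t
    draws = m.rvs(200_000, seed=17)
    tail = draws[draws > t] - t
    se = tail.std() / np.sqrt(tail.size)
    assert abs(mrl(m, t) - tail.mean()) < 3 * se
    with pytest.raises(ValueError):
        mrl(m, -1.0)


# -- entropies -----------------------------------------------------------------


def test_renyi_entropy_monotone_in_order():
    m = MKME(1.5, 0.8)
    vals = [renyi_entropy(m, phi) for phi in (0.5, 0.8, 1.2, 2.0, 4.0)]
    assert np.all(np.diff(vals) <= 1e-10)


def test_renyi_tends_to_shannon():
    m = MKME(2.0, 0.6)
    s = shannon_entropy(m)
    assert renyi_entropy(m, 1 + 1e-4) == pytest.approx(s, abs=1e-3)
    assert renyi_entropy(m, 1 - 1e-4) == pytest.approx(s, abs=1e-3)


def test_shannon_entropy_matches_monte_carlo():
    m = MKME(1.0, 0.5)
    draws = m.rvs(200_000, seed=23)
    lp = m.logpdf(draws)
    se = lp.std() / np.sqrt(lp.size)
    assert abs(shannon_entropy(m) - (-lp.mean())) < 3 * se


def test_entropy_scale_shift():
    m1, m2 = MKME(1.5, 2.0), MKME(1.5, 1.0)
    assert renyi_entropy(m1, 2.0) == pytest.approx(renyi_entropy(m2, 2.0) - np.log(2.0), abs=1e-8)


def test_renyi_domain_error_near_origin():
    # theta*phi - phi + 1 <= 0: non-integrable f^phi
    with pytest.raises(ValueError, match="integrable"):
        renyi_entropy(MKME(0.4, 1.0), 2.0)


# -- quantile shape, PWMs, order statistics ------------------------------------


def test_quantile_shape_measures():
    gs, mk = quantile_shape(MKME(0.5, 1.0))
    assert -1 < gs < 1
    assert gs > 0  # right-skewed, consistent with moment skewness 3.27
    gs2, _ = quantile_shape(MKME(0.5, 7.3))
    assert gs == pytest.approx(gs2, rel=1e-9)


def test_pwm_reductions_and_mc():
    m = MKME(1.3, 0.9)
    assert pwm(m, 2, 0) == pytest.approx(moment_numeric(m, 2), rel=1e-8)
    for i in (1, 2, 5):
        assert pwm(m, 0, i) == pytest.approx(1 / (i + 1), rel=1e-8)
    draws = m.rvs(200_000, seed=29)
    ref = draws * m.cdf(draws)
    se = ref.std() / np.sqrt(ref.size)
    assert abs(pwm(m, 1, 1) - ref.mean()) < 3 * se


def test_order_statistic_pdf():
    m = MKME(1.5, 0.8)
    x = np.linspace(0.1, 5.0, 7)
    assert np.allclose(order_stat_pdf(m, 1, 1, x), m.pdf(x), rtol=1e-12)
    hi = float(m.ppf(1 - 1e-10))
    total, _ = integrate.quad(lambda t: order_stat_pdf(m, 2, 5, t), 0, hi, limit=200)
    assert total == pytest.approx(1.0, abs=1e-6)
    mean_25, _ = integrate.quad(lambda t: t * order_stat_pdf(m, 2, 5, t), 0, hi, limit=200)
    samples = m.rvs(5 * 20_000, seed=37).reshape(20_000, 5)
    second = np.sort(samples, axis=1)[:, 1]
    se = second.std() / np.sqrt(second.size)
    assert abs(mean_25 - second.mean()) < 3 * se
    with pytest.raises(ValueError):
        order_stat_pdf(m, 6, 5, 1.0)
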