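"""Superstatistical gamma-mixture model of internucleotide intervals.

The model treats a chromosome as a chain of L = 150 bp segments.  Within a
segment, positions of a symbol class are random, so intervals l between
consecutive occurrences are locally exponential with rate beta = n/L (the
local class fraction, acting as the intensity parameter).  Across segments
n fluctuates; taking its distribution to be a gamma law with shape
alpha = 1/rho^2 and rate lambda = alpha/<n> (moment-matched to the
observed mean <n> and standard deviation sigma_n, rho = sigma_n/<n>), the
law of total probability gives the marginal interval density in closed
form:

    P(l) = alpha * s^alpha / (s + l)^(alpha + 1),   s = alpha * L / <n>,

a Lomax (Pareto-II) density whose tail decays as l^-(alpha+1).  It is
asymptotically a q-exponential with entropic index q = 1 + rho^2; the
exact tail-exponent correspondence is alpha = 1/(q-1) - 1, which for the
small rho of real genomes coincides with 1/(q-1) to within rho^2.

Because sequence positions are integers, the package also provides the
discrete counterpart (a gamma mixture of geometric laws) for comparisons
with empirical interval histograms at short mean intervals, where the
continuum density is visibly off at l = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .segments import DEFAULT_SEGMENT_LENGTH, SegmentStats


@dataclass(frozen=True)
class GammaSuperstatModel:
    """Parameter bundle (alpha, lambda, <n>, rho, q) of the gamma model.

    ``lam`` lives on the per-segment-count axis (lam = alpha/<n>); the
    per-bp interval scale used by the marginal law is
    ``interval_scale = alpha * L / <n>``.
    """

    alpha: float
    lam: float
    mean_n: float
    rho: float
    q: float
    segment_length: int = DEFAULT_SEGMENT_LENGTH

    @property
    def mean_beta(self) -> float:
        """Mean per-bp occurrence rate <beta> = <n>/L."""
        return self.mean_n / self.segment_length

    @property
    def interval_scale(self) -> float:
        """Scale s of the Lomax marginal, in bp: s = alpha/<beta>."""
        return self.alpha / self.mean_beta


def model_from_moments(
    mean_n: float,
    sigma_n: float,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
) -> GammaSuperstatModel:
    """Moment-match the gamma intensity law to observed segment statistics.

    alpha = 1/rho^2, lambda = alpha/<n> and q = 1 + rho^2 with
    rho = sigma_n/<n>.
    """
    if mean_n <= 0 or sigma_n <= 0:
        raise ValueError("mean_n and sigma_n must be positive")
    rho = sigma_n / mean_n
    alpha = 1.0 / rho**2
    lam = alpha / mean_n
    return GammaSuperstatModel(alpha, lam, mean_n, rho, 1.0 + rho**2, segment_length)


def model_from_stats(stats_: SegmentStats) -> GammaSuperstatModel:
    return model_from_moments(stats_.mean_n, stats_.sigma_n, stats_.segment_length)


def gamma_intensity_pdf(model: GammaSuperstatModel, beta) -> np.ndarray:
    """Gamma density of the local intensity beta = n/L.

    Shape alpha; scale chosen so the mean is <n>/L and the variance
    (sigma_n/L)^2.  The support (0, inf) slightly exceeds the physical
    bound beta <= 1; see :func:`truncated_gamma_intensity_pdf`.
    """
    beta = np.asarray(beta, dtype=np.float64)
    scale = model.mean_beta / model.alpha
    return stats.gamma.pdf(beta, a=model.alpha, scale=scale)


def truncated_gamma_intensity_pdf(model: GammaSuperstatModel, beta) -> np.ndarray:
    """Gamma intensity density truncated to the physical range (0, 1]."""
    beta = np.asarray(beta, dtype=np.float64)
    scale = model.mean_beta / model.alpha
    mass = stats.gamma.cdf(1.0, a=model.alpha, scale=scale)
    out = stats.gamma.pdf(beta, a=model.alpha, scale=scale) / mass
    return np.where((beta > 0) & (beta <= 1.0), out, 0.0)


def marginal_interval_pdf(model: GammaSuperstatModel, l) -> np.ndarray:
    """Closed-form marginal interval density (Lomax / Pareto-II).

    P(l) = alpha * s^alpha * (s + l)^-(alpha+1) with s = alpha * L / <n>;
    equal to the gamma-weighted average of local exponential laws
    integral Gamma(beta) * beta * exp(-beta l) dbeta.
    """
    l = np.asarray(l, dtype=np.float64)
    a, s = model.alpha, model.interval_scale
    # log-space evaluation: s^alpha overflows for alpha ~ hundreds
    log_pdf = np.log(a) + a * np.log(s) - (a + 1.0) * np.log(s + l)
    return np.exp(log_pdf)


def marginal_interval_sf(model: GammaSuperstatModel, l) -> np.ndarray:
    """Survival function of the closed-form marginal, P(L > l)."""
    l = np.asarray(l, dtype=np.float64)
    a, s = model.alpha, model.interval_scale
    return np.exp(a * (np.log(s) - np.log(s + l)))


def marginal_interval_pdf_quadrature(model: GammaSuperstatModel, l) -> np.ndarray:
    """Direct adaptive quadrature of the mixture integral (oracle path).

    Numerically integrates Gamma(beta) * beta * exp(-beta l) over beta;
    used to validate the closed form, not for production evaluation.
    """
    from scipy.special import gammaln

    rate = model.alpha / model.mean_beta  # gamma rate on the beta axis
    a = model.alpha

    def one(li: float) -> float:
        # P(l) = rate^a / Gamma(a) * int beta^a exp(-beta (rate + l)) dbeta.
        # The integrand is factored by its peak value so the far tail
        # (densities below double-precision underflow of the raw integrand)
        # is still resolved at full relative precision.
        total_rate = rate + li
        peak_beta = a / total_rate
        log_peak = a * np.log(peak_beta) - a

        def integrand(b: float) -> float:
            if b <= 0:
                return 0.0
            return np.exp(a * np.log(b) - b * total_rate - log_peak)

        val, _ = integrate.quad(
            integrand, 0.0, np.inf, limit=400, epsabs=0.0, epsrel=1e-10
        )
        log_p = np.log(val) + log_peak + a * np.log(rate) - gammaln(a)
        return float(np.exp(log_p))

    l = np.atleast_1d(np.asarray(l, dtype=np.float64))
    return np.array([one(float(li)) for li in l])


def marginal_interval_pmf(
    model: GammaSuperstatModel, l_max: int, n_nodes: int = 600
) -> np.ndarray:
    """Discrete marginal law on integer intervals l = 1..l_max.

    Mixes the geometric in-segment law P(l|beta) = beta (1-beta)^(l-1)
    (the exact interval law for randomly placed symbols on an integer
    lattice, whose continuum limit is the exponential used by the closed
    form) over the gamma intensity truncated to beta in (0, 1).  Evaluated
    by Gauss-Legendre quadrature; returned masses are normalized to sum
    to one over 1..l_max plus the analytic tail beyond.
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    beta = 0.5 * (nodes + 1.0)  # map to (0, 1)
    w = 0.5 * weights
    dens = gamma_intensity_pdf(model, beta)
    mass = float(np.sum(w * dens))
    dens = dens / mass
    ls = np.arange(1, l_max + 1)
    # pmf[l-1] = sum_j w_j f(beta_j) beta_j (1-beta_j)^(l-1)
    log1m = np.log1p(-beta)
    pmf = (w * dens * beta)[None, :] * np.exp(np.outer(ls - 1, log1m))
    return pmf.sum(axis=1)


def marginal_interval_cdf_discrete(model: GammaSuperstatModel, l_max: int) -> np.ndarray:
    """CDF at integers 1..l_max of the discrete marginal law."""
    return np.cumsum(marginal_interval_pmf(model, l_max))


def q_exponential_pdf(
    q: float, mean_n: float, l, segment_length: int = DEFAULT_SEGMENT_LENGTH
) -> np.ndarray:
    """Normalized q-exponential interval density.

    P(l) = (2-q)/s * (1 + (q-1) l / s)^(-1/(q-1)) with the per-bp scale
    s = (2-q) * L / <n>, which pins the density at l = 0 to the mean rate
    <n>/L.  Defined for 1 < q < 2; the q -> 1 limit is the exponential
    with that rate, and at q = 1 + 1/(alpha+1) the density coincides with
    the gamma-mixture closed form of the same mean.
    """
    if not 1.0 < q < 2.0:
        raise ValueError("q must lie in (1, 2)")
    l = np.asarray(l, dtype=np.float64)
    s = (2.0 - q) * segment_length / mean_n
    return (2.0 - q) / s * np.power(1.0 + (q - 1.0) * l / s, -1.0 / (q - 1.0))


def alpha_from_q(q: float) -> float:
    """Gamma shape corresponding asymptotically to entropic index q.

    The q-exponential tail exponent 1/(q-1) matches the mixture tail
    l^-(alpha+1) when alpha ~ 1/(q-1) (large-alpha asymptotics; the exact
    exponent identity is alpha + 1 = 1/(q-1)).
    """
    if q <= 1.0:
        raise ValueError("q must exceed 1")
    return 1.0 / (q - 1.0)


def q_from_rho(rho: float) -> float:
    """Entropic index from the coefficient of variation: q = 1 + rho^2."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    return 1.0 + rho**2


def sample_marginal(
    model: GammaSuperstatModel, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Monte-Carlo draws from the mixture: beta ~ Gamma, then l ~ Exp(beta).

    Independent brute-force sampler used as the distributional oracle for
    the closed form.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = model.mean_beta / model.alpha
    beta = rng.gamma(model.alpha, scale, size=n)
    return rng.exponential(1.0 / beta)
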