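"""Closed-form SFS theory under geographically concentrated sampling.

A deleterious allele at mutation–selection balance spreads over a
characteristic length ``ell_c = sigma / sqrt(s)`` before going extinct.
When a sample of size ``n`` is drawn with a Gaussian spatial kernel of
breadth ``w``, the kernel-weighted population frequency at a site follows a
Gamma distribution with shape ``theta_E`` (effective mutation supply) and
rate ``gamma_E`` (effective selection intensity):

    theta_E = mu * rho * ell_c**2 * lam,
    gamma_E = s  * rho * ell_c**2 * lam,

where the dimensionless sampling-effect scalar ``lam`` depends only on the
ratio ``w / ell_c``:

    lam = 4 * pi / (exp(x) * E1(x)),    x = (w / ell_c)**2,

with ``E1`` the exponential integral.  ``lam`` interpolates between
``-2*pi / ln(w/ell_c)`` for narrow sampling and ``4*pi*(w/ell_c)**2`` for
broad sampling; ``rho * ell_c**2 * lam`` acts as the population size
effectively being sampled and is capped at the census size ``N = rho*L**2``,
at which point the effective parameters equal the uniform-sampling values
``N*mu`` and ``N*s``.

Mixing a Poisson sampling model over the Gamma frequency gives the
finite-sample SFS: the derived-allele count ``K`` at a site is Negative
Binomial with size ``theta_E`` and success probability
``gamma_E / (gamma_E + n)``.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.special as sc
from scipy.stats import nbinom

from .params import EffectiveParams, ExpectedSFS, ModelParams, PanmicticParams, SamplingKernel

__all__ = [
    "characteristic_length",
    "scaled_exp_e1",
    "sampling_effect_scalar",
    "effective_params",
    "expected_sfs",
    "small_theta_sfs",
    "panmictic_density",
    "summary_expectations",
    "sfs_ratio_to_uniform",
]

_FOUR_PI = 4.0 * math.pi

# switch point between exp(x)*E1(x) and its asymptotic series; exp(50) is
# nowhere near overflow and 18 asymptotic terms give ~1e-15 relative error
_ASYMPTOTIC_CUT = 50.0
_ASYMPTOTIC_TERMS = 18


def characteristic_length(sigma: float, s: float) -> float:
    """Spatial scale ``sqrt(sigma**2 / s)`` of an allele's spread.

    Lineages diffuse with coefficient ``sigma**2`` and persist for about
    ``1/s`` generations, so carriers of one mutation cluster on this scale.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if not (0 < s <= 1):
        raise ValueError(f"s must lie in (0, 1], got {s}")
    return sigma / math.sqrt(s)


def scaled_exp_e1(x):
    """Numerically stable ``exp(x) * E1(x)`` for ``x > 0``.

    ``E1`` underflows and ``exp`` overflows near ``x ~ 700``; the scaled
    product is well behaved (it decays like ``1/x``), so it is evaluated as a
    single quantity: directly below ``x = 50`` and by the asymptotic series
    ``(1/x) * sum_k (-1)**k k! / x**k`` above.  Accepts scalars or arrays.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError("scaled_exp_e1 requires finite x > 0")
    out = np.empty_like(arr)
    small = arr < _ASYMPTOTIC_CUT
    if np.any(small):
        xs = arr[small]
        out[small] = np.exp(xs) * sc.exp1(xs)
    if np.any(~small):
        xl = arr[~small]
        term = np.ones_like(xl)
        acc = np.ones_like(xl)
        for k in range(1, _ASYMPTOTIC_TERMS):
            term *= -k / xl
            acc += term
        out[~small] = acc / xl
    return out.item() if np.isscalar(x) or arr.ndim == 0 else out


def sampling_effect_scalar(w: float, ell_c: float):
    """Sampling-effect scalar ``lam = 4*pi / (exp(x)*E1(x))``, ``x=(w/ell_c)**2``.

    Depends on its arguments only through ``w / ell_c`` and increases
    strictly with that ratio, from ``-2*pi/ln(w/ell_c)`` (narrow sampling)
    to ``4*pi*(w/ell_c)**2`` (broad sampling).
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("w must be positive")
    if not ell_c > 0:
        raise ValueError("ell_c must be positive")
    ratio = w / ell_c
    return _FOUR_PI / scaled_exp_e1(ratio**2)


def effective_params(params: ModelParams, kernel: SamplingKernel) -> EffectiveParams:
    """Effective mutation supply and selection intensity for a sampling kernel.

    For a Gaussian kernel the effectively sampled population is
    ``rho * ell_c**2 * lam``, capped at the census size ``N`` (the
    infinite-plane theory otherwise grows without bound as ``w`` exceeds
    ``L``); a uniform kernel samples the whole population, giving
    ``theta_E = N*mu`` and ``gamma_E = N*s`` exactly.  In every case
    ``gamma_E / theta_E = s / mu``.
    """
    ell_c = characteristic_length(params.sigma, params.s)
    if kernel.kind == "uniform":
        n_eff = params.N
    else:
        lam = sampling_effect_scalar(kernel.w, ell_c)
        n_eff = min(params.rho * ell_c**2 * lam, params.N)
    return EffectiveParams(
        ell_c=ell_c,
        lam=n_eff / (params.rho * ell_c**2),
        theta_E=params.mu * n_eff,
        gamma_E=params.s * n_eff,
    )


def _nbinom_logpmf(k, theta_E: float, gamma_E: float, n: int):
    """Log pmf of the sample count ``K`` at counts ``k`` (log space, any size)."""
    # NegBin(size=theta_E, p=gamma_E/(gamma_E+n)); log(p) and log(1-p) formed
    # stably via log1p so gamma_E up to ~1e12 and n up to ~1e7 do not overflow
    k = np.asarray(k, dtype=float)
    log_p = -np.log1p(n / gamma_E)
    log_q = -np.log1p(gamma_E / n)
    return (
        sc.gammaln(k + theta_E)
        - sc.gammaln(theta_E)
        - sc.gammaln(k + 1.0)
        + theta_E * log_p
        + k * log_q
    )


def expected_sfs(eff: EffectiveParams, n: int, k_max: int) -> ExpectedSFS:
    """Expected finite-sample SFS: Negative-Binomial probabilities ``xi_k``.

    ``xi_k`` is the probability a site shows derived-allele count ``k`` among
    ``n`` sampled chromosomes, for ``k = 0 .. k_max``; the mass beyond
    ``k_max`` is reported as ``tail_mass`` rather than renormalized away.
    """
    if n < 1 or k_max < 1:
        raise ValueError("require n >= 1 and k_max >= 1")
    ks = np.arange(k_max + 1)
    xi = np.exp(_nbinom_logpmf(ks, eff.theta_E, eff.gamma_E, n))
    return ExpectedSFS(n=int(n), k_max=int(k_max), xi=xi, tail_mass=float(1.0 - xi.sum()))


def small_theta_sfs(eff: EffectiveParams, n: int, k) -> float | np.ndarray:
    """Small-``theta_E`` SFS approximation ``(theta_E/k) * (n/(gamma_E+n))**k``.

    First-order (in ``theta_E``) expansion of the Negative-Binomial pmf for
    segregating counts ``k >= 1``; also the exact expected density of
    distinct mutation origins at count ``k`` under an infinite-sites reading.
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 1):
        raise ValueError("small-theta approximation applies to segregating counts k >= 1")
    log_q = -np.log1p(eff.gamma_E / n)
    out = eff.theta_E / k_arr * np.exp(k_arr * log_q)
    return out.item() if np.isscalar(k) else out


def panmictic_density(pan: PanmicticParams, x, log: bool = False):
    """Unnormalized well-mixed frequency density ``exp(-gamma*x) * [x(1-x)]**(theta-1)``.

    The classic two-parameter density for a negatively selected allele's
    population frequency; dropping its ``x -> 1`` tail yields the Gamma
    approximation used throughout this package.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr <= 0) or np.any(x_arr >= 1):
        raise ValueError("frequency x must lie strictly inside (0, 1)")
    log_g = -pan.gamma * x_arr + (pan.theta - 1.0) * np.log(x_arr * (1.0 - x_arr))
    out = log_g if log else np.exp(log_g)
    return out.item() if np.isscalar(x) else out


def summary_expectations(eff: EffectiveParams, params: ModelParams, n: int) -> dict:
    """Expected sample summary statistics implied by the Negative-Binomial SFS.

    Returns a record with the expected allele frequency over all sites
    (``mu/s``, independent of the sampling kernel), the probability a site is
    variant, singleton proportions in both conventions (per site and among
    variant sites), the mean frequency at variant sites, and the expected
    per-site heterozygosity ``2*E[K]/n - 2*E[K^2]/n**2``.
    """
    theta, gamma = eff.theta_E, eff.gamma_E
    xi = np.exp(_nbinom_logpmf(np.arange(2), theta, gamma, n))
    xi0, xi1 = float(xi[0]), float(xi[1])
    prop_variant = 1.0 - xi0
    mean_k = n * theta / gamma
    var_k = theta * (n / gamma) * ((gamma + n) / gamma)
    mean_k2 = var_k + mean_k**2
    mean_freq_all = params.mu / params.s
    return {
        "mean_freq_all": mean_freq_all,
        "prop_variant": prop_variant,
        "prop_singleton_per_site": xi1,
        "prop_singleton_among_variant": xi1 / prop_variant if prop_variant > 0 else float("nan"),
        "mean_freq_variant": mean_freq_all / prop_variant if prop_variant > 0 else float("nan"),
        "expected_het_all": 2.0 * mean_k / n - 2.0 * mean_k2 / n**2,
    }


def sfs_ratio_to_uniform(
    params: ModelParams,
    w: float | None,
    n: int,
    k_max: int,
    center: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, int | None]:
    """Ratio ``xi_k(w) / xi_k(uniform)`` for ``k = 1..k_max`` and its 1-crossing.

    Narrow sampling depresses the low-count classes (fewer distinct variants
    discovered) and inflates the high-count classes (each discovered variant
    at higher local frequency); the returned index is the smallest ``k`` at
    which the ratio first reaches 1, or ``None`` when the spectra coincide or
    no crossing occurs within range.  Computed in log space so that deep
    Negative-Binomial tails do not underflow.
    """
    kernel = SamplingKernel.uniform() if w is None else SamplingKernel.gaussian(w, center)
    eff_w = effective_params(params, kernel)
    eff_u = effective_params(params, SamplingKernel.uniform())
    ks = np.arange(1, k_max + 1)
    log_ratio = _nbinom_logpmf(ks, eff_w.theta_E, eff_w.gamma_E, n) - _nbinom_logpmf(
        ks, eff_u.theta_E, eff_u.gamma_E, n
    )
    ratio = np.exp(np.minimum(log_ratio, 700.0))  # deep-tail ratios saturate rather than overflow
    crossing: int | None = None
    if ratio[0] < 1.0:
        above = np.nonzero(ratio >= 1.0)[0]
        if above.size:
            crossing = int(ks[above[0]])
    return ratio, crossing
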