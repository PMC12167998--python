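"""Independent numerical oracles used across the test suite.

These deliberately avoid the code paths they check: direct quadrature for
the exponential integral and for the Gamma-Poisson mixture, and a series
evaluation for small arguments.
"""

from __future__ import annotations

import numpy as np
import scipy.special as sc
from scipy.integrate import quad

EULER_GAMMA = 0.5772156649015329


def e1_quadrature(x: float) -> float:
    """E1(x) by direct quadrature of its defining integral (moderate x only)."""
    val, _ = quad(lambda t: np.exp(-t * x) / t, 1.0, np.inf, limit=400)
    return val


def e1_small_series(x: float, terms: int = 30) -> float:
    """E1(x) = -ln(x) - gamma + sum_{k>=1} (-1)^{k+1} x^k / (k * k!)."""
    acc = -np.log(x) - EULER_GAMMA
    term = 1.0
    for k in range(1, terms + 1):
        term *= -x / k
        acc -= term / k
    return acc


def scaled_e1_asymptotic(x: float, terms: int = 10) -> float:
    """exp(x)*E1(x) ~ (1/x) * sum_k (-1)^k k!/x^k for large x."""
    acc, term = 1.0, 1.0
    for k in range(1, terms):
        term *= -k / x
        acc += term
    return acc / x


def xi_gamma_poisson(k: int, theta: float, gamma: float, n: float) -> float:
    """P(K = k) by adaptive quadrature of the Gamma-Poisson mixture.

    Integrates Pois(k; n*x) against Gamma(x; shape=theta, rate=gamma) with
    the x**(theta-1) singularity handled by an algebraic quadrature weight.
    """
    rate = gamma + n
    upper = (k + theta + 80.0) / rate
    lead = theta * np.log(gamma) - sc.gammaln(theta) - sc.gammaln(k + 1.0)

    def rest(x: float) -> float:
        if x <= 0.0:
            return float(np.exp(lead)) if k == 0 else 0.0
        return float(np.exp(lead + k * np.log(n * x) - rate * x))

    val, _ = quad(rest, 0.0, upper, weight="alg", wvar=(theta - 1.0, 0.0), limit=400)
    return val


def torus_distance(a: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    """Euclidean distance on the torus [0, L)^2."""
    d = np.abs(np.asarray(a) - np.asarray(b))
    d = np.minimum(d, L - d)
    return np.sqrt((d**2).sum(axis=-1))
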