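"""Maximum-likelihood fitting of the Negative-Binomial SFS.

Two levels of inference are supported.  ``fit_effective`` estimates the two
effective parameters ``(theta_E, gamma_E)`` from a single observed SFS by
maximizing the multinomial likelihood of the site-count histogram under the
Negative-Binomial per-site probabilities.  ``fit_structural`` estimates the
structural parameters ``(rho, sigma, s)`` jointly from spectra observed at
several sampling breadths: a single spectrum identifies only the effective
pair, but the way ``(theta_E, gamma_E)`` vary with ``w`` pins down the
underlying density, dispersal scale and selection strength (with ``mu``
held fixed, as it is confounded with ``rho`` through the product
``mu * rho``).

Sites are treated as independent, matching the model's independent-sites
assumption; the likelihood depends on the data only through the histogram.
Count classes may be masked (e.g. singletons and doubletons), in which case
class probabilities are renormalized over the unmasked set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .params import ModelParams, SamplingKernel
from .resample import ObservedSFS
from .theory import _nbinom_logpmf, effective_params

__all__ = ["FitResult", "negbin_loglik", "fit_effective", "fit_structural"]


@dataclass
class FitResult:
    """Point estimates, the maximized log-likelihood, and diagnostics."""

    estimates: dict[str, float]
    loglik: float
    mask: frozenset[int]
    converged: bool
    message: str
    n_evaluations: int
    boundary: bool = False
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood at the optimum must be finite")
        for name, v in self.estimates.items():
            if not v > 0:
                raise ValueError(f"estimate {name} must be positive, got {v}")


def _histogram(sfs: ObservedSFS) -> tuple[np.ndarray, np.ndarray]:
    """Observed (k, count) pairs including the monomorphic class."""
    ks = np.array([0] + sorted(sfs.counts), dtype=float)
    cs = np.array([sfs.num_monomorphic] + [sfs.counts[int(k)] for k in ks[1:]], dtype=float)
    return ks, cs


def negbin_loglik(
    sfs: ObservedSFS, theta_E: float, gamma_E: float, mask: frozenset[int] = frozenset()
) -> float:
    """Multinomial log-likelihood of the SFS histogram (up to a constant).

    Classes in ``mask`` are dropped and the remaining class probabilities
    renormalized, so masked fits condition on a site not falling in a masked
    class.
    """
    if not (theta_E > 0 and gamma_E > 0):
        raise ValueError("parameters must be positive")
    ks, cs = _histogram(sfs)
    keep = np.array([int(k) not in mask for k in ks])
    if not keep.any() or cs[keep].sum() == 0:
        raise ValueError("all populated count classes are masked")
    n = sfs.n_chroms
    ll = float(cs[keep] @ _nbinom_logpmf(ks[keep], theta_E, gamma_E, n))
    if mask:
        masked_mass = np.exp(
            _nbinom_logpmf(np.array(sorted(mask), dtype=float), theta_E, gamma_E, n)
        ).sum()
        if masked_mass >= 1.0:
            return -np.inf
        ll -= cs[keep].sum() * np.log1p(-masked_mass)
    return ll


def _moment_init(sfs: ObservedSFS) -> tuple[float, float]:
    ks, cs = _histogram(sfs)
    S = cs.sum()
    m = float((ks * cs).sum() / S)
    v = float((ks**2 * cs).sum() / S - m**2)
    n = sfs.n_chroms
    if m <= 0:
        return 1e-4, float(n)
    if v > m * 1.0001:
        theta0 = m**2 / (v - m)
        gamma0 = n * theta0 / m
    else:  # near-Poisson histogram: start from a weakly overdispersed guess
        theta0 = m
        gamma0 = float(n)
    return theta0, gamma0


def fit_effective(
    sfs: ObservedSFS,
    mask: frozenset[int] = frozenset(),
    x0: tuple[float, float] | None = None,
) -> FitResult:
    """MLE of ``(theta_E, gamma_E)`` from one observed SFS.

    Optimizes in log-parameter space (Nelder-Mead with fixed settings) from
    a moment-matching start; deterministic given the data and settings.  A
    histogram concentrated entirely at k = 0 pushes ``theta_E`` to the zero
    boundary and is reported with ``boundary=True``.
    """
    mask = frozenset(int(k) for k in mask)
    ks, cs = _histogram(sfs)
    if (cs[[int(k) not in mask for k in ks]] > 0).sum() < 3:
        # fewer than three populated classes leave at most one free
        # probability: the two parameters sit on a likelihood ridge or
        # boundary, so report moment-based values instead of optimizing
        theta0, gamma0 = _moment_init(sfs)
        return FitResult(
            estimates={"theta_E": max(theta0, 1e-12), "gamma_E": gamma0},
            loglik=negbin_loglik(sfs, max(theta0, 1e-12), gamma0, mask),
            mask=mask,
            converged=False,
            message="degenerate histogram: parameters not jointly identifiable",
            n_evaluations=0,
            boundary=True,
        )

    if x0 is None:
        x0 = _moment_init(sfs)

    def nll(logp: np.ndarray) -> float:
        return -negbin_loglik(sfs, float(np.exp(logp[0])), float(np.exp(logp[1])), mask)

    settings = {"method": "Nelder-Mead", "xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000}
    res = minimize(
        nll,
        np.log(np.asarray(x0, dtype=float)),
        method="Nelder-Mead",
        options={k: v for k, v in settings.items() if k != "method"},
    )
    theta_hat, gamma_hat = np.exp(res.x)
    if not res.success:
        raise RuntimeError(f"effective-parameter fit did not converge: {res.message}")
    return FitResult(
        estimates={"theta_E": float(theta_hat), "gamma_E": float(gamma_hat)},
        loglik=-float(res.fun),
        mask=mask,
        converged=bool(res.success),
        message=str(res.message),
        n_evaluations=int(res.nfev),
        settings=settings,
    )


def fit_structural(
    spectra: list[tuple[float | None, ObservedSFS]],
    mu: float,
    L: float,
    mask: frozenset[int] = frozenset(),
    x0: tuple[float, float, float] | None = None,
) -> FitResult:
    """Joint MLE of ``(rho, sigma, s)`` from spectra at several breadths.

    ``spectra`` pairs each observed SFS with its sampling breadth ``w``
    (``None`` for uniform sampling).  The mutation rate ``mu`` and habitat
    side ``L`` are fixed inputs.  At least two distinct breadths are
    required: a single spectrum determines only ``(theta_E, gamma_E)`` and
    cannot separate density, dispersal and selection.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    labels = {("uniform" if w is None else float(w)) for w, _ in spectra}
    if len(labels) < 2:
        raise ValueError(
            "structural parameters are not identifiable from a single sampling breadth; "
            "provide spectra for at least two distinct w values"
        )
    mask = frozenset(int(k) for k in mask)

    def nll(logp: np.ndarray) -> float:
        rho, sigma, s = np.exp(logp)
        if s >= 1.0 or not np.all(np.isfinite([rho, sigma, s])):
            return np.inf
        params = ModelParams(sigma=float(sigma), s=float(s), mu=mu, rho=float(rho), L=L)
        total = 0.0
        for w, sfs in spectra:
            kernel = SamplingKernel.uniform() if w is None else SamplingKernel.gaussian(w)
            eff = effective_params(params, kernel)
            total -= negbin_loglik(sfs, eff.theta_E, eff.gamma_E, mask)
        return total

    if x0 is None:
        x0 = (1.0, L / 20.0, 0.01)
    settings = {"method": "Nelder-Mead", "xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000}
    res = minimize(
        nll,
        np.log(np.asarray(x0, dtype=float)),
        method="Nelder-Mead",
        options={k: v for k, v in settings.items() if k != "method"},
    )
    if not res.success or not np.isfinite(res.fun):
        raise RuntimeError(f"structural fit did not converge: {res.message}")
    rho_hat, sigma_hat, s_hat = np.exp(res.x)
    return FitResult(
        estimates={"rho": float(rho_hat), "sigma": float(sigma_hat), "s": float(s_hat)},
        loglik=-float(res.fun),
        mask=mask,
        converged=bool(res.success),
        message=str(res.message),
        n_evaluations=int(res.nfev),
        settings=settings,
    )
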