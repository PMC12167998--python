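"""Parameter containers for the spatial mutation–selection-balance model.

The population model lives on a two-dimensional torus of side ``L``:
deleterious allele copies arise by mutation (rate ``mu`` per site per
chromosome per generation), disperse by Brownian motion with diffusion
coefficient ``sigma**2``, reproduce at rate ``1 - s`` and die at rate 1.  ``rho`` is the density of chromosomes per unit area, so
the total (haploid) population size is ``N = rho * L**2``.

Sampling effort is described by a kernel: either uniform over the habitat or
a Gaussian of standard deviation ``w`` (the sampling breadth) wrapped on the
torus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "SamplingKernel",
    "EffectiveParams",
    "ExpectedSFS",
    "PanmicticParams",
]


@dataclass(frozen=True)
class ModelParams:
    """Structural parameters of the spatial population model.

    Parameters
    ----------
    sigma : float
        Dispersal parameter, in habitat length units: ``sigma**2`` is the
        diffusion coefficient, i.e. per-axis displacement variance
        ``2 * sigma**2`` per generation (the convention under which
        ``ell_c = sigma / sqrt(s)``).
    s : float
        Heterozygous selection coefficient per generation; allele copies
        branch at rate ``1 - s`` and die at rate 1, so ``0 < s <= 1``.
    mu : float
        Per-site, per-chromosome, per-generation mutation rate.
    rho : float
        Population density (chromosomes per unit area).
    L : float
        Side length of the square (toroidal) habitat.
    """

    sigma: float
    s: float
    mu: float
    rho: float
    L: float

    def __post_init__(self) -> None:
        for name in ("sigma", "mu", "rho", "L"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (0 < self.s <= 1):
            raise ValueError(f"s must lie in (0, 1], got {self.s}")
        if not math.isfinite(self.rho * self.L**2):
            raise ValueError("total population size rho*L^2 must be finite")

    @property
    def N(self) -> float:
        """Total (haploid) population size ``rho * L**2``."""
        return self.rho * self.L**2

    @property
    def ell_c(self) -> float:
        """Characteristic length ``sqrt(sigma^2 / s)`` of an allele's spread."""
        return self.sigma / math.sqrt(self.s)


@dataclass(frozen=True)
class SamplingKernel:
    """Spatial sampling-effort kernel on the torus.

    ``kind`` is ``"gaussian"`` (wrapped Gaussian of SD ``w`` around
    ``center``) or ``"uniform"``.  The kernel is a probability density over
    the habitat: it integrates to one.
    """

    kind: str
    w: float | None = None
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "uniform"):
            raise ValueError(f"kernel kind must be 'gaussian' or 'uniform', got {self.kind!r}")
        if self.kind == "gaussian":
            if self.w is None or not self.w > 0:
                raise ValueError("gaussian kernel requires w > 0")

    @classmethod
    def gaussian(cls, w: float, center: tuple[float, float] = (0.0, 0.0)) -> "SamplingKernel":
        return cls(kind="gaussian", w=w, center=center)

    @classmethod
    def uniform(cls) -> "SamplingKernel":
        return cls(kind="uniform")


@dataclass(frozen=True)
class EffectiveParams:
    """Effective parameters of the Gamma / Negative-Binomial SFS.

    Attributes
    ----------
    ell_c : float
        Characteristic length of allele spread.
    lam : float
        Sampling-effect scalar; ``rho * ell_c**2 * lam`` is the population
        size effectively being sampled.
    theta_E : float
        Effective mutation supply (shape of the Gamma frequency density).
    gamma_E : float
        Effective selection intensity (rate of the Gamma frequency density).
    """

    ell_c: float
    lam: float
    theta_E: float
    gamma_E: float

    def __post_init__(self) -> None:
        for name in ("ell_c", "lam", "theta_E", "gamma_E"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class PanmicticParams:
    """Population-scaled parameters of the classic well-mixed frequency density.

    ``gamma = 4*Ne*s`` and ``theta = 4*Ne*mu`` in the usual notation.
    """

    gamma: float
    theta: float

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not self.theta > 0:
            raise ValueError("theta must be positive")


@dataclass
class ExpectedSFS:
    """Expected per-site sample SFS, truncated at ``k_max``.

    ``xi[k]`` is the probability that a site shows derived-allele count ``k``
    in a sample of ``n`` chromosomes, for ``k = 0 .. k_max``; ``tail_mass``
    is the probability of counts above ``k_max``.
    """

    n: int
    k_max: int
    xi: np.ndarray = field(repr=False)
    tail_mass: float

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        if self.xi.shape != (self.k_max + 1,):
            raise ValueError("xi must have length k_max + 1")
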