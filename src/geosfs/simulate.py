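"""Continuous-time spatial branching-process simulator on a torus.

Allele copies ("carriers") arise by mutation as a Poisson influx of rate
``rho * mu * L**2`` per site, branch at rate ``1 - s``, die at rate 1, and
diffuse with diffusion coefficient ``sigma**2`` — per-axis displacement
variance ``2 * sigma**2 * dt`` over a time ``dt``, the convention under
which the characteristic length is ``ell_c = sigma / sqrt(s)``.  Events are
scheduled with an exact Gillespie algorithm (exponential waiting times,
categorical event choice); positions are updated lazily, with one Brownian
increment covering the elapsed time, only when a carrier reproduces or at
snapshot times — rates never depend on position, so this is exact.

Mutation events draw a site label uniformly from ``n_sites`` recurrent
sites, so independent mutation origins at the same site superpose in its
frequency, matching the finite-``mu`` theory at any mutation supply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .kernels import kernel_density, wrapped_gaussian_density  # noqa: F401  (re-export)
from .params import ModelParams, SamplingKernel
from .resample import ObservedSFS

__all__ = [
    "SimConfig",
    "CarrierPopulation",
    "run_branching",
    "wrapped_gaussian_density",
    "weighted_frequency",
    "sample_counts",
    "estimate_effective_params",
    "simulated_sfs",
]

_BLOCK = 1 << 16


@dataclass(frozen=True)
class SimConfig:
    """Run configuration: model, number of sites, schedule, and seed.

    Snapshots are recorded at ``burn_in, burn_in + record_every, ...`` up to
    ``horizon`` (inclusive).  The default burn-in of ``10 / s`` generations
    spans several allele lifetimes; the default thinning of ``1 / s``
    generations keeps successive snapshots weakly correlated.
    """

    params: ModelParams
    n_sites: int
    burn_in: float | None = None
    record_every: float | None = None
    horizon: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be non-negative")
        s = self.params.s
        if self.burn_in is None:
            object.__setattr__(self, "burn_in", 10.0 / s)
        if self.record_every is None:
            object.__setattr__(self, "record_every", 1.0 / s)
        if self.horizon is None:
            object.__setattr__(self, "horizon", self.burn_in)
        if self.burn_in < 0 or self.horizon < self.burn_in:
            raise ValueError("require 0 <= burn_in <= horizon")


@dataclass
class CarrierPopulation:
    """Snapshot of all living carriers: site labels and torus positions."""

    site_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    time: float
    event_count: int

    @property
    def size(self) -> int:
        return self.site_id.size


def run_branching(
    config: SimConfig,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> Iterator[CarrierPopulation]:
    """Exact Gillespie simulation, yielding a snapshot at each record time.

    ``init`` optionally seeds the population with ``(site_id, x, y)`` arrays
    at time zero (the default start is the empty state, which burn-in brings
    to stationarity).  With zero mutation influx the empty state is
    absorbing: remaining snapshots are emitted empty and the run ends.
    Fixed seeds give bit-reproducible output.
    """
    p = config.params
    L, s, sigma = p.L, p.s, p.sigma
    lam_imm = p.rho * p.mu * L**2 * config.n_sites
    per_carrier = 2.0 - s  # birth (1 - s) + death (1)

    rng = np.random.default_rng(config.seed)
    # batched draws; scalar consumption from python lists is ~5x faster than
    # per-event Generator calls
    u_blk = rng.random(_BLOCK).tolist()
    z_blk = rng.standard_normal(_BLOCK).tolist()
    iu = iz = 0

    site: list[int] = []
    xs: list[float] = []
    ys: list[float] = []
    tl: list[float] = []
    if init is not None:
        s0, x0, y0 = init
        site = [int(v) for v in s0]
        xs = [float(v) % L for v in x0]
        ys = [float(v) % L for v in y0]
        tl = [0.0] * len(site)

    snap_times = []
    t_snap = config.burn_in
    while t_snap <= config.horizon + 1e-9:
        snap_times.append(t_snap)
        t_snap += config.record_every
    n_snaps = len(snap_times)

    t = 0.0
    events = 0
    i_snap = 0
    log = math.log

    def take_snapshot(at: float) -> CarrierPopulation:
        m = len(site)
        if m:
            x_arr = np.array(xs)
            y_arr = np.array(ys)
            dt = at - np.array(tl)
            step = sigma * np.sqrt(2.0 * dt)
            x_arr = (x_arr + rng.standard_normal(m) * step) % L
            y_arr = (y_arr + rng.standard_normal(m) * step) % L
            xs[:] = x_arr.tolist()
            ys[:] = y_arr.tolist()
            tl[:] = [at] * m
            return CarrierPopulation(np.array(site, dtype=np.int64), x_arr, y_arr, at, events)
        return CarrierPopulation(
            np.empty(0, dtype=np.int64), np.empty(0), np.empty(0), at, events
        )

    while i_snap < n_snaps:
        m = len(site)
        total = lam_imm + per_carrier * m
        if total == 0.0:
            # absorbing empty state with no mutation influx
            for at in snap_times[i_snap:]:
                yield take_snapshot(at)
            return

        if iu + 8 > _BLOCK:
            u_blk = rng.random(_BLOCK).tolist()
            iu = 0
        if iz + 4 > _BLOCK:
            z_blk = rng.standard_normal(_BLOCK).tolist()
            iz = 0

        dt = -log(1.0 - u_blk[iu]) / total
        iu += 1
        if t + dt >= snap_times[i_snap]:
            # memoryless clocks: emit the snapshot and redraw from there
            t = snap_times[i_snap]
            yield take_snapshot(t)
            i_snap += 1
            continue
        t += dt
        events += 1

        v = u_blk[iu] * total
        iu += 1
        if v < lam_imm:
            site.append(int(u_blk[iu] * config.n_sites))
            xs.append(u_blk[iu + 1] * L)
            ys.append(u_blk[iu + 2] * L)
            tl.append(t)
            iu += 3
        else:
            r = v - lam_imm
            idx = int(r / per_carrier)
            if idx >= m:  # guard against float roundoff at the boundary
                idx = m - 1
            if r - idx * per_carrier < 1.0:
                # death: swap-remove
                last = m - 1
                site[idx] = site[last]
                xs[idx] = xs[last]
                ys[idx] = ys[last]
                tl[idx] = tl[last]
                site.pop()
                xs.pop()
                ys.pop()
                tl.pop()
            else:
                # birth: diffuse the parent to now, child starts alongside
                step = sigma * math.sqrt(2.0 * (t - tl[idx]))
                nx = (xs[idx] + z_blk[iz] * step) % L
                ny = (ys[idx] + z_blk[iz + 1] * step) % L
                iz += 2
                xs[idx] = nx
                ys[idx] = ny
                tl[idx] = t
                site.append(site[idx])
                xs.append(nx)
                ys.append(ny)
                tl.append(t)


def weighted_frequency(
    pop: CarrierPopulation, kernel: SamplingKernel, rho: float, L: float, n_sites: int
) -> np.ndarray:
    """Kernel-weighted population frequency per site.

    ``X_site = sum_i density(z_i) / rho`` over that site's carriers; sites
    with no living carriers get 0, and under a uniform kernel ``X = m / N``
    for ``m`` carriers.
    """
    X = np.zeros(n_sites)
    if pop.size:
        dens = kernel_density(np.column_stack([pop.x, pop.y]), kernel, L)
        np.add.at(X, pop.site_id, np.asarray(dens) / rho)
    return X


def sample_counts(X, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sampled allele counts ``K ~ Poisson(n * X)``, independently per site."""
    if n < 1:
        raise ValueError("sample size n must be >= 1")
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("frequencies must be non-negative")
    return rng.poisson(n * X)


def estimate_effective_params(X) -> tuple[float, float]:
    """Moment-matched Gamma parameters ``(theta_hat, gamma_hat)`` from frequencies.

    Matching the first two moments of the per-site frequency distribution to
    a Gamma(shape, rate): ``gamma_hat = mean / var``, ``theta_hat =
    mean**2 / var``.
    """
    X = np.asarray(X, dtype=float).ravel()
    if X.size < 2:
        raise ValueError("need at least two frequency samples")
    mean = X.mean()
    var = X.var(ddof=1)
    if var <= 0:
        raise ValueError("zero variance in frequencies; moment matching is degenerate")
    return float(mean**2 / var), float(mean / var)


def simulated_sfs(
    config: SimConfig,
    kernel: SamplingKernel,
    n: int,
    reps: int = 1,
    collect_frequencies: bool = False,
):
    """Observed SFS aggregated over snapshots and replicate runs.

    Each replicate reruns the branching process with seed ``config.seed +
    rep``; per snapshot, kernel-weighted frequencies are thinned to counts
    ``K ~ Poisson(n * X)`` and histogrammed.  ``total_sites`` counts every
    (site, snapshot) pair, so sites currently extinct contribute to the
    monomorphic class.  With ``collect_frequencies`` the per-snapshot
    frequency matrix is returned as well (rows = snapshots).
    """
    p = config.params
    counts: dict[int, int] = {}
    total = 0
    freqs = []
    for rep in range(reps):
        cfg = SimConfig(
            params=p,
            n_sites=config.n_sites,
            burn_in=config.burn_in,
            record_every=config.record_every,
            horizon=config.horizon,
            seed=config.seed + rep,
        )
        count_rng = np.random.default_rng((config.seed + rep, 0x5F5))
        for pop in run_branching(cfg):
            X = weighted_frequency(pop, kernel, p.rho, p.L, config.n_sites)
            K = sample_counts(X, n, count_rng)
            for k, c in zip(*np.unique(K[K > 0], return_counts=True)):
                counts[int(k)] = counts.get(int(k), 0) + int(c)
            total += config.n_sites
            if collect_frequencies:
                freqs.append(X)
    sfs = ObservedSFS(n_chroms=n, counts=counts, total_sites=total)
    if collect_frequencies:
        return sfs, np.array(freqs)
    return sfs
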