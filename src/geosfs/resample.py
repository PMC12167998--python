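"""Geographic sampling-importance-resampling (SIR) and observed-SFS summaries.

Given a cohort of individuals with known coordinates, the SIR step reweights
individuals so that a subsample of size ``n`` follows a target spatial
distribution (a Gaussian of chosen breadth ``w``, or uniform), emulating a
study that recruits around a center with a given geographic reach.  The rest
of the module computes the observed site frequency spectrum of a subsample
and the downstream summary statistics (variant sites per kb, singletons per
kb, heterozygosity over all or variant sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import kernel_density
from .params import SamplingKernel

__all__ = [
    "ObservedSFS",
    "bin_counts",
    "assign_bins",
    "sir_weights",
    "draw_subsample",
    "compute_sfs",
    "fold_sfs",
    "summary_statistics",
    "relative_change",
    "write_sfs_csv",
    "read_sfs_csv",
]


@dataclass
class ObservedSFS:
    """Site counts by sample allele count.

    ``counts[k]`` is the number of sites observed at derived (or minor, if
    ``folded``) allele count ``k >= 1`` among ``n_chroms`` sampled
    chromosomes; monomorphic sites are included in ``total_sites`` only.
    """

    n_chroms: int
    counts: dict[int, int] = field(repr=False)
    total_sites: int
    folded: bool = False

    def __post_init__(self) -> None:
        self.counts = {int(k): int(v) for k, v in self.counts.items() if v}
        k_cap = self.n_chroms // 2 if self.folded else self.n_chroms
        for k in self.counts:
            if not 1 <= k <= k_cap:
                raise ValueError(f"allele count {k} outside [1, {k_cap}]")
        if self.num_variant > self.total_sites:
            raise ValueError("variant sites exceed total_sites")

    @property
    def num_variant(self) -> int:
        return sum(self.counts.values())

    @property
    def num_monomorphic(self) -> int:
        return self.total_sites - self.num_variant

    def to_array(self, k_max: int | None = None) -> np.ndarray:
        """Counts as a dense vector indexed by k (k=0 holds monomorphic sites)."""
        k_hi = max(self.counts, default=0) if k_max is None else k_max
        arr = np.zeros(k_hi + 1, dtype=float)
        arr[0] = self.num_monomorphic
        for k, v in self.counts.items():
            if k <= k_hi:
                arr[k] = v
        return arr


def assign_bins(coords, bin_width: float, L: float) -> tuple[np.ndarray, int]:
    """Flat bin index for each coordinate pair on a square grid over [0, L)^2."""
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    n_bins = int(np.ceil(L / bin_width))
    ij = np.clip((coords % L / bin_width).astype(int), 0, n_bins - 1)
    return ij[:, 0] * n_bins + ij[:, 1], n_bins


def bin_counts(coords, bin_width: float, L: float) -> np.ndarray:
    """2-D occupancy histogram of coordinates; empty bins kept as zeros."""
    flat, n_bins = assign_bins(coords, bin_width, L)
    return np.bincount(flat, minlength=n_bins * n_bins).reshape(n_bins, n_bins)


def sir_weights(coords, target: SamplingKernel, bin_width: float, L: float) -> np.ndarray:
    """Per-individual importance weights matching a target spatial distribution.

    Individuals are binned on a grid of resolution ``bin_width``; each
    individual in a bin receives weight proportional to (target mass of the
    bin) / (bin occupancy), so the weighted empirical bin distribution equals
    the target renormalized over occupied bins.  Weights sum to one.
    """
    coords = np.asarray(coords, dtype=float)
    flat, n_bins = assign_bins(coords, bin_width, L)
    occupancy = np.bincount(flat, minlength=n_bins * n_bins).astype(float)

    centers_1d = (np.arange(n_bins) + 0.5) * bin_width
    gx, gy = np.meshgrid(centers_1d, centers_1d, indexing="ij")
    grid_pts = np.column_stack([gx.ravel(), gy.ravel()])
    mass = np.asarray(kernel_density(grid_pts, target, L), dtype=float)
    mass /= mass.sum()

    occupied = occupancy > 0
    occ_mass = mass[occupied].sum()
    if occ_mass <= 0:
        raise ValueError("target places no mass on occupied bins; cannot resample")
    mass = np.where(occupied, mass / occ_mass, 0.0)

    w = mass[flat] / occupancy[flat]
    return w / w.sum()


def _inclusion_probs(weights: np.ndarray, n: int) -> np.ndarray:
    """Inclusion probabilities proportional to weights, capped at one.

    Probabilities above one are clipped and the surplus redistributed over
    the uncapped individuals (iterated until feasible); the result sums to
    ``n`` exactly.
    """
    w = weights / weights.sum()
    capped = np.zeros(w.size, dtype=bool)
    pi = n * w
    for _ in range(w.size):
        over = pi > 1.0 + 1e-12
        if not over.any():
            break
        capped |= over
        remaining = n - int(capped.sum())
        free = ~capped
        if remaining <= 0 or not free.any():
            return capped.astype(float)
        pi = np.where(capped, 1.0, w * (remaining / w[free].sum()))
    return np.minimum(pi, 1.0)


def draw_subsample(
    weights, n: int, seed: int, replicates: int = 1
) -> list[np.ndarray]:
    """Weighted subsamples (without replacement) of ``n`` individual indices.

    Uses systematic probability-proportional-to-size sampling in randomized
    order (Madow's method): each individual enters a subsample at most once,
    with inclusion probability exactly proportional to its weight (capped at
    one), which keeps the resampled spatial distribution on target even at
    large sampling fractions, where sequential weighted draws distort it.
    Returns ``replicates`` index arrays; the same seed reproduces the same
    replicate sets.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    n_pos = int((weights > 0).sum())
    if n > n_pos:
        raise ValueError(f"cannot draw {n} individuals from {n_pos} with positive weight")
    pi = _inclusion_probs(weights, n)
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(replicates):
        perm = rng.permutation(weights.size)
        edges = np.cumsum(pi[perm])
        points = rng.random() + np.arange(n)
        sel = np.minimum(np.searchsorted(edges, points, side="right"), weights.size - 1)
        draws.append(np.sort(perm[sel]))
    return draws


def compute_sfs(dosages, ploidy: int, total_sites: int | None = None) -> ObservedSFS:
    """Observed SFS of a genotype-dosage matrix (individuals x sites).

    Dosages count derived alleles per individual (0/1 haploid, 0/1/2
    diploid); per-site allele counts are taken over ``ploidy * n_individuals``
    chromosomes.  Monomorphic sites enter ``total_sites`` only.
    """
    import scipy.sparse as sp

    if sp.issparse(dosages):
        if dosages.nnz and (dosages.min() < 0 or dosages.max() > ploidy):
            raise ValueError(f"dosages outside [0, {ploidy}]")
        n_ind, n_sites = dosages.shape
        k = np.asarray(dosages.sum(axis=0)).ravel().astype(int)
    else:
        dosages = np.asarray(dosages)
        if dosages.size and (dosages.min() < 0 or dosages.max() > ploidy):
            raise ValueError(f"dosages outside [0, {ploidy}]")
        n_ind, n_sites = dosages.shape
        k = dosages.sum(axis=0).astype(int)
    if total_sites is None:
        total_sites = n_sites
    seg = k[k > 0]
    ks, cs = np.unique(seg, return_counts=True)
    return ObservedSFS(
        n_chroms=ploidy * n_ind,
        counts=dict(zip(ks.tolist(), cs.tolist())),
        total_sites=int(total_sites),
    )


def fold_sfs(sfs: ObservedSFS) -> ObservedSFS:
    """Fold to minor-allele counts: merge k and n_chroms - k into min(k, n-k)."""
    if sfs.folded:
        raise ValueError("SFS is already folded")
    n = sfs.n_chroms
    folded: dict[int, int] = {}
    for k, v in sfs.counts.items():
        kf = min(k, n - k)
        if kf == 0:
            # k == n_chroms: fixed in the sample, folds onto the monomorphic class
            continue
        folded[kf] = folded.get(kf, 0) + v
    return ObservedSFS(n_chroms=n, counts=folded, total_sites=sfs.total_sites, folded=True)


def summary_statistics(sfs: ObservedSFS, kb: float) -> dict:
    """Heterozygosity and per-kb variant/singleton rates of an observed SFS.

    Per-site heterozygosity is the plug-in ``2*p*(1-p)`` at the sample
    frequency ``p = k / n_chroms`` (no small-sample correction; invariant
    under folding since ``2p(1-p)`` is symmetric in ``p -> 1-p``).
    """
    if not kb > 0:
        raise ValueError("kb must be positive")
    if sfs.total_sites == 0:
        raise ValueError("SFS contains no sites")
    ks = np.array(list(sfs.counts), dtype=float)
    cs = np.array([sfs.counts[int(k)] for k in ks], dtype=float)
    p = ks / sfs.n_chroms
    het = 2.0 * p * (1.0 - p)
    het_sum = float((het * cs).sum())
    n_var = sfs.num_variant
    return {
        "het_all": het_sum / sfs.total_sites,
        "het_variant": het_sum / n_var if n_var else 0.0,
        "variant_per_kb": n_var / kb,
        "singletons_per_kb": sfs.counts.get(1, 0) / kb,
    }


def relative_change(narrow_value: float, broad_value: float) -> float:
    """Signed percent change ``100 * (broad - narrow) / narrow``."""
    if narrow_value == 0:
        raise ValueError("relative change undefined for a zero baseline")
    return 100.0 * (broad_value - narrow_value) / narrow_value


def write_sfs_csv(sfs: ObservedSFS, path, meta: dict | None = None) -> None:
    """Write an observed SFS as CSV (columns k, count) with '#' metadata header."""
    with open(path, "w") as fh:
        header = {
            "n_chroms": sfs.n_chroms,
            "total_sites": sfs.total_sites,
            "folded": sfs.folded,
            **(meta or {}),
        }
        for key, val in header.items():
            fh.write(f"# {key}={val}\n")
        fh.write("k,count\n")
        for k in sorted(sfs.counts):
            fh.write(f"{k},{sfs.counts[k]}\n")


def read_sfs_csv(path) -> ObservedSFS:
    """Read an SFS written by :func:`write_sfs_csv`."""
    meta: dict[str, str] = {}
    counts: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key] = val
            elif line != "k,count":
                try:
                    k_str, c_str = line.split(",")
                    counts[int(k_str)] = int(c_str)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed SFS row {line!r}") from exc
    try:
        return ObservedSFS(
            n_chroms=int(meta["n_chroms"]),
            counts=counts,
            total_sites=int(meta["total_sites"]),
            folded=meta.get("folded", "False") == "True",
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing required SFS metadata {exc}") from exc
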