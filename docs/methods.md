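# Methods

## Model

A population of chromosomes lives at density ρ (per unit area) on a square
torus of side L, so the census size is N = ρL². At a given genomic site,
deleterious allele copies arise by mutation as a Poisson process of rate
ρμL² per generation (μ per chromosome per site), uniformly in space. Each
copy behaves as an independent lineage of a subcritical branching process:
it produces offspring at rate 1 − s, dies at rate 1, and diffuses with
diffusion coefficient σ² — per-axis displacement variance 2σ²Δt over time
Δt. Under this convention the characteristic spatial scale of an allele's
spread before extinction is

    ℓ_c = σ / √s,

the distance a lineage diffuses during its ~1/s-generation lifetime. The
rare-allele assumption (no homozygote effects, no interaction between
lineages) makes the model exactly linear: mutant families are independent.

One parameterization note, because two diffusion conventions circulate: if
σ were instead the per-generation, per-axis displacement *standard
deviation* (variance σ²Δt), every closed form below would acquire factors
of 2 (the small-breadth scalar becomes −π/ln(w/ℓ_c), not −2π/ln(w/ℓ_c)).
We verified the convention used here against the exact stationary pair
correlation of the branching model — a Helmholtz equation in the separation
coordinate whose 2-D Green's function is the Bessel K₀ — which reproduces
the λ formula below exactly (up to a (1−s) factor and the kernel
self-overlap term, both negligible in the regimes of interest). The
simulator uses the same convention, and the agreement tests would detect a
mismatch immediately (a factor 2e^{2x}E1(2x)/e^{x}E1(x) ≈ 1.2–2 in the
frequency variance).

## Sampling and effective parameters

Sampling effort is a probability density over the habitat: a wrapped
Gaussian of breadth (SD) w around a center, or uniform. The kernel-weighted
population frequency of a site, X = Σᵢ f(zᵢ)/ρ over its carriers, is
approximately Gamma distributed with shape θ_E (effective mutation supply)
and rate γ_E (effective selection intensity):

    θ_E = μ ρ ℓ_c² λ,    γ_E = s ρ ℓ_c² λ,
    λ   = 4π / (e^x E1(x)),    x = (w/ℓ_c)²,

where E1 is the exponential integral. λ depends only on w/ℓ_c, increases
strictly with it, and interpolates between −2π/ln(w/ℓ_c) (narrow sampling:
only logarithmic dependence on breadth and selection) and 4π(w/ℓ_c)²
(broad sampling: θ_E → μρ4πw², a panmictic population of the size found in
a circle of radius 2w). The quantity ρℓ_c²λ is the population size
effectively being sampled; we cap it at the census N, at which point the
effective parameters equal the uniform-sampling values Nμ and Ns. A uniform
kernel bypasses λ entirely. In all cases γ_E/θ_E = s/μ, so the expected
sample allele frequency over all sites is μ/s regardless of sampling
breadth — the model's central invariant.

For a sample of n chromosomes, Poisson sampling over the Gamma frequency
gives a Negative-Binomial per-site SFS: K ~ NegBin(size θ_E, success
probability γ_E/(γ_E+n)). All pmfs are evaluated in log space through
log-Gamma functions (non-integer sizes; γ_E up to 10¹², n up to 10⁷ without
overflow). e^x·E1(x) is computed as a single scaled quantity — direct
product below x = 50, truncated asymptotic series above — because e^x and
E1(x) separately overflow/underflow near x ≈ 700. Expected spectra report
the truncation tail mass explicitly instead of renormalizing.

Summary-statistic expectations follow from NegBin moments. The "proportion
of singletons" is reported in both conventions (per site, ξ₁, and among
variant sites, ξ₁/(1−ξ₀)); the per-site value is the CLI default.
Heterozygosity uses plug-in 2p(1−p) with no n/(n−1) correction — negligible
at biobank sample sizes and stated in output metadata.

## Simulator

`run_branching` is an exact Gillespie scheduler over {mutation influx,
birth, death}; a single uniform draw picks both the event type and the
affected carrier. Positions are updated lazily — one Brownian increment
covering the time since the carrier's last update, applied when it
reproduces or at snapshot times — which is exact because event rates never
depend on position. Defaults: burn-in 10/s generations (several allele
lifetimes, starting from the empty state), snapshot thinning 1/s
generations. Mutation events draw their site label uniformly from n_sites
recurrent sites, so independent origins at one site superpose in its
frequency; this matches the finite-μ Negative-Binomial theory at any θ_E,
whereas fresh-label (infinite-sites) bookkeeping matches only to first
order in θ_E. Validation runs therefore inflate μ freely: the SFS depends
on μ only through θ_E and μ/s, so "many families per site" is a scale
choice, not an approximation.

Moment matching (γ̂ = mean/var, θ̂ = mean²/var of the per-site weighted
frequency) recovers the effective parameters; standard errors come from
batch means over consecutive snapshot blocks. Because a single narrow
kernel sees few independent family clusters, validation averages the
frequency samples over a 4×4 grid of kernel centers (exchangeable by
translation invariance on the torus); the χ² goodness-of-fit test uses only
well-separated centers and 4/s-generation snapshot spacing to keep counts
effectively independent. The wrapped-Gaussian kernel density truncates
periodic images below a 10⁻¹² relative contribution.

Sampling uses the Poisson thinning K ~ Poisson(nX) of the theory; the
cohort generator (below) provides the discrete-individual alternative.

## SIR resampling

Individuals are binned on a grid (default resolution w/5 of the narrowest
kernel); each individual's weight is the target's bin mass divided by the
bin occupancy, with target mass renormalized over occupied bins (with a
warning — the analogue of coastlines and empty countryside in real
cohorts). Subsamples are drawn **without replacement** by systematic
probability-proportional-to-size sampling in randomized order (Madow's
method) with inclusion probabilities min(n·wᵢ, 1) (surplus redistributed).
At small sampling fractions this is indistinguishable from sequential
weighted draws; at the large fractions used in desk-scale experiments
(10,000 of 20,000) sequential draws systematically flatten the realized
distribution, while the systematic scheme keeps inclusion probabilities
exact. Feasibility bound worth knowing: a without-replacement subsample can
only match a target whose peak density times n does not exceed the cohort's
local density; the geographic-targeting check therefore uses w = 150 on
L = 500 at n = 10,000 (n·peak ≈ 0.071 < 0.08 per km²), while narrower
kernels are exercised at smaller n.

Folding merges counts k and n−k into min(k, n−k), with the k = n/2 class
kept once; summary statistics are invariant under folding because 2p(1−p)
is symmetric. Replicate tables report means with 2·SE error bars; for
Gaussian kernels the SE is taken over kernel-center means, which captures
the spatial (between-region) variability that replicate draws from a single
center would miss.

## Maximum likelihood

The likelihood is multinomial over the site-count histogram (sites
independent, matching the model), with optional masking of count classes
(e.g. singletons+doubletons) and renormalization over the unmasked set.
`fit_effective` optimizes (log θ_E, log γ_E) by Nelder–Mead from a
moment-matching start with fixed deterministic settings; histograms with
fewer than three populated classes leave the two parameters on a
likelihood ridge and are returned as flagged boundary results with
moment-based values rather than optimized. `fit_structural` shares (ρ, σ,
s) across spectra observed at two or more breadths, mapping each breadth
through the effective-parameter formulas with μ and L fixed (μ is
confounded with ρ through μρ); a single breadth identifies only (θ_E, γ_E)
and is rejected with an explanatory error.

## Synthetic cohorts

`generate_cohort` places individuals uniformly on the torus, runs the
branching process to one stationary snapshot per variant class at
chromosome density 2·n_individuals/L², and assigns each carrier copy to the
nearest individual with spare dosage capacity (k-d tree with periodic
boundaries; overflow carriers are dropped with a logged count). This
nearest-neighbour bridge preserves the spatial frequency field at scales
well above the inter-individual spacing, which is what the resampling
analysis consumes.

Default demo scale: 20,000 diploid individuals, L = 500 km, σ = 8 km, three
2,000-site classes with s = 0.01/0.03/0.1 ("weak"/"moderate"/"strong",
ℓ_c = 80/46/25 km) and a shared inflated μ = 3.125×10⁻⁶ chosen so each
class segregates ~600–1,400 variants and the whole cohort generates in
about a minute. The exact-event simulator's cost scales as 1/s² (live
carriers × burn-in), which is why the weakest class uses s = 0.01: an
s = 0.001 class at comparable variant counts would need on the order of
10⁹ events. Because the SFS depends on μ only through θ_E and μ/s, the
inflation rescales frequencies without changing the phenomena under study;
classes share μ so that variant counts decrease with s, as they should.
The demo resamples at w ∈ {50, 100, 150} km plus uniform over an 8-center
grid, two draws per center, n = 1,000 individuals, and tabulates the four
summary statistics with 2·SE bars and the narrow-vs-uniform relative
change.

What the generator emulates: spatially clustered rare variation with
class-dependent cluster scale ℓ_c, in selection classes playing the role of
annotation categories (synonymous/missense/LoF). What it does not emulate:
real population-density maps or coastlines, relatedness and ancestry
structure, non-equilibrium demography (growth, admixture), long-range
dispersal layers, or linkage. Passing tests therefore demonstrate internal
consistency of theory, simulation and pipeline under the model's
assumptions — not that real cohorts obey them; in real data, old variants
shared across the habitat and non-equilibrium history attenuate the
predicted SFS shifts.

## Numerical choices and limitations

- Truncated spectra always report tail mass; mean-identity checks choose
  k_max from the geometric tail rate so the neglected mass is below 10⁻¹⁵.
- The uniform-limit cap min(ρℓ_c²λ, N) is a pragmatic bridge between the
  infinite-plane derivation (w ≪ L) and the uniform limit; near w ≈ L the
  theory is interpolation, not derivation.
- Moment matching requires positive sample variance and at least two
  samples; degenerate inputs raise errors rather than returning NaNs.
- Theory–simulation agreement degrades when w approaches σ (the
  measure-valued approximation meets discrete-individual reality) and for
  weak selection where alleles stop being rare; validation stays in
  w/ℓ_c ∈ [0.1, 3] with w ≥ 2.5σ.
- The kernel self-overlap term (μ/(sρ·4πw²) for a Gaussian kernel) adds a
  relative s/(x e^x E1(x)) to the frequency variance not captured by the
  Gamma theory — about 7% at w/ℓ_c = 0.25 and s = 0.01, inside Monte-Carlo
  error at validation scale but visible in principle.
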