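# Methods

## Model and assumptions

`sfsdyn` models unlinked sites under genic (additive) selection in the
Poisson random field setting: infinitely many sites, no linkage or
interference, genotype fitnesses 1, 1 − s, 1 − 2s with s ≥ 0 deleterious.
The state is the expected density f(x, t) of derived alleles at population
frequency x, advanced by the forward Kolmogorov equation

    ∂f/∂t = ∂/∂x [ S x(1−x) f ] + (1/2) ∂²/∂x² [ x(1−x) f / ρ(t) ],

S = 2N₀s, time in 2N₀-generation (coalescent) units, ρ(t) the population
size relative to the reference N₀. Selection enters in N₀ units and is
unaffected by size change; drift accelerates as 1/ρ. Mutational input is
the low-frequency boundary datum x(1−x)f → θρ(t); the high-frequency
boundary absorbs (x(1−x)f → 0) and its flux accumulates as expected
fixations. Dominance (h ≠ 1/2), migration after the population split,
linked selection, and joint two-population spectra are out of scope.

All outputs are expectations. Sampling noise only appears where it is the
point: the synthetic exome generator draws Poisson site counts and
binomial sample counts from the solved spectra.

## Numerical scheme

Writing g = x(1−x)f, the probability flux is J = −S g − g′/(2ρ). The
solver uses a conservative, vertex-centered finite-volume discretization
on a power-law grid x_i = (i/(M+1))^r (defaults M = 2000, r = 3, so
spacing is ~10⁻¹⁰ at the boundary and ~1.5×10⁻³ near x = 1), with
Scharfetter–Gummel (exponential-fitting) face fluxes

    J_face = (D/h) [ B(P) g_left − B(−P) g_right ],
    D = 1/(2ρ),  P = 2ρS h,  B(z) = z/(eᶻ − 1).

This choice has three consequences that shape the whole package:

* The closed-form equilibrium g(x) = θρ(e^{−2Sρx} − e^{−2Sρ})/(1 − e^{−2Sρ})
  is piecewise-exponential with constant flux, which Scharfetter–Gummel
  fluxes reproduce exactly; the equilibrium is therefore a fixed point of
  the discrete operator to machine precision (measured drift ~10⁻¹⁴ over
  τ = 0.2 for S between 0 and 100), and stationarity tests probe the
  dynamics rather than discretization error.
* The semidiscrete system is an M-matrix, so backward-Euler steps preserve
  positivity unconditionally.
* Mass balance is exact by construction: the change in cell-integrated
  mass equals injected minus lost minus fixed flux at every step (the
  neutral stationary state fixes θ/2 per coalescent unit and injects θ/2,
  the molecular clock).

Time stepping is Crank–Nicolson (dt = 10⁻³ coalescent units by default)
with two backward-Euler startup steps after every size discontinuity
(Rannacher smoothing), because Crank–Nicolson does not damp the stiff
boundary-layer transient that an instantaneous bottleneck excites. Within
exponential-growth epochs the step is additionally capped so ρ changes by
at most 0.1 e-foldings per step; recent human growth runs at ~500
e-foldings per coalescent unit and would otherwise be traversed in a
handful of steps. The no-mutation counterfactual (boundary datum zeroed)
collapses the 1/x boundary layer entirely and steps fully implicitly.
Negative values within −10⁻¹² of the spectrum maximum are clipped to
zero; anything larger aborts with the offending step named.

Self-convergence on the OOA history (halving dt, doubling the grid) moves
present-day heterozygosity, burden, and P₂₀ by well under 0.2%; the test
suite runs at 800 grid points, which the same check shows is converged at
that level.

## Quadrature

f diverges like θρ/x at the origin, so naive truncation of ∫φ(x)f dx at
the first grid point biases singleton-heavy statistics. All summary
integrals use trapezoid quadrature on the grid closed analytically at both
endpoints: the integrand φf = φg/(x(1−x)) tends to φ′(0)·θρ at x → 0 and
to φ(1)·g(x_M)/(1 − x_M) at x → 1. Binomial projection weights are
evaluated in log space, so sample sizes in the tens of thousands are safe.

Heterozygosity is defined as E[q_{2,1}] = ∫2x(1−x)f dx — the factor 2 is
forced by the n = 2 binomial projection; plots of the "contribution to
heterozygosity" x(1−x)f elsewhere differ by that constant. The derived
burden is per diploid genome, 2(∫x f dx + fixations); derived
homozygosity is ∫x²f dx + fixations; the identity burden =
heterozygosity + 2·homozygosity holds pointwise and is asserted
numerically. Per-megabase outputs use a configurable l (default 10⁶ bp),
μ = 1.2×10⁻⁸, and a 2/3 nonsynonymous fraction; no genome-wide coding
length is assumed.

## Demographic models

Histories are contiguous epochs (constant or exponential) in generations
before present; sizes are quoted as chromosome counts 2N. The African and
OOA presets implement the fitted human model: ancestral 2N = 14,620
doubling to 29,240 at 5,920 generations ago (the doubling is taken as
exact and its time only needs to predate the split; both are
configurable), an OOA bottleneck to 13% (2N = 3801) at 2,000 generations,
a second bottleneck to 55% of the bottlenecked size with 0.31%/generation
recovery at 920 generations, and growth at 1.95%/generation (OOA) or
1.66%/generation (African) from 205 generations ago. The second
bottleneck's base is the size prevailing at 920 generations (0.55 × 3801);
the model prints only percentages, and this reading matches the event
ordering. N₀ references the pre-split 2N = 29,240 for both populations so
they share one time and θ scale. At a boundary instant the younger
epoch's size applies. Solves start "at equilibrium" from the closed form
at the oldest epoch's relative size (ρ = 0.5 for the presets).

## Equilibrium selection rates on PN/PT

At equilibrium the expected PN/PT is constant; the package isolates the
instantaneous contribution of selection to its rate of change. For a
sample of k chromosomes,

    d/dt (PN/PT)|sel = −θ_N ∫ (1 − xᵏ − (1−x)ᵏ) · 2S²e^{−2Sx}/(1 − e^{−2S}) dx
                        · PS_k/(PN_k + PS_k)²,

per 2N generations, and for the whole population −SθN·PS/(PN + PS)². The
sample form is verified against an independent finite-difference oracle:
advance the closed-form spectrum one small step under the selection term
alone and re-measure PN/PT (agreement ~10⁻⁶ relative). Whole-population
counts use P_{2N} — the expected number of sites polymorphic in a sample
of all 2N chromosomes — which avoids an arbitrary frequency cutoff. θ_N
is a free parameter (whether it embeds a site count is a units choice
that cancels in the package's contrasts).

## Wright–Fisher oracle

The validation engine propagates the expected number of sites at each
derived count i = 1..2N−1 through the exact Wright–Fisher kernel:
deterministic selection x* = x(1 − s(1+x))/(1 − 2sx) followed by binomial
resampling, 2Nlμ new singletons per generation, absorbed mass booked as
lost/fixed. Expected-value propagation (not Monte-Carlo) matches what the
diffusion predicts and removes sampling noise; dense kernels cap 2N at
1000. Comparisons start both models at their own stationary state (the
chain is burned in 10·2N generations) and restrict diffusion integrals to
[1/(4N), 1 − 1/(4N)], the midpoint cell correspondence between lattice
counts and frequency cells — continuum mass below half a lattice cell
maps to the monomorphic classes. Across a 50% bottleneck at 2N ∈ {200,
400} and S ∈ {0, 2, 10}, heterozygosity, burden, and P₂₀ agree within
about 2% (1% at 2N = 400), consistent with the O(1/N) accuracy of the
diffusion approximation.

## Synthetic exome tables

The generator emulates the *structure* of a two-population exome
aggregation call set, not its empirical joint distributions. Each
mutation class (selection coefficients 10⁻⁵..10⁻², equal weights summing
to 2/3, plus 1/3 neutral — the conventional 2:1 deleterious:neutral input
ratio) contributes latent sites in proportion to its weight; the common
normalization is set so the expected number of sample-visible sites hits
the target (default 50,000). Per site and population, the frequency is 0,
drawn from the normalized solved spectrum, or 1 (fixed derived) with
probabilities proportional to spectrum masses; sample counts are binomial
given called chromosomes. Defaults: sample sizes 2,000 and 10,000
chromosomes (desk scale; the full-study sizes 2×5,203 and 2×33,370 are a
preset), 1% ancestral misassignment (labels swapped), 2% of sites
hard-to-call in both populations (Beta(1,9) called fraction, versus
Beta(30,2) otherwise), 0.4% failing the upstream quality filter. The
conservation score is 7 + 2·log₁₀(s) + N(0,1) for selected sites and
N(0, 1.5) for neutral ones, so bins overlap and most sites in any bin are
neutral.

Because frequencies are drawn independently across populations within a
class, per-class marginal summaries converge to the solved spectra (the
tests check the projected-SFS histogram and cross-population
heterozygosity ratios) but cross-population covariance at a site is not
modeled; pipeline tests that depend only on per-population means and
their differences are unaffected, which is what passing them does and
does not show about real data. GERP-score/selection joint structure is
explicitly synthetic — the score model is a device for testing bin-level
recovery, not an empirical fit.

## Exome pipeline

Polarization trusts the recorded ancestral call where available and
otherwise assigns the highest combined-frequency allele as ancestral
(exact ties keep the recorded orientation). The missingness filter
removes sites with >90% missing chromosomes in *both* groups — the
literal "in both" reading; an OR variant is available by flag. Scores are
split into 20 equal-width bins over the observed range at or above −1.8,
with a strict catch-all bin below −1.8; bins are right-closed, ties at
edges fall to the lower bin, the observed maximum lands in the last bin,
and a degenerate range falls back to one bin with a warning. Per-site
estimators are plug-in (2p̂(1−p̂), p̂², p̂); the O(1/n) finite-sample bias
is negligible at exome-aggregation sample sizes and no correction is
specified. Confidence intervals are percentile bootstraps (default 1000
replicates) resampling sites within a bin, paired across populations.
Bins with fewer than two sites are flagged with undefined CIs. The
score-weighted burden Σᵢ GERPᵢ·fᵢ is reported per population with a
bootstrap CI on the difference, optionally cumulatively over a running
score threshold.

## Problem sizes and determinism

Default production resolution is 2000 grid points and dt = 10⁻³; the test
suite and experiment defaults use 400–800 points, which the convergence
contract shows is within a fraction of a percent for every reported
summary. The diffusion and Wright–Fisher engines are fully deterministic;
all stochastic stages (site generation, bootstraps) take explicit seeds
and reruns are byte-identical. Experiment drivers log a configuration
hash and wall time with each output set.

## Known limitations

Expectations only — no variance predictions for the deterministic
summaries; folded spectra are not computed; the ancestral-misassignment
correction is limited to the majority-rule polarization (a flip that the
recorded ancestral call endorses cannot be detected); the generator's
independence across populations understates between-population covariance
at shared sites; and the counterfactual machinery (selection switched off
from an event onward) composes solves at epoch boundaries, so switching
selection off mid-epoch requires an explicit split of the solve window.
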