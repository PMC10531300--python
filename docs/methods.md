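# Methods

This note records the models, conventions, numerical choices and known
limitations behind `sfstests`, in the order a user meets them.

## Spectrum model and units

θ is the population-scaled mutation rate **per base** (θ = 2pμN_e); expected
class counts are always θ·L·shape, with the neutral unfolded shape
ξ⁰ᵢ = 1/i and the folded shape n/(i(n−i)(1+δ_{i,n−i})). Counts are stored as
reals so that observed and expected spectra share one container
(`SpectrumCounts`); integrality of observed data is validated only on
request. All public indexing is 1-based in the allele-count class. The CLI
can display θ per sequence (θL) for comparison with the per-locus convention
common in the literature, but every computation is per base.

The default stochastic model throughout is the independent-sites
approximation (free recombination, θ ≪ 1): SFS class counts are independent
Poisson variables with mean μᵢ. This reproduces the standard second-moment
formula μ_ij = θLξ⁰ᵢδ_ij + θ²L²ξ⁰ᵢξ⁰ⱼ and extends it to all orders through
Touchard polynomials (raw Poisson moments via Stirling numbers of the second
kind). Linked-sites (finite recombination) covariances are *not* hard-coded
anywhere; an `empirical` covariance model estimated from replicates can be
plugged into the linear machinery instead.

## Weight schemes and scalings

A test is defined sample-size-independently by a weight function plus
singleton masses. Three realisations are implemented:

* **centering** — Ωᵢ = Ω(i/n) + singletons − mean. Exact centredness by
  subtraction; refused for weight functions diverging like f^(−k), k ≥ 1,
  because there the subtracted mean is neither small nor free of the 1/N
  frequency cutoff (the test suite demonstrates both the log-n growth of the
  correction and the N-dependence).
* **ratio** — difference of two independently renormalised estimator weight
  vectors. This is the form implicitly used by almost all published tests and
  the only valid one for Watterson-type weights, where the 1/log N
  normalisation cancels exactly (the realised weights (1/i)/a_n are N-free).
* **binomial** — weights assigned by integrating the weight density against
  the binomial sampling kernel. Dirac components are kept symbolic
  (location, mass) and integrated analytically, so the admixture test
  (δ(f−1/2) against uniform) is exact to machine precision. Smooth parts use
  Gauss–Legendre quadrature with max(256, 64·⌊√n⌋) nodes — the kernel has
  width ~1/√n, so the node count grows with n to keep the quadrature at
  ~1e−12 (verified against Beta-integral closed forms).

Singleton masses are applied directly to classes 1 and n−1 rather than
materialising the frequency cutoff φ of the underlying indicator-function
weights; this is valid while n ≪ 2/φ. Error-corrected tests set the masses
to cancel the weight function at the singleton classes, which makes the
final singleton weights exactly zero under the ratio form.

Fu's F(r,r′) catalogue entries accept r, r′ ≤ 1 (r = 1 is the Watterson
weight); larger exponents would need an n^(1−k) divergent normalisation with
no published recipe, so they are refused rather than guessed.

Normalisation/centredness tolerances are 1e−9 relative: all the sums
involved are short and well-conditioned.

## Linear tests

`LinearTest` evaluates T_Ω = Σ i Ωᵢ ξᵢ / √(Σ (iΩᵢ)² μᵢ) under the
independent-sites covariance by default, with μ at a known θ or a Watterson
plug-in. Significance is meant to come from simulated critical values, not
from the asymptotic N(0,1) (the normalisation only fixes the scale).

The undetectable-deviation constructor realises, for any weight vector, a
spectrum shape that is entry-wise non-negative, has at least one exactly
empty frequency class, and gives a zero test numerator. Construction: take
the null space of the single constraint Σ i Ωᵢ Δᵢ = 0 (the neutral direction
1/i always belongs to it), pick the orthonormal basis vector with maximal
angle to 1/i (lowest index on ties), flip its sign to have a negative entry,
and mix it with the neutral shape. The mixture minimum is concave and
piecewise linear in the mixing weight α, so its zero is computed in closed
form as α* = maxᵢ Δᵢ/(Δᵢ − 1/(i a_n)) over the negative-Δ classes; the
argmin entry is then set to exactly 0. The closed form (rather than
bisection) is what lets the test suite assert "minimum exactly zero, all
entries ≥ 0" without tolerance games.

## Optimal, tunable, and power

The geometric optimal test uses the scalar product ⟨x,y⟩ = x·c⁻¹y.
Ill-conditioned empirical covariances are inverted with an eigenvalue-floored
pseudo-inverse (floor 1e−12 × largest eigenvalue), since covariances
estimated from finitely many replicates can be rank-deficient.

Two z-value conventions appear in Gaussian power formulas: τ = erfinv(1−2α)
(erf convention) and τ = Φ⁻¹(1−α) = √2·erfinv(1−2α) (Φ convention). They are
deliberately kept in separate, explicitly named code paths to avoid a silent
√2 error: `gaussian_power` is the exact Gaussian power in the Φ convention
(it matches Monte-Carlo power to < 0.01 in the test suite), while
`gaussian_power_erf_form` evaluates the erf-convention closed form literally.
The literal form is anchored correctly at the null point (power = α) and at
the critical value (power = 1/2) but omits √2 factors in between; treat it
as documentation of that convention, not as the better estimate.

The tunable family Ωᵢ(λ) = (1/i)[1 − a_n/((1+λiξ̄ᵢ)·Σⱼ 1/(j(1+λjξ̄ⱼ)))] is
scanned on a 200-point logarithmic grid over [1e−4, 1e4] plus the analytic
λ→0⁺ limit (the usual optimal weights ξ̄ᵢ − (1/i)Σξ̄ⱼ/a_n); every local
maximum of the criterion is reported, because weights can change abruptly
with the scenario and several maxima can coexist, and the best grid point is
refined by bounded scalar optimisation in log λ. On small instances the
family optimum coincides with brute-force maximisation over the whole
centred-weight space to ~1e−12 in the objective — i.e. the family really
does contain the maximiser.

## Polynomial tests

Multisets of class indices are kept as ordered non-decreasing tuples Ĩ with
multiplicity σ_I = n_I!/Π(multiplicities!); the stored coefficient per
multiset is σ_I·W_I, so the statistic is a plain dot product with the
monomial vector. Strong centredness is imposed as orthogonality to the
Taylor coefficients (in θL) of the null moment vector, which makes the null
mean vanish order by order and hence for *any* plugged-in θ̂; weak
centredness fixes only the constant γ at the construction θ. Both optimal
solutions satisfy the identity Var_null(t) = E_alt(t) exactly, which the
suite checks to 1e−9 together with the agreement between the degree-2
closed forms and the general solver. Replacing the inverse covariance of the
monomials by the inverse raw second-moment matrix leaves the strongly
centred optimum unchanged (verified exactly); for weakly centred optima the
same substitution changes the statistic, so it is not offered there.

The θ plug-in default for data analysis is the Watterson estimate from the
analysed spectrum; the power study uses known-θ mode, the best case for
weakly centred tests. Weights are built once at the construction θ; the
denominator variance of Fu's renormalised G is likewise evaluated at the
plugged-in θ (a convention — the quadratic form itself does not prescribe
it). The general-degree solver refuses more than 5000 ordered multisets
(configurable); degree 2 at n = 20 uses 209.

## Simulator

Genealogies are sampled by exact competing-risks exponential event
simulation (numba kernels), accumulating branch length per
subtended-leaf-count; shapes are mean lengths divided by 2, with time in
units of 2N generations, so a single population of size N gives exactly 1/i.

* **Subdivision**: two demes of size N/2 (total N), all n lineages sampled
  from deme 1, within-deme pair coalescence rate 2, per-lineage migration
  rate M/2 (M = 4Nm). With total size N held fixed, the M→∞ limit is exactly
  the standard neutral spectrum — magnitude included — so every test's power
  decays to α at high migration. The migration-rate unit convention is not
  uniquely fixed by the literature; only qualitative power trends are
  asserted against it.
* **Expansion**: step change by a factor N₀/N = 10 (default) at time T
  before present, with the **present** size N₀ as the reference for θ and
  for the time unit (4N₀ generations) — the standard ms/msprime `-eN T 0.1`
  parameterisation. Recent pair-coalescence rate 1, ancestral rate N₀/N.
  T→∞ recovers the neutral spectrum, so power again decays to α; choosing
  the ancestral population as reference instead would leave a tenfold
  magnitude offset detectable forever, contradicting that limit.

The internal sampler is cross-validated against msprime (branch-mode SFS of
the identical two-deme model) in the test suite; msprime is never used as
the implementation.

Mutations are Poisson draws per class over the mean spectrum (the
independent-sites regime), so "replicates" are cheap and vectorised; the
genealogy stage is the only Monte-Carlo cost per scenario.

## Problem sizes and calibration choices

The power study runs at the study conditions n = 20, θ = 0.05 per base,
L = 1000, ρ = ∞. Defaults: 1e5 genealogies per scenario point, 1e5 Poisson
replicates per power estimate (Wilson 95% CI half-width ≈ 0.003 at
mid-range power), and null critical values from 4× as many replicates as the
rejection-rate estimate, so that threshold noise is small against the ±3 SE
calibration band. Critical values are plain empirical quantiles; one-sided
tests put the whole α in their tail, two-sided tests split it. Optimal tests
reject on the right tail (they are built to be maximal under their
alternative); Tajima's D is assessed on each tail separately.

## Known limitations

* No linked-sites (ρ < ∞) covariances or higher moments: every analytic
  variance is independent-sites. With real linked data, use empirical
  covariances from replicates, or empirical critical values throughout.
* The synthetic generator emulates two demographies with a single step
  parameter each; real data add linkage, sequencing error (partially
  addressable via the error-corrected weights), ancestral-state
  misidentification and missing data (no hypergeometric projection is
  implemented). Passing tests therefore demonstrate correctness of the
  statistics and their calibration under the stated model, not robustness to
  those artefacts.
* Weakly centred tests inherit the full sensitivity to θ̂ bias that their
  definition implies; they are only recommended when θ is well estimated.
* Folded-spectrum support covers the containers, estimators, covariance
  models and polynomial machinery (via folded μ, μ̄); the catalogue weights
  are defined for the unfolded spectrum.
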