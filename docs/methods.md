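# Methods

## The two-state quenching model

A probe `L` and a metal ion `M` form a 1:1 complex `ML` with association
constant `K = [ML]/([L][M])` (M⁻¹). The free probe emits with relative
quantum yield 1, the complex with `f ∈ (0, 1]`; quenching is *static*
(ground-state complexation), not collisional. Two model curves for the
quenching ratio are implemented:

* **Approximate (dilute-probe) model** — assuming the free quencher
  concentration equals the total concentration `c`,
  `F0/F = (1 + K c)/(1 + f K c)`. Monotone in `c`, saturating at `1/f`;
  it nests the static Stern–Volmer law at `f → 0`.
* **Exact model** — the bound fraction `x = [ML]/[L]0` comes from the 1:1
  mass balance `K([L]0 − [ML])([M]0 − [ML]) = [ML]` and
  `F0/F = 1/(1 − (1 − f)x)`. The physical root of the quadratic is
  evaluated in the cancellation-free form
  `[ML] = 2 K [L]0 [M]0 / (b + √(b² − 4K²[L]0[M]0))`, `b = K([L]0+[M]0)+1`,
  which stays accurate over `K = 10²–10¹²` M⁻¹ (verified against a
  bisection oracle at 10⁻⁹ relative tolerance).

The two curves differ appreciably only when `K·[L]0` is not small; below
`K·[L]0 = 10⁻³` they agree to better than 0.1%, which is why the
approximate model is the default fitting target. Fitting the
approximate model to data generated by the exact model at
`K = 10⁷ M⁻¹`, `[L]0 = 0.5 µM` biases log K low by ≈ 0.17; the
`precise=True` fitter removes this bias and is the right choice for
strong binders at non-negligible probe concentration.

## Ensemble pipeline

Relative quantum yields are measured as the OLS slope of fluorescence
against absorbance over several probe concentrations (three by default),
with a free intercept for robustness against baseline offsets
(through-origin is available via the underlying regression if needed).
The quenching ratio is `φ0/φ(c)` with first-order error propagation from
the two slope standard errors; the zero-quencher point is fixed at 1
with the reference slope's relative error. Note that with only three
points per slope the standard error has 1 degree of freedom: the
slope/se pivot is t(1)-distributed, so "±3 se" covers only ≈ 79.5% of
replicates — the per-point σ are honest but noisy, and reduced χ² of
downstream fits on this route scatters more widely than on curves with
known σ.

The two-state fit minimizes `Σ((y_i − m(c_i))/σ_i)²` over `(log10 K, f)`
with bounds `log K ∈ [0, 14]`, `f ∈ (10⁻⁶, 1]` (the lower bound on `f`
keeps the ratio finite while still admitting an effectively dark
complex). Because the saturating model has local minima, the optimizer
is multi-started from the deterministic grid
`log K ∈ {4,5,6,7,8} × f ∈ {0.05, 0.3, 0.7}`; the best converged start
wins, with grid order breaking exact ties. Standard errors come from
the Gauss–Newton curvature of the weighted objective at the optimum
(covariance = (JᵀJ)⁻¹ for σ-scaled residuals). When a curve carries no
σ, unit weights are used and the unreduced sum of squares is reported
with a warning. The Stern–Volmer null model is a weighted
through-origin line in `(c, F0/F − 1)`.

Reduced χ² is `Σ((y−ŷ)/σ)²/(n − p)`. On curves with correctly
specified σ it averages 1.0 (calibrated over 500 replicates); values
near 1 therefore indicate a correctly specified noise model, and the
Stern–Volmer fit on genuinely two-state data with `f = 0.05` exceeds
the two-state fit's χ² by far more than the factor 5 used as the
model-discrimination threshold.

## Benesi–Hildebrand analysis

At a wavelength on one wing of an isosbestic point,
`A(c) − A0 = Δε d [ML]`. In the excess-metal regime the transform
`y = d [L]0 c/(A − A0)` is linear in `c` with `K = slope/intercept`,
independent of the unknown `Δε`. Rows with `|A − A0|` below a
configurable floor (recommended: 3× the absorbance noise) are excluded
because the transform diverges there. The fit is unweighted ordinary
least squares, matching the straight-line usage; the standard error of
`log10 K` propagates from the slope/intercept covariance
(`cov(slope, intercept) = −x̄·var(slope)` for OLS). A non-positive
intercept (non-physical K) produces a *flagged* result, never a silent
number. The `curvature()` diagnostic — the relative residual reduction
of a quadratic over the linear fit — is positive on full-equilibrium
data, quantifying the low-concentration bend that appears when probe
binding depletes the free metal. On the default synthetic protocol
(probe 0.5 µM, metal 1–50 µM in 10 steps, path 0.3 cm, truth
log K = 5.16) the noiseless recovery error from full-equilibrium data
is −0.022 in log K, dominated by exactly that bend.

## Single-molecule trace analysis

Each immobilized molecule switches between a bright (free) and a dim
(metal-bound) state and finally photobleaches in a single step to a
background level that lies *below* the dim state. Per-trace analysis:

1. **Histogram** of per-bin counts; bin width 1 count while the count
   range is below 200, Freedman–Diaconis above.
2. **Three-Gaussian decomposition** by least squares on the occupancy
   histogram. Means are parameterized as cumulative positive increments
   (`m_b`, `m_b + d₁`, `m_b + d₁ + d₂`), which enforces
   background < dim < bright and eliminates label switching. Residuals
   carry approximate Poisson weights `1/√(occupancy+1)`: occupancies are
   counts, and without weighting the long post-bleach background segment
   (thousands of bins at a skewed Poisson(2)) dominates the objective
   and drags the dim component off its peak. Starts are deterministic:
   an occupancy-weighted 3-means seed, a variant with the background
   pinned at the lowest occupied count, and a local-maxima seed.
3. **Quality screening.** A decomposition is flagged when neighbouring
   components merge (separation < 1.5× the larger σ), when a component
   carries < 0.1% of the mass, or when the third component fails to earn
   its keep — the weighted RSS improvement of three Gaussians over the
   best two-Gaussian fit is below 50%, the signature of a histogram with
   only two real modes (a molecule that never bleached, or a dim state
   buried in the background). Flagged traces and traces with
   `f ∉ [−0.1, 1.1]` are excluded from aggregates, with exclusions
   counted; values within 0.1 outside [0,1] are clipped with a logged
   anomaly.
4. **Per-trace estimate** `f = (m_dim − m_bg)/(m_bright − m_bg)` and the
   arithmetic mean ± sample standard deviation over the surviving traces
   of one experiment. An experiment in which no trace survives yields
   no estimate (in practice one records more molecules).

Under the default simulation conditions (below), the aggregate mean over
many experiments recovers a true ratio of 0.18 to within ≈ 0.02
(slightly low: the Gaussian approximation to the skewed Poisson dim and
background peaks pulls both means down by a few tenths of a count, and
the bright mean is recovered to < 1%). Ratios of 0.37 are recovered to
< 0.01. Ratios at or below ≈ 0.11 place the dim mean within ~1.5 σ of
the background at bright = 40 counts/bin: such traces are screened out
as unresolvable rather than reported with a biased value — consistent
with the large experimental scatter seen for weakly emissive dim
states. With brighter molecules (200 counts/bin) a 0.11 ratio becomes
resolvable and is recovered to ≈ 0.01.

## Förster radii

`J = ∫ F̄_D(λ) ε_A(λ) λ⁴ dλ` with the donor emission area-normalized on
the overlap window; both spectra are linearly interpolated onto the
union grid restricted to that window (no extrapolation), and the
integral is trapezoidal. Disjoint spectra give `J = 0` with a warning.
`R0 = 0.02108·(κ² n⁻⁴ Φ_D J)^(1/6)` nm for `J` in M⁻¹ cm⁻¹ nm⁴ — the
standard prefactor collecting the physical constants for these units.
Defaults `κ² = 2/3` (isotropic dynamic averaging), `n = 1.33` (aqueous
buffer), `Φ_D = 0.1` (the donor yield used for the dye/metal-bipyridine
pairs). Quadrature error on smooth band spectra is below 0.1% at 1 nm
sampling. Computing radii for real probe/metal pairs requires measured
emission and extinction spectra as inputs; the package validates the
computation against analytic box-spectrum values instead.

## Synthetic-data generators

The generators emulate the measurement designs, and their defaults are
the study conditions used throughout the tests:

* **Ensemble titrations** — 21 quencher concentrations, 0–20 µM; probe
  concentrations 0.34/0.47/0.68 µM; absorbance proportional to probe
  concentration and independent of quencher (extinction × path
  2.85×10⁴ L mol⁻¹, i.e. A ≈ 0.01–0.02, safely below the inner-filter
  regime); fluorescence = absorbance × φ0/ratio with 2% multiplicative
  Gaussian noise. The direct curve generator used for fitter
  calibration draws `ratio = m(c)(1 + 0.02 ε)` with `σ = 0.02 m(c)`
  and ε truncated at ±3 (0.3% of draws; symmetric, so unbiased) to keep
  every curve physically valid.
* **Absorbance titrations** — `A = A0 + Δε d [ML]` with the *full* mass
  balance (not the excess approximation), `Δε = 10⁵ M⁻¹cm⁻¹`, d = 0.3 cm,
  additive Gaussian noise. The full mass balance is what produces the
  Benesi–Hildebrand low-concentration curvature.
* **Blinking traces** — continuous-time two-state Markov chain starting
  bright, `k_on = 1.0 s⁻¹`, `k_off = 1.5 s⁻¹` (dwells of order 1 s,
  long against the 1 ms bins; rates chosen for testability at 0.1 µM
  quencher), exponential bleach time with mean 20 s on a 30 s trace,
  bright 40 / background 2 counts per bin, dim set from the target
  ratio. The emission-rate path is integrated exactly over each bin
  (the cumulative intensity is piecewise linear), and counts are
  Poisson. About 22% of traces never bleach within 30 s and are later
  screened out for lacking a background mode — deliberately retained in
  the generator as part of the realistic trace population.
* **Spectra** — sums of Gaussian bands on a configurable grid.

Every generator is bit-reproducible from its seed and records seed and
parameters in its output metadata.

**What the generators do not emulate:** triplet shelving and other
photophysics beyond two emissive states, spectral diffusion, detector
afterpulsing, drift, inner-filter effects, impurity fluorescence, and
incomplete probe hybridization. Passing recovery tests therefore show
that the estimators are correct and calibrated under the stated noise
models — not that real data are free of these systematics; on real
measurements the probe-purity and background caveats still apply.

## Problem sizes and reproducibility

The recovery protocols use 200 simulated titrations per ensemble
operating point, 100 experiments × 15 traces for the single-molecule
pipeline, 500 replicates for the χ² calibration, and 1000 random
parameter triples for the equilibrium-solver cross-check — sizes at
which the Monte-Carlo error of each summary statistic is several times
smaller than the tolerance it is compared against. All stochastic
tests and `scripts/acceptance.py` derive every stream from explicit
seeds (`numpy.random.SeedSequence`), so results are exactly
reproducible.

## Known limitations

* The approximate-model fitter inherits the dilute-probe assumption;
  use `precise=True` with the true probe concentration for
  `K·[L]0 ≳ 10⁻²`.
* The Gaussian histogram decomposition is a least-squares fit, not a
  Poisson mixture likelihood; at low count rates the Poisson skew
  biases background/dim means by a few tenths of a count (the
  dim/bright *ratio* stays within ±0.02 under the default conditions).
  A likelihood-based variant would remove this at the cost of leaving
  the histogram-fit convention.
* Dim states within ~1.5 σ of the background are declared unresolvable
  rather than estimated; aggregates over few surviving traces carry
  correspondingly wide spreads.
* 2:1 stoichiometries, hindered-access and excited-state-reaction
  models, dwell-time kinetics and TCSPC lifetime analysis are out of
  scope.
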