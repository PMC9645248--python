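# Methods

## Model and assumptions

The core object is a size-resolved phytoplankton–herbivore system in
which each diameter class carries its own herbivore pool (the class is
the prey size range):

    dP_i/dt = µ P_i − c₁ P_i H_i
    dH_i/dt = c₁ c₂ P_i H_i − c₃ H_i²

Assumptions inherited from this minimal form: no grazing saturation or
thresholds, no explicit nutrient state (nutrients act only through µ),
and a quadratic closure for losses to unresolved higher predators.
Setting both rates to zero with H > 0 gives H* = µ/c₁ and
P* = c₃µ/(c₁²c₂). Two consequences carry all downstream results:
equilibria are strictly proportional to µ, and the realized per-capita
loss c₁H* equals µ exactly — which is why size-dependent division rates
barely move the size spectrum (faster division is compensated by
equally faster loss; what survives in P* is µ·c₃/c₂).

µ = 0 is treated as degenerate (H* = 0, P* undetermined) and refused
rather than guessed.

## Size grid and spectrum conventions

Cells are spheres of constant carbon density (default 1, arbitrary
units): biomass per cell is (π/6)d³·ρ. Bin centers are geometric means
√(lo·hi) in both binning modes, so a power-law density is exactly
log-linear at the centers and fitted slopes are bin-count invariant.
Abundance density is (P_i / biomass-per-cell) / bin-width
(cells·ml⁻¹·µm⁻¹); the SDS is unweighted OLS of log₁₀ density on log₁₀
diameter (base-10 throughout). Zero-density bins are dropped from the
regression with a logged warning; at least three positive bins are
required. The default grid is 24 proportional bins over 0.5–100 µm
(pico- through micro-phytoplankton); slope results do not depend on the
bin count for exact power laws, only plotting fidelity does.

Reference normalization multiplies the whole spectrum by one scalar so
the bin containing 0.5 µm (half-open [lo, hi) membership) holds
10⁴ cells·ml⁻¹; the slope is invariant.

The volume/biomass transform assigns each diameter bin's biomass
(density·width·biomass-per-cell at the center) to the logarithmically
spaced volume bin containing its center volume, conserving total
biomass to machine precision. Note the continuum identity
dB/dlog d ∝ d^(s+4): at the fundamental slope s = −4 biomass per
log-volume bin is exactly flat; bloom-tilted spectra (s > −4) place the
balance of biomass in large cells, and the deeper stable slopes
(s < −4) in small cells. This is the quantitative content of the
contrast between oligotrophic and productive systems.

## Allometric rules and their calibration

Size dependence is expressed as pure power laws
value(d) = base·(d/d_ref)^exponent with d_ref = 1 µm, which makes every
slope shift exactly additive: SDS = −4 + e_µ + e_c₃ − e_c₂. The default
calibrated exponents are e_µ = −0.1 and e_c₂ = +0.25, e_c₃ = −0.25
(net −0.5 from the grazing pair), reproducing the −4.1 and −4.6
outcomes. These are calibrations, not mechanistic derivations: the
functional forms behind those outcomes are not fully specifiable from
first principles here, and a genuinely strong µ size dependence such as
the surface-flux limit (absolute nutrient flux ∝ surface area d²,
divided by a volume-proportional quota ⇒ µ ∝ d⁻¹) would by itself shift
the slope by −1, not −0.1. That tension is deliberately surfaced: the
surface-flux rule ships as a separate named preset rather than being
folded into the calibrated default.

The calibrated c₂ rule is anchored at base 0.3 rather than the
size-independent default c₂ = 0.5, because 0.5·d^0.25 would exceed the
ingestion-efficiency bound c₂ ≤ 1 above d ≈ 16 µm. The anchor is
immaterial to every slope (P* depends on c₂ only through a ratio); the
bound is enforced where per-bin parameters are constructed. Grazing
rate c₁ is size-independent by default but accepts a rule, honoring the
per-class subscript in the data model.

ODE verification uses an explicit adaptive Runge–Kutta integrator
(scipy `solve_ivp` RK45, rtol 1e−8, atol 1e−12); negative excursions
beyond −1e−10 abort, smaller ones are clipped to zero. The system is
not stiff at these parameter scales. The analytic equilibrium and
long-horizon integration agree to 1e−3 relative across random parameter
draws in the test suite — a dual-route check, not a shared code path.

## Lagged dynamics

In the tightly coupled but time-lagged food web the loss rate equals a
prior division rate, r(t) = µ(t) − µ(t−j). The exact difference form is
used; the derivative form (dµ/dt)·Δt is its first-order approximation
and is not used. Lags default to j(d) = j₀·d^θ with j₀ = 1 d at 1 µm
and θ = 0.5 — only the monotone increase of j with size is
scientifically constrained; the magnitudes are illustrative and fully
configurable. Pre-history is steady state: µ(t−j) clamps to the
series' initial value before its start.

Division-rate series are uniformly sampled and linearly interpolated;
per-class values are clipped hard into [µ_min, µ_max] (µ_max is a
ceiling that ends the acceleration phase, not a smooth saturation).
Integration advances ln P with the trapezoidal rule, which preserves
positivity, is exact for piecewise-linear r with breakpoints on the
grid, and makes j = 0 conserve biomass to machine precision. Steps with
|r|·dt > 0.5 are rejected as unresolved. A useful closed form anchors
the scenario design: once µ settles Δµ above its start, every class's
log-biomass gain is exactly j·Δµ, independent of the ramp rate.

Peak-time succession ordering breaks ties by diameter, ascending; a
class whose biomass is still rising at the horizon is reported as
having no peak. The per-time SDS maps each class to the diameter bin
containing it and refits the slope on the occupied bins.

## Spacing analysis

Cell placement is modelled as a homogeneous Poisson point process —
the appropriate null for *average* spacing; patchiness, swimming, and
turbulence move individuals but do not change the mean. The expected
nearest-neighbor distance is Γ(4/3)·(4πn/3)^(−1/3) with n in
cells·µm⁻³ (554 µm at 10³ cells·ml⁻¹). Body length ≡ cell diameter, and
the tree analogy multiplies the body-length spacing by a 12 m analog
height; both assumptions are explicit function arguments. The Monte
Carlo oracle places points uniformly in a periodic cube (KD-tree
nearest-neighbor queries; periodicity removes edge bias) and agrees
with the analytic mean within 3 standard errors at 10⁵ points.

## Synthetic data

Synthetic spectra are power laws with multiplicative lognormal noise:
density_i = A·d_i^s·10^ε, ε ~ N(0, σ²) with σ in dex (default 0.1,
chosen as a visually realistic scatter for field spectra; no published
value constrains it). A anchors the noise-free envelope at
10⁴ cells·ml⁻¹ in the 0.5 µm bin, i.e. the anchor is median-exact under
noise; the stable/bloom pair generator renormalizes after the noise
draw so both members anchor exactly. Generators are pure functions of
(config, seed). What the generator does not emulate: instrument sizing
biases, multi-segment spectra, patchiness — so passing tests demonstrate
correct recovery under the assumed error model, not robustness to real
instrument artifacts.

Scenario fixtures use a small/mid/large triplet (2, 10, 50 µm; lags
1.41, 3.16, 7.07 d from the default lag model) with size-ordered ramp
accelerations 0.5/0.25/0.1 d⁻² and ceilings µ_max = 1.2/1.6/2.0 d⁻¹.
Environments differ in the pre-bloom floor and improvement window:
deep mixing (µ_min = 0.1, 40 d window) lets every class reach its
ceiling, so peak gains ≈ j·(µ_max − µ_min) order small < mid < large and
the succession completes; shallow mixing (µ_min = 0.5, 4 d window) cuts
the large class's achieved amplitude enough that the mid class wins;
Si limitation reduces only the large class's ceiling (0.8 d⁻¹),
truncating its bloom while leaving the others bit-identical. These
parameter choices were made once from the j·Δµ gain formula.

## Problem sizes and numerical tolerances

Default analyses run in well under a second (24–100 bins, a few
thousand time steps); the Monte Carlo spacing check uses 10⁵ points.
Slope assertions use 1e−6 absolute for the exact pipeline results and
0.01 for the calibrated allometry outcomes; equilibrium-vs-ODE
agreement 1e−3 relative; biomass conservation 1e−9 relative.

## Known limitations

Herbivore dynamics are reduced to the scalar lagged division rate in
the bloom module (no explicit predator state), grazing is linear, and
nutrients never feed back on µ within a scenario. The wholesale-grazer
tilt is a stated proportionality applied to the slope, not a
two-predator re-derivation. Field spectra are emulated, not ingested;
conclusions about real communities rest on the model, not on data
packaged here.
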