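# Methods

`celldose` models the absorbed dose to, and survival of, individual cells in
radiolabeled multicellular populations — cell pairs, planar colonies and 3-D
clusters — for alpha-, beta- and Auger-electron-emitting radiopharmaceuticals.
This note records the model, its assumptions, the numerical choices, and the
places where the design was genuinely open.

## Physical model

**Cells.** Every cell is two concentric spheres of liquid water at unit
density: a cell of radius `r_cell` and a nucleus of radius `r_nucleus`.
Source regions are the whole cell (C), nucleus (N), cytoplasm (Cy) and cell
surface (CS); target regions are C, N and Cy (Cy is always evaluated as
C minus N, which makes the energy partition exact by construction). All cells
in a population are identical. Radii above 10 µm trigger a warning: the
concentric-sphere dosimetry has been exercised mainly for smaller cells, and
ignoring photons becomes progressively less defensible as spheres grow.

**Transport.** Charged particles follow straight tracks in the
continuous-slowing-down approximation (CSDA): a particle of energy `E0` has
a fixed range `R(E0)`, and the energy remaining after a path `x` is
`E(x) = R⁻¹(R(E0) − x)`. Electrons (betas at their average energy,
conversion and Auger electrons at their line energy) default to the Cole
empirical power law `R[µm] = 0.0431 (E[keV] + 0.367)^1.77 − 0.007`, inverted
in closed form; an alternative electron relation built from a packaged CSDA
range table is selectable. Alpha particles use a packaged range–energy table
interpolated piecewise-linearly in log–log space, with the stopping power
taken as the exact derivative of the interpolant so that kernel integrals
conserve energy identically. The packaged tables are approximate
transcriptions of standard stopping-power compilations (ICRU 49 / ICRU 37
lineage); their headers say so. Angular scattering, energy-loss straggling,
delta rays, bremsstrahlung and photons are outside the model — gamma and
x-ray lines are parsed and reported but deposit nothing.

**S coefficients.** The S coefficient (absorbed dose per decay,
Gy·(Bq·s)⁻¹) for a target←source pair is `S = Σ Δ·φ/m(target)` over the
emission lines, with `Δ` the mean energy emitted per nuclear transition and
`φ` the absorbed fraction. `φ` is computed by a two-level Gauss–Legendre
quadrature: the source region is reduced to the closed-form probability
density of the distance ρ between emission point and target-sphere center
(uniform-ball, spherical-shell and sphere-surface pair-distance densities,
for both the self case and a source cell a distance d away), and the
direction average at each ρ differences the residual energy at the chord
entry and exit points — exact under straight-line CSDA. The direction
integrand has a kink where the path length to the sphere boundary equals
the particle range; that direction cosine has the closed form
`µ_L = (r_t² − ρ² − L²)/(2Lρ)`, and each quadrature row is split there
(128 + 128 nodes). The ρ-quadrature (48 nodes per smooth segment) is
clipped to emission points that can reach the target at all, which keeps
thin "sliver" configurations (short range, distant source region) fully
resolved. Convergence was checked by node-doubling; values are stable to
better than 1 part in 10⁶, and cross-S is exactly zero beyond
`range + 2 r_cell`.

**Monte Carlo oracle.** An independent brute-force estimator samples decay
positions uniformly in the source region, isotropic directions, and tallies
chord-differenced energy deposits in the target sphere, reporting a standard
error. It shares only the range–energy model with the quadrature, so the
agreement demanded by the test suite (self within 2%, cross within 5%, both
typically within ~0.2%) is a genuine cross-check of the integration, not of
the physics data. It stands in for an external track-structure code, which
this package deliberately does not attempt to replace.

## Populations

Cells sit on a simple cubic lattice with pitch equal to the center-to-center
spacing, anchored at the cluster center, ordered deterministically by
(z, y, x). Non-spherical shapes (circle, rectangle, ellipse, ellipsoid, rod,
cone) include every lattice point inside the closed boundary.

**The spherical cluster uses a calibrated capacity rule.** The published
reference configuration (cluster radius 125 µm, cell radius 6 µm, nucleus
5 µm, spacing 13 µm) is reported with 3,473 cells. No radial threshold on
the centered lattice can produce that count: achievable counts jump from
3,431 to 3,575 across a 144-fold degenerate lattice shell, and any
octahedrally symmetric rule can add that shell only in orbits of 24 or 48.
(The plain rule |center| ≤ R gives exactly 3,743 — the same source's other
printed estimate for this spheroid; the two figures differ by a digit
transposition and the discrepancy is unresolved upstream.) To pin the
reported count, lattice sites are admitted in order of increasing distance
from the center (ties broken by (z, y, x)) up to a continuum capacity
`round((4/3)π R_eff³ / s³)` with `R_eff = R − κ·r_cell`, κ = 0.4787,
calibrated once against the reference configuration and frozen. `R_eff`
falls between `R − r_cell` and `R`, i.e. the boundary cells of the admitted
population protrude partway past the nominal surface, as they must for any
count in the calibration window.

**Cold core.** A drug-penetration depth marks cells within that exact
distance of the cluster's outer surface as eligible for labeling; the
distance is computed exactly per shape (the ellipsoid case solves the
Lagrange nearest-point problem, including the degenerate zero-coordinate
candidates). Unlimited depth makes all cells eligible; depth 0 makes none.

## Labeling and activities

Labeled cells are a uniform random subset of the eligible cells of size
`round(percent × n_cells / 100)`; a request exceeding the eligible count is
clamped to all eligible cells with a warning (the interactive-tool
behavior). Activities come from:

* **uniform** — every labeled cell gets ⟨A⟩;
* **normal** — Normal(⟨A⟩, σ²) with negative draws rejected and redrawn;
  the induced upward mean shift is `σ·φ(µ/σ)/Φ(µ/σ)` and is negligible for
  σ ≲ ⟨A⟩/3, the intended regime;
* **lognormal** — `ln A ~ Normal(ln⟨A⟩ − σ²/2, σ²)`, whose mean is exactly
  ⟨A⟩ for every shape parameter σ;
* **radial profiles** (3-D, non-ellipsoid) — linear, exponential
  `exp(k·r)`, polynomial up to degree 10, a 4-parameter lognormal
  `a·exp(−ln²((r−c)/b)/(2s²))`, or a user table (linear interpolation,
  constant extrapolation). r = 0 is the cluster center. The profile fixes
  only the *shape*; the scale is set so the mean activity per cell over
  **all** cells equals `max_mean_activity_bq`, the same quantity that tops
  the activity sweep. Because this fixes the total activity, the choice of
  profile has little effect when only a thin surface layer is labeled.
  (Normalizing instead to the hottest labeled cell was considered and
  rejected: it makes the delivered dose depend strongly on the profile
  shape and understates the reference scenario's dose scale by an order of
  magnitude.)

The exponential sign convention — activity maximal at the cluster surface,
decaying inward for k > 0 — reflects a radiopharmaceutical binding from
outside; the scale-invariant normalization makes any anchor radius drop
out. Every cell shares one subcellular split (f_N, f_Cy, f_CS), summing
to 1.

Randomness uses named substreams of one master seed (label selection,
activity sampling, and one fate stream per sweep point), so changing one
choice never scrambles another, and a fixed seed reproduces every output
byte for byte.

## Dosimetry

Decays per cell are `A_k × τ × 3600` with the time-integrated activity
coefficient τ in hours; `τ = T_p/ln 2` reproduces pure physical decay and
any override models clearance. Self-dose components are
`f_region × Ã_k × S_self`; cross components sum `f_region × Ã_j × S(d_kj)`
over labeled neighbors, using an S table precomputed for exactly the finite
set of realized lattice distances (an absent distance is a hard error, never
an interpolation). Pairs beyond `max range + 2 r_cell` are skipped; for
alpha emitters this keeps the reference spheroid run near-linear.
Accumulation follows the fixed cell order, so totals are bit-reproducible.

A note on conservation testing: with spacing larger than the cell diameter
the cell spheres do not tile space, so summing absorbed energy over cells
cannot recover the emitted energy in general. Conservation is therefore
verified (a) at the kernel level — the volume integral of the point kernel
recovers E0 to better than 0.5% — and (b) with emissions whose range is
contained in the source cell, where `S(C←N)·m(C) = Δ` holds to 0.1%.

## Bioeffect

Simple model: `P = exp(−α_s D_s − β_s D_s²)·exp(−α_c D_c − β_c D_c²)`.
Complex model: one such factor per (radiation type, source region,
self/cross) component for the chosen target region, an
independent-interaction product with no synergy terms; a missing parameter
for a present component is a hard error. The shipped default table
(α = 0.1 Gy⁻¹, β = 0.01 Gy⁻² everywhere) is arbitrary and warns on use.

Cell fates are drawn once per sweep point (alive iff u < P with u uniform
on [0, 1), realizing survival with probability exactly P). The SF curve
sweeps activity linearly over 21 points (configurable) from zero to the
maximum with the labeling pattern held fixed, reporting both the MC
realization `SF_mc` and the deterministic `SF_expected = mean(P_k)` — the
stable quantity for regression — against seven domains (mean activity,
decays and dose per cell / per labeled / per unlabeled cell). TCP is
reported both as the Poisson form `(1 − SF)ⁿ` (n = all cells in the
cluster) and as the exact product `Π(1 − P_i)` evaluated on the pre-draw
probabilities; with any cell at P = 1 the product is identically zero,
which is the correct reading of the formula.

## Reference scenario

The packaged reference configuration (`celldose.examples`) models a
250-µm-diameter spheroid whose outer ~12 µm binds a ²¹³Bi-labeled antibody:
²¹³Bi plus equilibrium daughters on the cell surface, nucleus target,
radial-exponential labeling (factor 0.4 µm⁻¹) clamped to the 696-cell rim,
τ = 1.11 h, peak mean activity 0.02 Bq per cell, and an alpha-only LQ
response α = 1/D₀ = 1/1.8 Gy ≈ 0.56 Gy⁻¹ (zeros for betas and Auger
electrons; running with defaults for those radiations changes nothing
because only the alpha dose is weighted). The survival curve shows the
expected two-component structure — a steep fall as the rim and the
alpha-reachable shell are sterilized, then a tail from the unlabeled core
beyond alpha range — and at the top of the sweep every surviving cell is an
unlabeled interior cell. The packaged ²¹³Bi half-life gives
τ = T_p/ln 2 = 1.096 h, about 1% below the quoted 1.11 h; the difference
traces to the half-life datum/rounding and is accepted as within tolerance.

## What the tests do and do not show

The synthetic populations are perfect lattices of identical spheres with
noiseless emission data; real spheroids have packed, size-dispersed cells,
nonuniform binding, biokinetic clearance and dose-rate effects, none of
which are modeled (a scalar τ and user-chosen LQ parameters are the only
knobs that can absorb them). Passing tests therefore demonstrate the
internal correctness of the geometry, quadrature and bookkeeping and the
qualitative reproduction of the reference scenario — not the absolute
accuracy of the underlying range–energy data, which enters as packaged
input. Stochastic fluctuation in the *number* of alpha decays per cell
(relevant at ~80 decays/cell) and bystander effects are likewise out of
scope.

## Problem sizes used in the automated checks

The reference spheroid (3,473 cells, ~300 distinct pair distances) runs the
full pipeline in well under a minute; oracle comparisons use 10⁶ histories
per line (standard errors a few 0.1%); distribution checks use 10⁵ draws.
These sizes were chosen so every documented property is resolved with
comfortable statistical margin.
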