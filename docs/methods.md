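# Methods

## The wetting model

The implanting embryo is treated as a passive fluid droplet of fixed volume
`V` inside an axisymmetric crypt, either a cylinder of radius `r` or a
conical frustum whose wall radius at axial coordinate `z` (measured from the
apex at `z = 0`) is `z·tan α`. The droplet–medium interface carries tension
`γ₀`; contact with the wall changes the energy per unit area by the Young
tension `Δγ` (droplet–substrate minus substrate–medium). Only the ratio
`δ = Δγ/γ₀` affects the shape, so `γ₀ = 1` internally and all tension
results are reported as the normalized `δ`. The shape is assumed
axisymmetric with free surfaces that are exact spherical caps (constant mean
curvature), so a configuration is finite-dimensional: the contact-line
separation `h` and common cap height `y` in the cylinder, or the contact
lines `z₁ > z₂` and signed cap heights `z₃, z₄` in the frustum (negative
heights curve into the droplet). Equilibria are stationary points of

    E = γ₀·(cap areas) + Δγ·(wall contact area)

under the volume constraint, with the Laplace pressure `ΔP` as the Lagrange
multiplier. Contact angles are measured through the droplet between surface
and wall; Young's relation is `cos θ = −δ`, so growing adhesion (falling
`δ`) spreads the droplet.

### Cylinder

Eliminating `h` with the volume constraint leaves a one-parameter family in
`y`. Stationarity gives `δ = 2ry/(r² + y²)` with roots
`y∓ = r(1 ∓ √(1−δ²))/δ`. The second variation
`d²E/dy² = 4π(γ₀ − Δγ·y/r)` is positive on `y₋` (stable) and negative on
`y₊` (unstable); the branches merge at `|δ| = 1`, the transition to total
wetting. When the stable branch cannot bridge the tube (`h < 0`), a
detached sphere of equal volume is returned with the dewetting label.
Physically admissible bridged shapes keep `|y| ≤ r` (caps at most
hemispherical, no self-intersection); the brute-force oracle used in tests
minimizes `E(y)` over exactly that admissible range.

### Frustum

Stationarity in `(z₁, z₂, z₃, z₄)` yields Young's condition at both contact
lines (`sin(φ_a − α) = δ` at the top, `sin(φ_b + α) = δ` at the bottom,
with `φ` the signed cap opening angle) and equal signed Laplace pressure
across both caps. Pressure equality fixes `z₂/z₁`, making the family
self-similar, and the volume constraint sets the scale in closed form. A
consequence of the stated energy is that a *free* interior equilibrium
exists only for `δ > sin α`: for smaller `δ` the energy decreases towards
the apex — the classical migration of a wetting liquid down a cone — and
the bottom contact line pins at the lower end of the wall (`z_range[0]`).
The solver then solves the pinned system (Young at the top line, pressure
equality, volume) with a bracketed root find and flags `pinned_bottom`;
the pinned branch joins the free branch continuously at the transition and
keeps `θ_b` smoothly and monotonically dependent on `δ`, which is what
makes the bottom angle informative for inference throughout the adhesion
range. Droplets that overfill the wall pin at the top (`pinned_top`);
droplets too small to reach the wall dewet.

Wetting regimes: I at the total-wetting transition (`θ → 0`), II for
partial wetting with flat or inward caps (`θ ≤ 90°`), III for outward caps
(`θ > 90°`), IV for dewetting. The split of II/III by cap orientation is a
documented choice; the partition is total.

## Tension dynamics and the quasi-static assumption

Adhesion maturation is modelled by a five-constant sigmoid for `δ(t)`:
plateaus `c1` (before `t1`) and `c2` (after `t2`), a monotone C¹ ramp in
between, and a modulation parameter `a ≥ 0`. The ramp is the cubic
smoothstep `s(u) = u²(3−2u)` sharpened through
`s^(1+a)/(s^(1+a) + (1−s)^(1+a))`; `a = 0` recovers the symmetric ramp with
midpoint `(c1+c2)/2` at `t0 = (t1+t2)/2`. This closed form is one isolated
function and can be swapped without touching the solver or the inference.

Shape trajectories are quasi-static: at each time the droplet is at
equilibrium for the instantaneous `V(t)` (piecewise-linear interpolation of
the measured or generated volume series; extrapolation is an error) and
`δ(t)`. No viscous relaxation or contact-line friction is modelled, and
`V(t)` is always an input — blastocoel inflation–collapse mechanics are not
predicted. Dewetting or pinning at individual time points is recorded as a
per-point regime label, never an exception.

## Inference

The posterior over `(c1, c2, t0, dt, a)` is obtained likelihood-free:
forward simulations are weighted by a Gaussian pseudo-likelihood on the
contact-angle residuals scaled by the per-point SEM (floored at 1° to avoid
zero-variance weighting). Only `θ_b` is required; `θ_a` enters when
present. Sampling is adaptive importance sampling: the budget is split over
three rounds, the first drawing from the bounded-uniform prior (defaults:
`c1, c2 ∈ [−1, 1]`, `t0` spanning the observation window, `dt ∈ [1, 30]` h,
`a ∈ [0, 5]`), later rounds from a defensive mixture of 80% Gaussian
moment-matched to the previous weighted sample (covariance regularized by
5% of each prior range) and 20% prior, with exact importance correction.
The scheme is deterministic under a fixed `(data, prior, n_sims, seed)`.
Point estimates are weighted posterior medians. Predictive bands are
quantiles of the noise-inclusive mixture (Gaussians of width SEM centred on
the simulated trajectories), inverted by bisection — this is the band whose
95% level is used for leave-one-out coverage. Model comparison fits the
restricted constant-tension null (`c1 = c2`) with the same machinery and
reports SEM-weighted RMSEs of the two point-estimate fits.

At desk-scale budgets (10⁴ simulations) the weighted sample has an
effective size of tens; posterior medians are accurate (parameter-recovery
errors ≲ 0.05 on `c1, c2`) but credible intervals are mildly underdispersed
— the calibration test uses the documented conservative 70% bound for the
90% interval.

## Quantification operators

All operators work in physical μm, voxel centers, 0-based indices, arrays
`[z, y, x]` with anisotropic spacing `(sx, sy, sz)`; the crypt axis is the
array's first axis after alignment.

* **Contact angle** — radial reslice about the symmetry axis over 180° in
  30° steps (left/right sides give the full circumference), boundary
  extraction per meridional half-plane, tangent fit over a 15 μm handle at
  the contact point, circumferential average. The default tangent estimator
  fits a local quadratic in a chord-aligned frame and evaluates the tangent
  at the contact point: a straight total-least-squares chord over handle
  length `L` on a cap of radius `R` biases the angle by ≈ `L/2R` (≈ 6° at
  `R ≈ 70` μm), which the quadratic removes to first order.
  `method="tls"` keeps the plain line fit. Azimuths with no boundary in the
  handle window are dropped with a warning; fewer than 3 valid azimuths is
  an error. On solver-rendered phantoms at 0.3 μm lateral spacing the
  recovery error is ≤ 2.3° across θ ∈ {45°, …, 135°}.
* **Middle axis** — Euclidean distance transform with anisotropic sampling;
  directed 26-neighbor voxel graph with edge cost `max(DT) − DT(target)`
  (deterministic lexicographic node order); Dijkstra shortest path between
  the voxels nearest the annotated poles (snap radius 5 μm); open cubic
  B-spline fitted with smoothing grown by bisection until the maximal node
  deviation reaches one voxel diagonal; arc length by Simpson quadrature on
  the spline speed. The sparse-graph Dijkstra is scipy's; the weighting is
  as stated above.
* **Diameter** — plane orthogonal to the middle axis minimizing the summed
  squared landmark distance, mask resampled on an in-plane grid at the
  finest voxel pitch, area-equivalent diameter `2√(A/π)`.
* **Kymograph fronts** — per line and frame, 3-point median filter then the
  first *sustained* half-maximum crossing (below → above for two samples),
  which single-pixel impulses cannot fake; fronts averaged across the nine
  lines and reported relative to the starting coordinate.
* **Aspect ratio** — height is the extent along the apicobasal axis, width
  the maximal extent along the two orthogonal frame directions (extents are
  voxel-center ranges plus one voxel).
* **Counts / volumes** — exact label counts; volume is voxel count times
  voxel volume.

## Synthetic data

Generators are the package's study conditions; each takes a mandatory seed
(numpy `default_rng`) and returns its ground truth alongside the data.
Calibrated defaults: trophoblast drift 2.51 μm/h down the crypt axis with a
small diffusion (0.1 μm²/h) so the pooled 1 h windowed speed stays near the
drift; egg-cylinder front speed 5.52 μm/h; division probability 12% per
nucleus per 24 h (divisions duplicate the parent with a 2 μm offset);
epiblast volume growth 1.78× per 8 h. The default crypt is a frustum of
half-angle 0.2 rad with wall between `z = 230` and `700` μm (radii ≈ 47–142
μm; a 140 μm opening performed best in culture), and the default tension
truth ramps from `δ = +0.4` to `−0.6` around 45 h post-E3.5 over 10 h —
near-neutral contact giving way to adhesion, reproducing the observed
θ_b decline from ~130° towards ~90°. Embryo volumes default to
`V₀ = 8×10⁵` μm³ growing at 3%/h with one 30% collapse at 44 h recovering
over 3 h; collapses are instantaneous fractional drops with exponential
recovery (no mechanistic functional form is claimed). Contact-angle
observations add Gaussian noise of σ = 3° per point and attach
SEM = σ/√k with k = 1 by default, keeping the error bar consistent with the
noise actually added.

What the generators do **not** emulate: microscopy point-spread functions
and photon noise, segmentation errors, non-axisymmetric embryo shapes,
wall deformation (soft wetting), or biological variability in the tension
law beyond the configurable t₀ jitter. Passing tests therefore demonstrate
correctness of the operators and identifiability of the model under its own
assumptions, not robustness to every imaging artefact of real data.

## Numerical choices and problem sizes

Root finds use Brent's method at relative tolerance 1e-14 (scalar) or 80
bisection steps (vectorized batch); closed-form branches are exact to
machine precision, and volume reconstruction errors are ≲ 1e-12 relative.
Flat caps (θ = 90°) are handled analytically (R = ∞) to avoid 1/y
singularities. Angles are degrees at interfaces, radians internally.
Test and acceptance problem sizes — 20-point series, 10⁴-simulation fits,
20-seed model-comparison sweeps, 3-embryo cohorts, phantoms of ~10⁷ voxels
— were chosen as the smallest sizes at which every reported quantity is
stable to well within its tolerance.

## Known limitations

* The frustum solver covers free, bottom-pinned, top-pinned and dewetted
  configurations; translational stability of the free branch in a cone is
  not analysed beyond the pinning argument above.
* The vectorized batch forward model omits the rare top-pinned branch
  (scalar solver handles it); under the default geometry and priors it is
  never reached.
* Credible intervals at small simulation budgets are underdispersed (see
  Inference); increase `n_sims` where calibrated uncertainty matters.
* The contact-angle operator assumes the crypt axis is the array z axis and
  the wall is the analytic confinement geometry; estimating the wall from a
  background-fluorescence mask is not implemented.
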