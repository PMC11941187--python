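# Methods

## Model

`conepore` simulates a single rigid spherocylinder (a capsule: cylinder of
length `l` capped by two hemispheres of radius `r`, uniform density, unit
total mass) performing overdamped Brownian motion inside an axisymmetric
conical channel.  The channel has length `L` along the `z` axis, wall
radius `R(z) = R0 + (RL - R0) z / L`, a reflecting entrance at `z = 0`
(the wide end) and an absorbing exit at `z = L` (the narrow end).  The
reference geometry is `L = 15`, `R0 = 0.5`, `RL = 0.25` (wide diameter one
unit, narrow diameter half of it); `RL = R0` gives the cylindrical control
channel.  Only one particle is in the channel at a time; hydrodynamic and
particle-particle interactions are outside the model.

Time is discrete and counted in steps.  One step consists of:

1. **Translation attempt.**  A displacement with three independent
   `N(0, sigma_x)` components is proposed for the centre of mass
   (Euler-Maruyama with unit time step).  It is accepted iff the displaced
   body does not intersect the channel wall and the new centre of mass has
   `z >= 0` (the reflecting entrance is realized by rejection).  A
   rejected proposal leaves the position unchanged but still consumes the
   step.
2. **Rotation attempt.**  A rotation axis `A` is drawn uniformly on the
   sphere (through the centre of mass), and the rotation angle from
   `N(0, sigma_phi(A))` with

       sigma_phi(A) = sigma_x / sqrt(A^T M A),

   the equipartition coupling between translational and rotational noise.
   `M` is the inertia tensor of the unit-mass capsule; by axisymmetry only
   `cos psi = A . u` enters, `A^T M A = Mxx (1 - cos^2 psi) + Mzz cos^2
   psi`.  The rotation (Rodrigues formula, director renormalized) is
   accepted iff the rotated body does not intersect the wall.
3. Time increases by one regardless of acceptances; then absorption is
   checked: the trajectory stops at the first step with centre-of-mass
   `z >= L`, and that step index is the first passage time (FPT).

Mass partition and moments for the unit-mass capsule follow from uniform
density: `m1 / m2 = 3 l / (2 r)` (cylinder over single hemisphere) with
`m1 + 2 m2 = 1`, and

    Mxx = Myy = m1 (l^2/12 + r^2/4) + 2 m2 (2 r^2/5 + l^2/4 + 3 l r / 8)
    Mzz = (m1/2 + 4 m2/5) r^2

`sigma_phi` is not capped: for very small particles it exceeds 2*pi and
the orientation simply decorrelates in one step, which is harmless since
for near-spherical particles orientation barely couples to the walls.

The particle is inserted at the wide end with its centre of mass at the
origin and an orientation drawn uniformly over the feasible directions
(rejection sampling); an axis-aligned start is available as a
configuration option.  The transverse start position is on-axis, the
symmetric feasible choice for every particle size.

## Wall containment

The capsule is the Minkowski sum of its axis segment and a ball of radius
`r`, so it is wall-free iff the perpendicular distance from the axis
segment to the cone surface is at least `r` everywhere.  The clearance of
an axis point at cylindrical radius `rho` and height `z` is
`(R(z) - rho) / sqrt(1 + slope^2)` — the 3-D distance to the surface of
revolution, not the horizontal gap (the two differ by 0.014% at the
reference slope, but the code is exact for steep cones).  Along the
segment the clearance is a concave function of the segment parameter
(linear wall radius minus a convex radial distance), so its minimum is
attained at an endpoint and containment reduces to two endpoint checks.
A brute-force surface-sampling oracle (area-weighted points on the
cylindrical shell and caps) validates this reduction in the test suite.

Because only the centre of mass is confined to `[0, L]`, a long particle
can overhang either end of the channel.  The wall is linearly extrapolated
beyond `z in [0, L]` wherever the body overhangs, so an overhanging
half-body is still tested against the extended cone.  The alternative
reading — a pore that opens into unconfined reservoirs, with the wall
acting only on the body portion at `z in [0, L]` (implemented by clamping
the axis segment to that slab before the endpoint checks) — was
implemented and measured during development: it introduces a strong
entropic trap at the pore mouth (rods dangling out of the entrance at
large angles), slowing the escape of long rods by one to two orders of
magnitude.  Neither reading reproduces the published escape rate of the
`l=7, r=0.05` rod exactly (see Limitations); the extrapolated wall is kept
as the primary model.

## Random numbers and reproducibility

Each trajectory runs on its own xoshiro256++ stream whose 256-bit state is
filled by splitmix64 from a 31-bit per-trajectory seed, itself derived by
a splitmix64 mix of (master seed, trajectory index).  Ensembles are
therefore bit-for-bit reproducible and independent of trajectory execution
order.  Gaussian deviates use the Marsaglia polar method and uniform
directions the Marsaglia sphere method — exact samplers chosen because the
compiled inner loop (numba) spends most of its time in random-number
generation.  A pure-Python backend built from the op-level functions
(`sample_translation`, `step`, `run_single`) implements the same model and
is statistically cross-checked against the compiled kernel in the tests.

## Analysis

* **MSD.**  `<|x(t) - x(0)|^2>` averaged over trajectories that are still
  in the channel at time `t` (survivor averaging); absorbed trajectories
  leave the average at their FPT.  States are recorded on a log-spaced
  grid (default 200 points per decade) because trajectories run to 10^6+
  steps.
* **Anomalous exponent.**  `msd = D t^alpha` fitted by nonlinear least
  squares in linear space over the window `[0.01 t_min, t_min]`, where
  `t_min` is the FPT of the fastest tracer — no point in the window is
  affected by absorption.  The fit is initialized from (and reported
  alongside) a log-log linear regression.  Note that `t_min` is an extreme
  order statistic: its seed-to-seed variability moves the fit window and
  is the dominant noise source in `alpha` at moderate ensemble sizes.
* **FPT statistics.**  The median of the non-censored FPTs (midpoint
  convention) is reported; if more than 10% of trajectories hit the step
  cap the median is refused as biased.
* **Survival.**  `S(t)` is the fraction of trajectories with `fpt > t`
  (censored runs survive up to the cap).  `S(t) = A exp(-lambda t)` is
  fitted log-linearly over the band `S in [0.01, 0.9]`, which excludes the
  early non-exponential transient and the noisy tail; the band is
  configurable, and the fit grid is truncated at the largest observed FPT
  so a censoring plateau cannot bias the rate.
* **Occupation histograms.**  `f(z)` (centre-of-mass height) and
  `p(theta)` with `theta = arccos|u_z|` folded to `[0, pi/2]` (the axis is
  a director).  Because log-spaced sampling over-weights early times,
  occupancy is accumulated on a separate linear-stride channel (default:
  every 8th step) into fine fixed grids (600 z-bins, 720 theta-bins) that
  are re-binned to the requested resolution; the stride estimate is an
  unbiased fraction-of-time estimator.  For `p(theta)` both the raw
  density and the sine-corrected density (relative to the isotropic
  director measure) are emitted.
* **Entropic force.**  `F_S(z) = d ln f / dz` (proportionality constant 1)
  by central differences at interior bin centres, one-sided at the edges;
  zero interior density is an error rather than silently infinite.

## Problem sizes

The reference conditions are `sigma_x = 0.05`, `L = 15`, and `N = 1000`
repetitions; the published size grid is `l in {0, 0.25, 0.5, 0.75, 1, 3,
5, 7}`, `r in {0.01, 0.02, 0.05, 0.1, 0.15}`.  The test suite and the
acceptance script run representative subsets at `N = 100..1000` with step
caps of 10^6 to 2*10^7, sized so that every quantity being measured is
unaffected by the cap: exponent fits use data up to `t_min` only, medians
are computed with censoring below 10%, and survival fits are truncated at
the largest observed passage.  With the compiled kernel
(~6*10^6 steps/s on one core) the full suite completes in minutes; the
`reproduce` CLI command runs the full-size canned setups.

## Known limitations

* The escape kinetics of long rods are sensitive to how the wall is
  treated where the body overhangs the channel ends, which the model
  leaves under-determined.  With the extrapolated wall the fitted decay
  rate for the `l=7, r=0.05` rod is ~1.7e-6 per step, a factor ~3.6 above
  the published 4.7e-7; the open-reservoir readings overshoot in the
  opposite direction by a larger factor.  Quantities dominated by bulk
  transport (cylinder control, subdiffusive exponents of short particles,
  monotonicity in `r`) are insensitive to this choice.
* The rejection realization of the reflecting boundary couples lateral
  wall collisions to axial motion: a proposal rejected for a lateral
  collision also discards its z-component.  The cylinder-control mean FPT
  is therefore `L^2 / (sigma_x^2 a_T)` with `a_T` the translation
  acceptance rate (~0.916 for `l=0, r=0.01`), about 12% above the naive
  decoupled value `L^2/sigma_x^2`.
* The anomalous exponent from the prescribed window `[0.01 t_min, t_min]`
  inherits the sampling noise of `t_min`; at `N = 200` the location of the
  minimum of `alpha(l)` along the length scan is not stable from seed to
  seed (the profile is flat for `l >= 0.5` within that noise).
* Censored trajectories are handled by right-censoring semantics
  throughout; the model itself has no upper time scale.
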