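# conepore

Brownian dynamics of rigid spherocylindrical particles diffusing through a
narrowing conical channel, with the full analysis toolchain for
quantifying the resulting transport: anomalous-diffusion exponents,
first-passage-time statistics, survival-probability decay, orientation and
position histograms, and entropic-force profiles.

## The problem

Transport of macromolecules through pores of varying cross-section —
membrane channels, nanopore sensors, zeolites — is shaped by confinement:
the narrowing wall removes accessible configurations, producing an
entropic force that pushes particles back toward the wide end.  `conepore`
implements a minimal model of this situation: a single rigid capsule
(cylinder length `l`, cap radius `r`, unit mass) performs a discrete-time
random walk inside a cone of length `L` whose radius falls linearly from
`R0` at the reflecting wide end to `RL` at the absorbing narrow end
(reference geometry `L=15`, `R0=0.5`, `RL=0.25`, noise scale
`sigma_x=0.05`).

Each time step is one translation attempt (isotropic Gaussian displacement
of the centre of mass, s.d. `sigma_x` per component) and one rotation
attempt (uniform random axis `A`, Gaussian angle with s.d.
`sigma_phi = sigma_x (A^T M A)^{-1/2}`, the equipartition coupling through
the capsule's inertia tensor `M`).  Either sub-move is rejected if the
moved body would intersect the wall; rejected steps still advance time.
The first passage time (FPT) is the step at which the centre of mass first
reaches `z >= L`.

The headline observable is the survivor-averaged mean squared displacement
fitted to

    <x^2(t)> = D t^alpha   over   t in [0.01 t_min, t_min],

with `t_min` the FPT of the fastest tracer.  In the cone, `alpha < 1` for
every particle size (effective subdiffusion driven by the entropic force
`F_S(z) ~ d ln f(z)/dz`), whereas the cylindrical control (`R0 = RL`)
recovers normal diffusion, `alpha ~ 1`.

## Worked example

```python
import numpy as np
from conepore import (Channel, Spherocylinder, SimulationConfig, run_ensemble,
                      ensemble_msd, find_tmin, fit_power_law, fpt_median,
                      survival_curve, fit_exponential)

cfg = SimulationConfig(
    channel=Channel(L=15.0, R0=0.5, RL=0.25),
    particle=Spherocylinder(l=0.25, r=0.1),
    n_rep=200, seed=42, max_steps=4_000_000,
)
res = run_ensemble(cfg)

tmin = find_tmin(res)
fit = fit_power_law(ensemble_msd(res), tmin)
print(f"fastest tracer exits at t_min = {tmin} steps")
print(f"MSD ~ D t^alpha over [{fit.window[0]:.0f}, {fit.window[1]:.0f}]: "
      f"D = {fit.D:.3e}, alpha = {fit.alpha:.3f}")
print(f"median first passage time = {fpt_median(res):,.0f} steps")

t_hi = int(res.absorbed_fpts.max())
grid = np.unique(np.logspace(0, np.log10(t_hi), 400).astype(int))
sfit = fit_exponential(survival_curve(res, grid), grid, t_max=t_hi)
print(f"survival S(t) = A exp(-lambda t): A = {sfit.A:.3f}, "
      f"lambda = {sfit.lam:.2e} per step (R^2 = {sfit.r_squared:.3f})")
```

prints

```
fastest tracer exits at t_min = 18566 steps
MSD ~ D t^alpha over [186, 18566]: D = 4.645e-03, alpha = 0.882
median first passage time = 321,812 steps
survival S(t) = A exp(-lambda t): A = 0.929, lambda = 1.94e-06 per step (R^2 = 0.996)
```

`alpha = 0.88 < 1`: the short, thick capsule subdiffuses in the cone.  The
median FPT (3.2e5 steps) characterizes the escape kinetics robustly; the
exponential survival tail (`R^2 = 0.996`) shows the escape rate is
constant, with `lambda ~ 1.9e-6` exits per step.

## Command line

```
conepore simulate config.yaml -o out/      # one ensemble -> CSV tables + manifest
conepore analyze  out/raw -o out2/         # re-analyze saved raw samples
conepore scan     config.yaml -o out/ -l 0,0.25,1 -r 0.01,0.1
conepore reproduce --case cone-rod -o out/ --scale 0.1
```

Configurations are YAML with sections `channel`, `particle`, `noise`,
`run`, `analysis` (see `conepore.io`); every output directory carries a
`manifest.json` with the config echo, seed and SHA-256 checksums, which
suffice to reproduce the run bit-for-bit.

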