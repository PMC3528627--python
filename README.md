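# nhdsim

Brownian dynamics of membrane particles under **non-homogeneous diffusion**
(NHD), with the closed-form theory needed to verify every simulation.

## The scientific problem

Cell-membrane proteins were classically pictured as diffusing freely in a
uniform 2D fluid, which would homogenize their concentration.  Real
membranes are laterally heterogeneous: microdomains ("lipid rafts",
typically cholesterol-rich and more viscous) colocalize with elevated
protein concentration.  This package implements a minimal physical
mechanism for that colocalization: if the diffusion coefficient depends on
position, freely diffusing particles still perform Brownian motion but
spend more time where diffusion is slow, so slow zones overconcentrate at
equilibrium — no binding, fences or traps required.

The model: particles on a periodic membrane ([-L, L) per axis, toric
topology) obey the overdamped multiplicative-noise SDE

    dX = a(X) o dZ        (Stratonovich),   D(x) = a(x)^2,

where a(x) > 0 is the noise amplitude ("diffusion profile").  Key results,
all implemented both as closed forms and as particle experiments:

* **Equilibrium**: rho(x) = Omega / a(x) with
  Omega = [int dx/a]^(-1) — density proportional to the inverse square root
  of diffusivity.  A zone 10x slower in D holds sqrt(10) ≈ 3.16x more
  particles; under the Ito convention the law is rho ~ 1/a^2 and the excess
  is the full ratio.
* **Transients (1D)**: the change of coordinate xt(x) = int_-L^x du/a(u)
  maps the problem onto classical diffusion on a circle, solved by wrapped
  heat kernels; slow zones are transiently *under*populated before filling.
* **FRAP**: the recovery half-time of a bleached zone of half-width r_b
  generalizes from gamma r^2 / D to gamma (int_{-r_b}^{r_b} du/a)^2.
* **Interactions**: adding a 6-12 Lennard-Jones force
  P(r) = eps[(sigma/r)^12 - 2(sigma/r)^6] amplifies the overconcentration —
  slow patches nucleate and retain particle clusters — measured by patch
  concentration folds and by the clustering coefficient
  c = (connected components of the proximity graph) / N.

Integration uses the Milstein scheme for the Stratonovich channel
(X += sqrt(dt) a Z + dt/2 a a' Z^2, applied per axis in 2D), plain Euler
increments for Ito, cell-list Lennard-Jones drift and a hard-core collision
pass for interacting runs (numba-compiled, bit-reproducible per seed).

## Worked example

```python
import numpy as np
from nhdsim import (GaussianWellSpec, make_gaussian_profile, SimConfig,
                    simulate, equilibrium_density, density_histogram,
                    compare_to_theory, overconcentration_ratio)

# a viscosity well: amplitude a(x) = 1 - 0.9 exp(-x^2 / 0.1) on [-1, 1)
profile = make_gaussian_profile(GaussianWellSpec(D0=1, d=0.9, omega=0.1), L=1.0)
print(profile.amplitude(np.array([0.0]))[0])      # 0.1  (10x slower amplitude)
print(overconcentration_ratio(D_slow=0.1, D_fast=1.0))  # 3.162...

cfg = SimConfig(n_particles=20_000, n_steps=1000, dt=0.01, seed=1,
                sample_every=100)
traj = simulate(cfg, profile)                     # ~3 s
est = density_histogram(traj.positions[-1], L=1.0, n_bins=100)
theory = equilibrium_density(profile)             # rho = Omega / a
rep = compare_to_theory(est, theory)
print(round(rep.z_sup, 2))                        # 2.48 — within multinomial noise
```

The simulated histogram's worst bin sits 2.5 standard errors from the
closed form — i.e. the particle ensemble reproduces rho = Omega/a within
counting noise, with the density at the well bottom ~10x the edge value.
Running the same trajectory with `formalism="ito"` instead equilibrates to
rho ~ 1/a^2 (a ~100x peak) and fails this comparison by a wide margin
(z_sup ≈ 38), which is the Stratonovich/Ito contrast the theory predicts.

Ready-made experiment presets (`fig1` ... `fig8`) reproduce the standard
figures end-to-end from the command line:

```bash
nhdsim preset fig1 --out out/fig1 --scale 0.1   # 1D equilibrium + theory table
nhdsim theory --config config.yaml --out out/   # closed-form density grids
```

Each output directory contains the analysis CSVs, the resolved config and a
log with the seed — enough to re-run the experiment exactly.

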