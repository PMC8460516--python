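# pdekit

Mesh-free PDE toolkit in Python: deferred-evaluation field expressions over
scattered particles, DC-PSE and finite-difference derivative operators behind
one contract, a mesh-free pressure-correction driver for steady
incompressible flow, and three benchmark applications:

- **cavity** — steady lid-driven cavity (Navier–Stokes in primitive
  variables, Picard linearization; Stokes limit at Re = 0),
- **active-fluid** — Lagrangian simulation of a 2-d viscous active polar
  fluid (polarity-driven Stokes flow, RK4 polarity update, Euler particle
  advection, operators rebuilt every step),
- **stokes-ball** — Stokes flow in the closed unit ball with
  vector-spherical-harmonic boundary velocity, validated against the
  closed-form interior solution.

## Layout

| module | contents |
| --- | --- |
| `pdekit.geometry` | box/ball domains, particle sets, jittered lattices, spiral sphere sampling, fixed-radius neighbor search |
| `pdekit.dcpse` | DC-PSE operator construction (monomial-exactness contract), finite-difference backend, operator bundles |
| `pdekit.expr` | expression trees over field handles, explicit evaluation, affine-system assembly (`value`/`value_nz`-style dual use) |
| `pdekit.solvers` | linear solves (direct / GMRES), pressure-correction loop with exact discrete projection and Krylov pressure update |
| `pdekit.cavity`, `pdekit.active_fluid`, `pdekit.stokes_ball` | the three applications plus convergence harnesses |
| `pdekit.io`, `pdekit.cli` | legacy-VTK/CSV/JSON output, JSON configs, `pdekit` umbrella command |

## CLI

```sh
pdekit cavity --re 100 --n 81 --backend dcpse --tol 1e-4 --out out/cavity
pdekit active-fluid --n 41 --steps 10 --dt 2e-7 --out out/active
pdekit active-fluid --n 41 --convergence spatial --out out/active
pdekit stokes-ball --h 0.125 --l 2 --m 0 --out out/ball
pdekit selftest
```

Outputs are legacy ASCII VTK point clouds (positions + all fields), CSV
summaries (centerlines, vortex center, error norms), and a JSON run report
(iteration counts, divergence history).

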