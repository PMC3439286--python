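# rdmesim

Stochastic simulation of reaction–diffusion and directed-transport
processes in realistic cell geometries.  `rdmesim` samples trajectories
of the **reaction–diffusion master equation (RDME)** on unstructured
tetrahedral and triangular meshes, which resolve curved inner and outer
boundaries (membranes, branched neurites) far better than Cartesian
lattices.  It is aimed both at modellers — who want to run spatial
stochastic models of, say, Min-protein oscillations in *E. coli* or
motor-driven cargo transport in a neuron — and at method developers,
who get mesh handling, operator assembly and an exact reference solver
for free when prototyping new simulation algorithms.

## The model and the numerics

The domain is discretized into voxels, one per mesh vertex, with voxel
volumes given by the row-lumped P1 finite-element mass matrix.  The
state `x_si` (copies of species `s` in voxel `i`) evolves as a
continuous-time Markov process: reactions fire within voxels with
mass-action propensities (`k x_A x_B / v_i` for a bimolecular channel),
and each molecule jumps between neighbouring voxels with intensity

    q_ij = gamma_s · max(0, −K_ij) / v_i

derived from the finite-element stiffness matrix `K` — the
discretization whose ensemble mean reproduces the macroscopic
diffusion equation.  Membrane-bound species diffuse on the triangulated
surface with the intrinsic (cotangent) operator; motor-driven transport
enters as upwinded advective jump rates built from a velocity field.

Two solvers sample the process:

* **NSM** — the Next Subvolume Method, statistically exact, with a
  compiled (numba) event loop for mass-action models;
* **DFSP** — Diffusive Finite State Projection, an approximate plug-in
  solver that aggregates diffusion over a macro-step `tau_D` using
  precomputed per-voxel transition tables (`tau`, `max_jump`, cache on
  disk), trading a controlled truncation error for speed.

## Worked example: Min oscillations

The MinD/MinE system self-organizes into pole-to-pole oscillations that
position the division site in *E. coli*.  Build a rod-shaped cell,
run the shipped five-species model, and measure the oscillation period
of membrane-bound MinD in one half of the cell:

```python
import numpy as np
from rdmesim import generate_capsule_mesh, simulate_nsm
from rdmesim.models import min_model
from rdmesim.analysis import half_cell_signal, find_oscillation_period, \
    oscillation_coherence

mesh = generate_capsule_mesh(length=4.5, radius=0.5, h=0.3, seed=1)
model = min_model(mesh, tspan=np.arange(0.0, 301.0, 1.0), seed=1)
traj = simulate_nsm(model)

sig = half_cell_signal("MinD_m", mesh)
print("voxels:   ", mesh.n_vertices)
print("period:   ", find_oscillation_period(traj, sig, mesh), "s")
print("coherence:", round(oscillation_coherence(traj, sig, mesh), 2))
```

Output:

```
voxels:    347
period:    43.0 s
coherence: 0.93
```

The period is the FFT power peak of the half-cell membrane-MinD copy
number — about 43 s here, the classic "close to 40 s" pole-to-pole
rhythm; the coherence score (fraction of spectral power in the peak,
1 = pure tone, ~0.01 = noise) says the oscillation is strongly
periodic.  Growing the cell via the `xsep` mesh parameter
(`rdme sweep --xsep 0 --xsep 2 --xsep 4 ...`) shows the oscillation
losing coherence as the cell elongates.

The same model runs from the shell:

```bash
rdme run-min --seed 1 --t-end 300          # writes min_trajectory.h5
rdme run -c config.toml --solver dfsp      # any model, TOML-configured
rdme run-neuron                            # cargo transport example
rdme run-sphere                            # discretization benchmark
```

Other shipped examples: molecular-motor cargo transport in a branched
neuron-like geometry (cargo relocalizes from axon to dendrites when the
kinesin/dynein switching ratio flips mid-run), and surface diffusion to
an absorbing polar cap on a sphere, whose mean absorption time has a
continuum closed form — the package's discretization benchmark
(sub-percent agreement at ~4000 voxels).

See `docs/methods.md` for the numerical details (operator assembly,
negative-rate clamping, DFSP error control, analysis definitions) and
`docs/config.schema.json` for the run-configuration schema.

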