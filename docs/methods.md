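# Methods

This note documents the models, numerical choices and limitations of
`rdmesim`.  It is written for users who need to judge what the package
computes and what its tests do and do not establish.

## The mesoscopic model

The state is the number of molecules of each species in each *voxel* of
an unstructured mesh; its probability law follows the
reaction-diffusion master equation (RDME).  Voxels are mesh *vertices*
(a vertex-centred dual), and the volume of voxel *i* is the entry
`v_i` of the row-lumped P1 finite-element mass matrix — in um^3 for
tetrahedral volume meshes, um^2 for triangulated surfaces, um for 1D
interval fixtures.  Well-mixed reactions fire independently in each
voxel with propensities in molecule-count convention: a bimolecular
channel with rate constant `k` (um^3/s) has per-voxel propensity
`k x_A x_B / v_i`.

Diffusive transport is a continuous-time Markov jump process per
molecule.  Its rates come from the P1 stiffness matrix `K` of the
Laplacian on the same mesh:

    q_ij = gamma * max(0, -K_ij) / v_i,

which is consistent simultaneously with the macroscopic diffusion
equation for ensemble means and with the single-particle Fokker-Planck
density.  Surface diffusion (curved membranes) uses the triangles'
intrinsic in-plane P1 operators (the cotangent formula); no thin-shell
volume approximation is involved.

**Negative-rate clamping.**  On 3D unstructured meshes the stiffness
matrix is not an M-matrix: poor-quality tetrahedra produce positive
off-diagonal entries, i.e. negative rate candidates.  These are clamped
to zero (the chain stays a valid CTMC) and their total magnitude is
reported as `clamped_mass` on the generator.  Clamping locally biases
diffusion; the built-in generators keep the clamped fraction of total
jump intensity in the few-percent range (exactly zero on 1D, structured
box and 2D Delaunay surface meshes, which the tests assert).

**Directed transport.**  A velocity field `v(x)` (um/s) becomes an
upwind edge process: for each stiffness edge (i, j) with unit vector
`u_ij` and weight `w_ij = |K_ij| |x_j - x_i|^2`, the flux
`phi = (v(mid) . u_ij) w_ij` contributes `max(0, phi)/v_i` to the i->j
rate only.  Upwinding guarantees non-negative rates; on
inversion-symmetric stencils the expected drift equals `v` exactly
(the box-mesh test verifies recovery within 5%).  This construction is
validated only through that drift property, not against any external
advection scheme.

## Mesh generation

Built-in generators produce interval chains, structured boxes (six
tetrahedra per cell), icosahedral and Fibonacci sphere surfaces, and
unions of capsule primitives (rod-shaped bacteria; a branched
neuron-like tube fixture).  Capsule unions are meshed by a simplified
isosurface-stuffing scheme: a body-centred-cubic lattice of spacing `h`
with points within `0.3 h` of the implicit surface snapped onto it,
Delaunay triangulated, then filtered by centroid sign.  This was chosen
over Delaunay of independent surface/interior point samples, which
produced sliver tetrahedra whose clamped generators over-estimated
diffusion several-fold.  Disjoint or merely touching bodies are meshed
separately and concatenated, so a translated-capsule union splits into
two components exactly when the implicit solids separate.

Generated surfaces are inscribed polyhedra: enclosed volume converges
from below with facet deficit O(h^2/r^2) (about 5% at h/r = 0.6, below
1% at h/r = 0.2).  Lumped voxel volumes always partition the *meshed*
volume exactly.

## Solvers

**NSM (exact).**  Event queue over voxels keyed by next-event time;
per event the voxel picks reaction vs diffusion proportionally to the
two rate totals, then the channel by linear search; the affected
voxels' totals are updated and pending times are reused by the
next-reaction rescaling `t' = t + (t_old - t) * r_old / r_new` (a fresh
exponential when the old total was zero).  Heap ties break on voxel
index.  Output states are recorded as the state immediately before the
first event past each output time; an event exactly at an output time
is processed after recording.

Two backends sample the same process: a numba-compiled loop for purely
mass-action models (rate prefactors, subdomain masks and per-voxel data
factors folded into dense per-reaction-per-voxel arrays, including an
optional global rate switch at `t_switch`), and a pure-Python loop for
arbitrary propensity callables driven by the declared dependency graph.
The backend is chosen deterministically from the model, and each
backend is bit-reproducible for a fixed seed; the two use different RNG
streams and agree in distribution (KS-tested).  Statistical exactness
is asserted against an independent brute-force direct SSA over the
flattened channel list.

**DFSP (approximate).**  Operator splitting with macro-step `tau_D`:
first all molecules are redistributed by one multinomial draw per
(species, voxel) from precomputed single-molecule transition rows
`p_i = exp(tau_D Q^T) e_i`, then reactions run as independent in-voxel
SSAs for `tau_D` with the spatial state frozen (Lie splitting,
diffusion first, mirroring the plug-in's component ordering; Strang
splitting would be a straightforward extension).  Rows are computed on
the BFS ball of graph radius `max_jump` by uniformization (series
truncated at relative 1e-12 — robust for generator matrices, unlike
scaling-and-squaring on stiff operators, which is used only as the
dense test oracle).  Probability mass escaping the ball is the FSP
truncation error `eps_i`; rows are renormalized by `1/(1 - eps_i)`
(keeping them stochastic, rather than dumping the residual on the
diagonal — the deviation is bounded by `tol`) and the computation
refuses to proceed if any `eps_i > tol`.  Tables are cached on disk
keyed by a hash of (generator, gamma, tau_D, max_jump, tol) and shared
between species with identical bound generators.  Whether reaction
propensities should see intra-step diffusion is a splitting-order
question; equivalence with the exact solver is claimed only in the
`tau_D -> 0` limit, which the convergence tests probe.

## Analysis

Oscillation periods are the inverse frequency of the maximal FFT power
of the mean-subtracted, Hann-windowed region-summed copy-number signal;
resolution is one FFT bin (1/record-length).  The *coherence score* is
the fraction of total f>0 power in the peak bin and its two neighbours
(a Hann window spreads an off-bin tone over ~3 bins): a pure sinusoid
scores near 1, white noise near 3/n_bins (calibrated on noise
ensembles in the tests).  The oscillating/non-oscillating
classification threshold used by the division-site sweep is 0.5:
coherently oscillating cells score above ~0.75 and elongated
non-oscillating ones below ~0.35 in 300 s records, with the noise
baseline near 0.02.  Flat signals return a NaN sentinel rather than an
exception.

## Example models

**Min oscillations.**  The five-species MinD/MinE membrane-cycling
model with cooperative recruitment of cytosolic MinD:ATP by *both*
membrane-bound MinD and the MinDE complex, at the classical
parameterization of Huang, Meir & Wingreen (PNAS 2003):
sigma_d = 0.025 um/s, sigma_dD = 0.0015 um^3/s, sigma_dE = 0.093
um^3/s, sigma_e = 0.7 /s, nucleotide exchange 1 /s, D_cyt = 2.5
um^2/s, D_mem = 0.01 um^2/s, 4500 MinD and 1575 MinE on the 4.5 um x
0.5 um capsule (1000 and 350 per um of cell length).  The fixture file
`min_rates_huang.json` is the single source of these numbers; every
quantitative Min result depends on this transcription.  Membrane
attachment in a membrane voxel uses the propensity
`sigma_d (A_i / v_i) x`, with `A_i` the voxel's lumped membrane area —
the natural vertex-centred realization of a surface reaction rate.
A variant restricting recruitment to membrane MinD only (with the
correspondingly larger published constant) was evaluated and oscillates
coherently but with a ~30 s period; the shipped two-channel Huang form
gives ~43 s on the default capsule, stable across seeds and mesh
resolutions h = 0.2-0.3 um.

**Sphere absorption.**  Surface diffusion on the unit sphere with an
absorbing polar cap is the discretization benchmark: the mesoscopic
mean absorption time has two independent oracles, the exact linear
solve `Q T = -1` on non-absorbing voxels and quadrature of the 1D polar
MFPT ODE.  The cap is realized by relabelling triangles whose centroid
lies inside it; their vertices absorb.  Any vertex-sink realization
carries an O(h) effective-boundary offset, so the relative error falls
with cap size; the default half-angle pi/3 on the ~4343-voxel
Fibonacci sphere gives a deterministic error of ~0.1% (pi/6: ~1%).
The Monte-Carlo ensemble (1e5 molecules, compiled first-passage
sampler) is additionally checked against the linear-solve oracle within
3 standard errors, independently of the continuum form.

**Cargo transport.**  Implicit-motor model: cargo V diffuses, binds as
Vk (kinesin, advected along the field) or Vd (dynein, against it);
switching rates sigma_dk/sigma_kd set the net direction and are swapped
halfway through the run.  The velocity field comes from an
interpolation table over surface-triangle centroids pointing at two
reference points (soma centre; a point beyond the axon terminus),
assigned per subdomain label and queried by nearest neighbour.  Dynein
runs at half the kinesin speed in the axon.  In the dendrites, mixed
fibre polarity is modelled by attenuating the net transport rate of
*both* motors to 1/100 of the axonal kinesin rate; attenuating dynein
alone would let full-speed dendritic kinesin expel cargo faster than
dynein could deliver it, making dendritic accumulation impossible for
any switching ratio.  Absolute rates (creation 5 /um^3/s in the soma,
degradation of unbound cargo 0.1 /s, bind 2 /s, unbind 1 /s, kinesin
1 um/s) are demonstration values chosen so the cargo pool reaches
steady state and completes the axon->dendrite relocalization within
the 1600 s default run; they are not fitted to any neuron.  The
branched mesh is a synthetic look-alike (one soma, one axon, two
dendrites) with no geometric fidelity claim, so localization results
are orderings of region fractions, never geometric quantities.

## Problem sizes and determinism

Default test and example sizes are deliberately modest: the Min capsule
at h = 0.3 um has ~350 voxels (the period is unchanged at h = 0.2 with
~970), the sweep runs 300 s per value, and distributional solver
comparisons use 1-3 x 10^3 replicates of 2-voxel models.  All
randomness flows from explicit integer seeds: mesh jitter, initial
placement and the solvers each take one, and repeated runs are
bit-identical per backend.

## Known limitations

- Clamped negative rates are dropped, not redistributed; `clamped_mass`
  is surfaced so users can judge severity on their meshes.
- The RDME itself loses accuracy for diffusion-limited bimolecular
  reactions as voxels shrink below the reaction radius scale; no
  mesh-dependent rate corrections are applied.
- DFSP output times snap to the macro-step grid (with a warning) when
  `tspan` is finer than `tau_D`.
- The Gmsh reader handles ASCII v2.2 and v4.1 with linear line,
  triangle and tetrahedron elements only; binary files are rejected.
- Propensity callables that read species not declared in `depends_on`
  are undetectable and silently break incremental updates (documented
  contract; the validator smoke-tests propensities at the initial
  state only).
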