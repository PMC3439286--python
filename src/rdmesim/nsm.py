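"""Next Subvolume Method: the exact core solver.

Each voxel carries one entry in an event queue keyed by its next event
time, exponential with rate (total reaction propensity + total diffusion
intensity).  On an event the voxel decides reaction vs diffusion
proportionally to the two totals, picks the specific channel by linear
search, applies it, updates the affected voxels' rates and reuses the
receiver's pending time via the next-reaction-method rescaling.

Two interchangeable backends sample the same process: a compiled
(numba) event loop for purely mass-action models, and a pure-Python loop
supporting arbitrary propensity callables.  The backend is chosen
deterministically from the model, keeping runs reproducible.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ._kernels import nsm_mass_action
from .binding import build_generators, generator_csr_arrays
from .model import (
    MassActionReaction,
    RDMEModel,
    build_dependency_graph,
    validate_model,
)
from .trajectory import Trajectory

__all__ = ["simulate_nsm"]


def simulate_nsm(
    model: RDMEModel,
    generators: dict[str, sp.csr_matrix] | None = None,
    seed: int | None = None,
    force_python: bool = False,
) -> Trajectory:
    """Sample one exact RDME trajectory of ``model`` with the NSM.

    ``generators`` maps species name -> bound (gamma-scaled, restricted)
    sparse jump generator; by default diffusion generators are assembled
    from the mesh.  ``seed`` overrides ``model.seed``.
    """
    validate_model(model)
    if generators is None:
        generators = build_generators(model)
    seed = int(model.seed if seed is None else seed)
    compiled = not force_python and all(
        isinstance(r, MassActionReaction) for r in model.reactions
    )
    if compiled:
        return _simulate_compiled(model, generators, seed)
    return _simulate_python(model, generators, seed)


# ---------------------------------------------------------------------------
# compiled mass-action path
# ---------------------------------------------------------------------------


def mass_action_arrays(model: RDMEModel):
    """Fold rate constants, volumes, data factors and subdomain masks into
    per-reaction per-voxel prefactors for the compiled kernel."""
    M, N = model.n_species, model.n_voxels
    R = len(model.reactions)
    kloc1 = np.zeros((R, N))
    kloc2 = np.zeros((R, N))
    tswitch = np.full(R, np.inf)
    rs1 = np.full(R, -1, dtype=np.int64)
    rs2 = np.full(R, -1, dtype=np.int64)
    rmask = model.reaction_subdomain_mask()
    vols = model.volumes
    for r, reac in enumerate(model.reactions):
        if not isinstance(reac, MassActionReaction):
            raise TypeError("compiled path requires MassActionReaction channels")
        pair = []
        for s, m in reac.reactants.items():
            pair += [model.species_index(s)] * m
        if len(pair) >= 1:
            rs1[r] = pair[0]
        if len(pair) == 2:
            rs2[r] = pair[1]
        order = len(pair)
        base = np.ones(N)
        if order == 0 and reac.per_volume:
            base = vols.copy()
        elif order == 2:
            safe = np.where(vols > 0, vols, np.inf)
            base = 1.0 / safe
            if rs1[r] == rs2[r]:
                base = base / 2.0
        if reac.local_factor is not None:
            base = base * model.data[reac.local_factor]
        base = base * rmask[r]
        kloc1[r] = reac.rate * base
        kloc2[r] = reac.rate_after * base
        tswitch[r] = reac.t_switch
    return kloc1, kloc2, tswitch, rs1, rs2


def _simulate_compiled(model, generators, seed):
    M, N = model.n_species, model.n_voxels
    ptrs = np.zeros((M, N + 1), dtype=np.int64)
    cols, rates = [], []
    qtot = np.zeros((M, N))
    offset = 0
    for m, spc in enumerate(model.species):
        p, c, d, q = generator_csr_arrays(generators[spc.name])
        ptrs[m] = p + offset
        cols.append(c)
        rates.append(d)
        qtot[m] = q
        offset += len(c)
    dcol = np.concatenate(cols) if cols else np.zeros(0, dtype=np.int64)
    drate = np.concatenate(rates) if rates else np.zeros(0)
    kloc1, kloc2, tswitch, rs1, rs2 = mass_action_arrays(model)
    S = model.stoichiometry_matrix()
    sink = (
        np.isin(model.mesh.vertex_subdomain, list(model.sink_subdomains))
        if model.sink_subdomains
        else np.zeros(N, bool)
    ).astype(np.uint8)
    u = model.u0.copy()
    tspan = model.tspan
    states = np.empty((len(tspan), M, N), dtype=np.int64)
    n_reac, n_diff = nsm_mass_action(
        u, tspan, states, ptrs, dcol, drate, qtot, kloc1, kloc2, tswitch,
        rs1, rs2, S, sink, np.uint32(seed % (2**32)),
    )
    return Trajectory(
        times=tspan.copy(),
        states=states,
        species_names=model.species_names,
        seed=seed,
        solver="nsm",
        event_counts={"reaction_events": int(n_reac), "diffusion_events": int(n_diff)},
        volumes=model.volumes,
    )


# ---------------------------------------------------------------------------
# python path (arbitrary propensity callables)
# ---------------------------------------------------------------------------


def _simulate_python(model, generators, seed):
    rng = np.random.default_rng(seed)
    M, N = model.n_species, model.n_voxels
    R = len(model.reactions)
    u = model.u0.astype(np.int64).copy()
    sd = model.mesh.vertex_subdomain
    vols = model.volumes
    S = model.stoichiometry_matrix()
    rmask = model.reaction_subdomain_mask()
    dg = build_dependency_graph(model)
    sink = (
        np.isin(sd, list(model.sink_subdomains)) if model.sink_subdomains else np.zeros(N, bool)
    )

    csr = {}
    qtot = np.zeros((M, N))
    for m, spc in enumerate(model.species):
        p, c, d, q = generator_csr_arrays(generators[spc.name])
        csr[m] = (p, c, d)
        qtot[m] = q

    def prop(r, i, t):
        if not rmask[r, i]:
            return 0.0
        a = model.reactions[r].propensity(
            u[:, i].astype(float), vols[i], int(sd[i]), model.data_vector(i), t
        )
        if a < 0 or not np.isfinite(a):
            raise RuntimeError(
                f"reaction {model.reactions[r].name} returned propensity {a!r} "
                f"in voxel {i} at t={t}; state {u[:, i].tolist()}"
            )
        return a

    t = float(model.tspan[0])
    ar = np.array([[prop(r, i, t) for i in range(N)] for r in range(R)]) if R else np.zeros((0, N))
    a = ar.sum(axis=0) if R else np.zeros(N)
    b = np.einsum("mi,mi->i", u, qtot)

    def draw(rate):
        return rng.exponential(1.0 / rate) if rate > 0 else np.inf

    tnext = t + np.array([draw(a[i] + b[i]) for i in range(N)])
    tspan = model.tspan
    T = len(tspan)
    states = np.empty((T, M, N), dtype=np.int64)
    states[0] = u
    out_ptr = 1
    n_reac = n_diff = 0

    while True:
        i = int(np.argmin(tnext))
        tev = tnext[i]
        while out_ptr < T and tspan[out_ptr] <= tev:
            states[out_ptr] = u
            out_ptr += 1
        if out_ptr >= T or not np.isfinite(tev):
            break
        t = tev
        x = rng.random() * (a[i] + b[i])
        affected_species: list[int] = []
        fired_reaction = -1
        j = -1
        if x < a[i]:
            acc = 0.0
            rsel = R - 1
            for r in range(R):
                acc += ar[r, i]
                if acc > x:
                    rsel = r
                    break
            u[:, i] += S[rsel]
            if u[:, i].min() < 0:
                raise RuntimeError(
                    f"reaction {model.reactions[rsel].name} drove counts negative in voxel {i}"
                )
            fired_reaction = rsel
            n_reac += 1
        else:
            x -= a[i]
            acc = 0.0
            msel = -1
            for m in range(M):
                acc += u[m, i] * qtot[m, i]
                if acc > x:
                    msel = m
                    break
            if msel < 0:
                msel = int(np.argmax(u[:, i] * qtot[:, i]))
            p, c, d = csr[msel]
            y = rng.random() * qtot[msel, i]
            acc = 0.0
            jsel = c[p[i + 1] - 1] if p[i + 1] > p[i] else i
            for k in range(p[i], p[i + 1]):
                acc += d[k]
                if acc > y:
                    jsel = c[k]
                    break
            u[msel, i] -= 1
            if not sink[jsel]:
                u[msel, jsel] += 1
                j = int(jsel)
            affected_species.append(msel)
            n_diff += 1

        # dependency-graph-driven propensity updates
        if fired_reaction >= 0:
            for r in dg.reactions_after_reaction(fired_reaction):
                ar[r, i] = prop(r, i, t)
        else:
            for v in [i] + ([j] if j >= 0 else []):
                for s in affected_species:
                    for r in dg.reactions_after_species(s):
                        ar[r, v] = prop(r, v, t)
        a[i] = ar[:, i].sum() if R else 0.0
        b[i] = float(u[:, i] @ qtot[:, i])
        tnext[i] = t + draw(a[i] + b[i])
        if j >= 0 and j != i:
            old = a[j] + b[j]
            a[j] = ar[:, j].sum() if R else 0.0
            b[j] = float(u[:, j] @ qtot[:, j])
            new = a[j] + b[j]
            if old <= 0 or not np.isfinite(tnext[j]):
                tnext[j] = t + draw(new)
            elif new != old:
                tnext[j] = t + (tnext[j] - t) * old / new

    while out_ptr < T:
        states[out_ptr] = u
        out_ptr += 1
    return Trajectory(
        times=tspan.copy(),
        states=states,
        species_names=model.species_names,
        seed=seed,
        solver="nsm",
        event_counts={"reaction_events": n_reac, "diffusion_events": n_diff},
        volumes=model.volumes,
    )
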