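"""Brute-force direct SSA over the flattened channel list.

Every (reaction, voxel) pair and every single-molecule diffusion edge is
one channel; all propensities are recomputed after every event.  This is
statistically exact and O(channels) per event — usable only on tiny
models, where it serves as the independence oracle for the optimized
solvers.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .binding import build_generators
from .model import RDMEModel
from .trajectory import Trajectory

__all__ = ["ssa_reference"]


def ssa_reference(
    model: RDMEModel,
    generators: dict[str, sp.csr_matrix] | None = None,
    seed: int | None = None,
    max_events: int = 50_000_000,
) -> Trajectory:
    """Direct Gillespie simulation of the full RDME channel list."""
    if generators is None:
        generators = build_generators(model)
    rng = np.random.default_rng(model.seed if seed is None else seed)
    M, N = model.n_species, model.n_voxels
    u = model.u0.copy()
    sd = model.mesh.vertex_subdomain
    vols = model.volumes
    S = model.stoichiometry_matrix()
    rmask = model.reaction_subdomain_mask()
    sink = np.isin(sd, list(model.sink_subdomains)) if model.sink_subdomains else np.zeros(N, bool)

    # flatten diffusion edges: (species, i, j, rate)
    edges = []
    for m, spc in enumerate(model.species):
        Q = generators[spc.name].tocoo()
        for i, j, q in zip(Q.row, Q.col, Q.data):
            if i != j and q > 0:
                edges.append((m, int(i), int(j), float(q)))
    reac_channels = [(r, int(i)) for r in range(len(model.reactions)) for i in np.flatnonzero(rmask[r])]

    tspan = model.tspan
    states = np.empty((len(tspan), M, N), dtype=np.int64)
    out_ptr = 0
    t = float(tspan[0])
    states[0] = u
    out_ptr = 1
    n_reac = n_diff = 0

    for _ in range(max_events):
        a = np.array(
            [
                model.reactions[r].propensity(u[:, i].astype(float), vols[i], int(sd[i]), model.data_vector(i), t)
                for r, i in reac_channels
            ]
        )
        if np.any(a < 0) or not np.all(np.isfinite(a)):
            bad = int(np.flatnonzero((a < 0) | ~np.isfinite(a))[0])
            r, i = reac_channels[bad]
            raise RuntimeError(f"propensity of reaction {model.reactions[r].name} invalid in voxel {i}")
        b = np.array([u[m, i] * q for m, i, j, q in edges])
        total = a.sum() + b.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        while out_ptr < len(tspan) and tspan[out_ptr] < t:
            states[out_ptr] = u
            out_ptr += 1
        if t > tspan[-1]:
            break
        x = rng.random() * total
        if x < a.sum():
            r, i = reac_channels[int(np.searchsorted(np.cumsum(a), x, side="right"))]
            u[:, i] += S[r]
            n_reac += 1
        else:
            x -= a.sum()
            m, i, j, q = edges[int(np.searchsorted(np.cumsum(b), x, side="right"))]
            u[m, i] -= 1
            if not sink[j]:
                u[m, j] += 1
            n_diff += 1
        if u.min() < 0:
            raise RuntimeError("negative copy number — inconsistent stoichiometry")
    while out_ptr < len(tspan):
        states[out_ptr] = u
        out_ptr += 1
    return Trajectory(
        times=tspan.copy(),
        states=states,
        species_names=model.species_names,
        seed=model.seed if seed is None else seed,
        solver="ssa_reference",
        event_counts={"reaction_events": n_reac, "diffusion_events": n_diff},
        volumes=vols,
    )
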