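"""Surface diffusion on a sphere with an absorbing polar cap.

A validation problem with a continuum closed form: molecules diffuse on
the surface of a sphere (radius ``r``) and are absorbed by a circular
patch of half-angle ``cap_half_angle`` around the north pole.  The mean
first-passage time from colatitude theta solves the 1D polar ODE

    (D / sin t) d/dt ( sin t  dT/dt ) = -1,   T(theta_a) = 0, T'(pi) = 0

which this module integrates by quadrature (the continuum oracle); the
mesoscopic mean absorption time is computed exactly by solving the
linear system Q T = -1 on the non-absorbing voxels, and stochastically
by sampling single-molecule first-passage times of the jump process.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.integrate import quad
from scipy.sparse.linalg import spsolve

from .._kernels import first_passage_times
from ..assembly import assemble_fem_operators, jump_rates_from_operators
from ..binding import generator_csr_arrays
from ..mesh import Mesh
from ..model import RDMEModel, Species

__all__ = [
    "SINK",
    "sphere_absorption_model",
    "continuum_absorption_time",
    "mesoscopic_absorption_time",
    "sample_absorption_times",
]

#: subdomain label of the absorbing cap (largest label wins at vertices)
SINK = 9


def _cap_mask(mesh: Mesh, cap_half_angle: float) -> np.ndarray:
    """Vertices incident to a triangle whose centroid lies in the cap."""
    cen = mesh.vertices[mesh.triangles].mean(axis=1)
    r = np.linalg.norm(cen, axis=1)
    theta = np.arccos(np.clip(cen[:, 2] / np.maximum(r, 1e-300), -1, 1))
    sink_tris = theta < cap_half_angle
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    if sink_tris.any():
        mask[np.unique(mesh.triangles[sink_tris])] = True
    return mask


def sphere_absorption_model(
    mesh: Mesh,
    cap_half_angle: float,
    gamma: float = 1.0,
    n_molecules: int = 100_000,
    tspan=None,
    seed: int = 0,
) -> RDMEModel:
    """RDME model of surface diffusion with the polar cap as a sink.

    The sphere mesh must be surface-only; the cap is realized by
    relabelling the triangles whose centroid lies inside it with the
    :data:`SINK` subdomain, whose voxels delete arriving molecules.
    Initial molecules are spread volume-proportionally over the
    non-absorbing voxels.
    """
    if not (0 < cap_half_angle < np.pi / 2):
        raise ValueError("cap half-angle must lie in (0, pi/2)")
    if len(mesh.tetrahedra):
        raise ValueError("expected a surface-only sphere mesh")
    mask = _cap_mask(mesh, cap_half_angle)
    if not mask.any():
        # smallest resolvable cap: smallest triangle-centroid colatitude
        cen = mesh.vertices[mesh.triangles].mean(axis=1)
        tmin = float(
            np.min(np.arccos(np.clip(cen[:, 2] / np.linalg.norm(cen, axis=1), -1, 1)))
        )
        raise ValueError(
            f"cap of half-angle {cap_half_angle:g} contains no voxel; "
            f"minimum resolvable half-angle on this mesh is {tmin:.4f}"
        )
    cen = mesh.vertices[mesh.triangles].mean(axis=1)
    r = np.linalg.norm(cen, axis=1)
    theta = np.arccos(np.clip(cen[:, 2] / np.maximum(r, 1e-300), -1, 1))
    tri_sd = mesh.tri_subdomain.copy()
    tri_sd[theta < cap_half_angle] = SINK
    labelled = Mesh(
        mesh.vertices.copy(), triangles=mesh.triangles.copy(), tri_subdomain=tri_sd
    )

    ops = assemble_fem_operators(labelled, "surface")
    vols = ops.M_lumped
    alive = labelled.vertex_subdomain != SINK
    rng = np.random.default_rng(seed)
    w = np.where(alive, vols, 0.0)
    w = w / w.sum()
    u0 = np.bincount(
        rng.choice(labelled.n_vertices, size=n_molecules, p=w), minlength=labelled.n_vertices
    )[None, :]
    if tspan is None:
        tspan = np.array([0.0, 1.0])
    return RDMEModel(
        mesh=labelled,
        species=[Species("S", gamma, "surface")],
        reactions=[],
        u0=u0,
        tspan=np.asarray(tspan, dtype=float),
        volumes=vols,
        seed=seed,
        sink_subdomains=frozenset({SINK}),
    )


def continuum_absorption_time(cap_half_angle: float, gamma: float, radius: float = 1.0) -> float:
    """Mean absorption time over a uniform start, by numerical quadrature.

    T(theta) = (r^2/D) * int_a^theta (1 + cos p)/sin p dp, averaged over
    the uniform (sin-weighted) start distribution on [a, pi].
    """
    a = cap_half_angle

    def T(theta):
        val, _ = quad(lambda p: (1.0 + np.cos(p)) / np.sin(p), a, theta)
        return val * radius**2 / gamma

    num, _ = quad(lambda th: T(th) * np.sin(th), a, np.pi, limit=200)
    den = 1.0 + np.cos(a)
    return num / den


def mesoscopic_absorption_time(model: RDMEModel) -> float:
    """Exact mesoscopic mean absorption time by solving Q T = -1.

    Averaged over the model's volume-proportional start distribution on
    the non-absorbing voxels.
    """
    gamma = model.species[0].diffusion_const
    ops = assemble_fem_operators(model.mesh, "surface")
    Q = jump_rates_from_operators(ops).scaled(gamma)
    alive = model.mesh.vertex_subdomain != SINK
    idx = np.flatnonzero(alive)
    Qaa = Q[np.ix_(idx, idx)].tocsc()
    T = spsolve(Qaa, -np.ones(len(idx)))
    w = model.volumes[idx]
    return float(np.sum(w * T) / w.sum())


def sample_absorption_times(model: RDMEModel, n: int, seed: int = 0) -> np.ndarray:
    """Monte-Carlo single-molecule absorption times (compiled sampler)."""
    gamma = model.species[0].diffusion_const
    ops = assemble_fem_operators(model.mesh, "surface")
    Q = jump_rates_from_operators(ops).scaled(gamma)
    indptr, indices, rates, qtot = generator_csr_arrays(Q)
    sink = (model.mesh.vertex_subdomain == SINK).astype(np.uint8)
    rng = np.random.default_rng(seed)
    alive = model.mesh.vertex_subdomain != SINK
    w = np.where(alive, model.volumes, 0.0)
    w = w / w.sum()
    starts = rng.choice(model.mesh.n_vertices, size=n, p=w).astype(np.int64)
    return first_passage_times(indptr, indices, rates, qtot, sink, starts, np.uint32(seed % 2**32))
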