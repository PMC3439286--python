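"""Finite-element assembly of per-molecule transport generators.

Mesoscopic diffusion jump rates on an unstructured mesh are obtained from
a linear (P1) finite element discretization of the diffusion equation:
with stiffness matrix ``K`` and row-lumped mass vector ``v`` (the voxel
volumes of the vertex-centred dual), a single molecule in voxel ``i``
jumps to neighbour ``j`` with intensity

    q_ij = max(0, -K_ij) / v_i        (times the species' diffusion
                                       constant gamma, bound later)

which reproduces both the macroscopic mean-field diffusion equation and
the single-particle Fokker-Planck density.  Positive off-diagonal
stiffness entries — produced by poor-quality elements — would yield
negative rates; they are clamped to zero (keeping a valid CTMC) and their
total magnitude is reported as ``clamped_mass``.

Directed (advective) transport from a velocity field uses a pure upwind
edge scheme on the same FEM edge structure, guaranteeing non-negative
rates and recovering the field as the mean drift on symmetric stencils.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import scipy.sparse as sp

from .mesh import Mesh

__all__ = [
    "FemOperators",
    "TransportGenerator",
    "assemble_fem_operators",
    "jump_rates_from_operators",
    "assemble_advection_rates",
    "apply_subdomain_restriction",
]


@dataclass
class FemOperators:
    """P1 stiffness matrix and lumped mass (voxel volumes) of one domain.

    ``M_lumped`` is in um^3 for volume assembly, um^2 for surface assembly
    and um for 1D interval meshes.  For surface operators on a mesh that
    also has a volume part, ``active`` marks the vertices carrying the
    operator; ``M_lumped`` is zero elsewhere.
    """

    K: sp.csr_matrix
    M_lumped: np.ndarray
    domain: str
    active: np.ndarray = field(default=None)  # bool mask, defaults to M_lumped > 0

    def __post_init__(self):
        if self.active is None:
            self.active = self.M_lumped > 0


@dataclass
class TransportGenerator:
    """Sparse CTMC generator of single-molecule jump intensities.

    Off-diagonal ``Q[i, j]`` is the jump intensity i -> j (per unit
    diffusion constant for ``kind='diffusion'``; absolute 1/s for
    ``kind='advection'``); rows sum to zero.
    """

    Q: sp.csr_matrix
    kind: str
    clamped_mass: float = 0.0

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    def scaled(self, gamma: float) -> sp.csr_matrix:
        """Generator bound to a species' diffusion constant."""
        return (self.Q * gamma).tocsr()

    def to_mtx(self, path) -> None:
        from scipy.io import mmwrite

        mmwrite(str(path), self.Q.tocoo())


# ---------------------------------------------------------------------------
# FEM operator assembly
# ---------------------------------------------------------------------------


def assemble_fem_operators(mesh: Mesh, domain: str = "volume") -> FemOperators:
    """Assemble P1 stiffness and lumped mass for ``domain`` ('volume'|'surface').

    'volume' uses the tetrahedra (or the 1D line elements of an interval
    mesh); 'surface' uses the triangles with their intrinsic in-plane
    operators (the cotangent formula), which handles curved membranes.
    """
    n = mesh.n_vertices
    if domain == "volume":
        if len(mesh.tetrahedra):
            rows, cols, vals, mass = _assemble_tets(mesh)
        elif len(mesh.lines):
            rows, cols, vals, mass = _assemble_lines(mesh)
        elif len(mesh.triangles):
            # surface-only mesh: its "volume" operator is the surface one
            rows, cols, vals, mass = _assemble_triangles(mesh)
        else:
            raise ValueError("mesh has no volume (or line) elements")
    elif domain == "surface":
        if not len(mesh.triangles):
            raise ValueError("mesh has no surface triangles")
        rows, cols, vals, mass = _assemble_triangles(mesh)
    else:
        raise ValueError(f"unknown domain {domain!r}")
    K = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    K.sum_duplicates()
    return FemOperators(K=K, M_lumped=mass, domain=domain)


def _assemble_tets(mesh: Mesh):
    tets = mesh.tetrahedra
    v = mesh.vertices[tets]
    B = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]], axis=2)
    vol = np.abs(np.linalg.det(B)) / 6.0
    Binv = np.linalg.inv(B)
    grads = np.empty((len(tets), 4, 3))
    # with B columns the edge vectors, lambda = Binv @ (x - x0), so the
    # gradient of barycentric lambda_i (i=1..3) is the i-th row of Binv
    grads[:, 1:, :] = Binv
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    Kloc = vol[:, None, None] * np.einsum("tad,tbd->tab", grads, grads)
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    mass = np.zeros(mesh.n_vertices)
    np.add.at(mass, tets.ravel(), np.repeat(vol / 4.0, 4))
    return rows, cols, Kloc.ravel(), mass


def _assemble_triangles(mesh: Mesh):
    tris = mesh.triangles
    p = mesh.vertices[tris]
    # in-plane P1 stiffness via the cotangent formula
    area = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    rows_l, cols_l, vals_l = [], [], []
    for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        # angle at vertex a, opposite edge (b, c)
        u = p[:, b] - p[:, a]
        w = p[:, c] - p[:, a]
        cross = np.linalg.norm(np.cross(u, w), axis=1)
        cot = np.einsum("ij,ij->i", u, w) / np.where(cross > 0, cross, 1.0)
        half = -0.5 * cot
        rows_l += [tris[:, b], tris[:, c], tris[:, b], tris[:, c]]
        cols_l += [tris[:, c], tris[:, b], tris[:, b], tris[:, c]]
        vals_l += [half, half, -half, -half]
    rows = np.concatenate(rows_l)
    cols = np.concatenate(cols_l)
    vals = np.concatenate(vals_l)
    mass = np.zeros(mesh.n_vertices)
    np.add.at(mass, tris.ravel(), np.repeat(area / 3.0, 3))
    return rows, cols, vals, mass


def _assemble_lines(mesh: Mesh):
    segs = mesh.lines
    d = mesh.vertices[segs[:, 1]] - mesh.vertices[segs[:, 0]]
    h = np.linalg.norm(d, axis=1)
    k = 1.0 / h
    rows = np.concatenate([segs[:, 0], segs[:, 1], segs[:, 0], segs[:, 1]])
    cols = np.concatenate([segs[:, 1], segs[:, 0], segs[:, 0], segs[:, 1]])
    vals = np.concatenate([-k, -k, k, k])
    mass = np.zeros(mesh.n_vertices)
    np.add.at(mass, segs.ravel(), np.repeat(h / 2.0, 2))
    return rows, cols, vals, mass


# ---------------------------------------------------------------------------
# jump-rate generators
# ---------------------------------------------------------------------------


def jump_rates_from_operators(ops: FemOperators) -> TransportGenerator:
    """Diffusion jump intensities q_ij = max(0, -K_ij)/v_i (unit gamma)."""
    K = ops.K.tocoo()
    off = K.row != K.col
    rows, cols, vals = K.row[off], K.col[off], K.data[off]
    cand = -vals  # rate candidates
    clamped = float(np.sum(np.where(cand < 0, -cand, 0.0) / np.where(ops.M_lumped[rows] > 0, ops.M_lumped[rows], 1.0)))
    rates = np.maximum(cand, 0.0)
    vi = ops.M_lumped[rows]
    ok = vi > 0
    rates = np.where(ok, rates / np.where(ok, vi, 1.0), 0.0)
    keep = rates > 0
    Q = sp.coo_matrix((rates[keep], (rows[keep], cols[keep])), shape=K.shape).tocsr()
    Q = _set_diagonal(Q)
    return TransportGenerator(Q=Q, kind="diffusion", clamped_mass=clamped)


def _set_diagonal(Q: sp.csr_matrix) -> sp.csr_matrix:
    Q = Q.tolil()
    Q.setdiag(0.0)
    Q = Q.tocsr()
    diag = -np.asarray(Q.sum(axis=1)).ravel()
    return (Q + sp.diags(diag)).tocsr()


def assemble_advection_rates(
    mesh: Mesh, velocity_field: Callable[[np.ndarray], np.ndarray], domain: str = "volume"
) -> TransportGenerator:
    """Upwind advection generator from a velocity field (um/s).

    For each FEM edge (i, j) with midpoint velocity v, the signed flux is
    ``phi_ij = (v . u_ij) * w_ij`` with unit edge vector ``u_ij`` and edge
    weight ``w_ij = |K_ij| * |x_j - x_i|^2``; only the upwind direction
    gets a positive rate ``max(0, phi_ij)/v_i``.
    """
    ops = assemble_fem_operators(mesh, domain)
    K = sp.triu(ops.K.tocoo(), k=1).tocoo()
    i, j, kij = K.row, K.col, K.data
    keep = np.abs(kij) > 1e-14
    i, j, kij = i[keep], j[keep], kij[keep]
    xi = mesh.vertices[i]
    xj = mesh.vertices[j]
    dx = xj - xi
    dist = np.linalg.norm(dx, axis=1)
    mid = 0.5 * (xi + xj)
    vel = np.asarray([np.asarray(velocity_field(m), dtype=float) for m in mid])
    if not np.all(np.isfinite(vel)):
        bad = int(np.where(~np.all(np.isfinite(vel), axis=1))[0][0])
        raise ValueError(f"velocity field is not finite near vertex {int(i[bad])}")
    w = np.abs(kij) * dist**2
    phi = np.einsum("ij,ij->i", vel, dx / dist[:, None]) * w
    vols = ops.M_lumped
    fwd = phi > 0
    bwd = phi < 0
    rows = np.concatenate([i[fwd], j[bwd]])
    cols = np.concatenate([j[fwd], i[bwd]])
    rates = np.concatenate([phi[fwd] / vols[i[fwd]], -phi[bwd] / vols[j[bwd]]])
    Q = sp.coo_matrix((rates, (rows, cols)), shape=ops.K.shape).tocsr()
    Q = _set_diagonal(Q)
    return TransportGenerator(Q=Q, kind="advection", clamped_mass=0.0)


def apply_subdomain_restriction(
    gen: TransportGenerator, sd: np.ndarray, allowed: Iterable[int]
) -> TransportGenerator:
    """Restrict jumps to voxels whose label is in ``allowed``.

    Rows and columns of disallowed voxels are zeroed and the diagonal is
    recomputed: molecules outside the allowed region become immobile
    rather than erroneous.
    """
    allowed = set(int(a) for a in allowed)
    if not allowed:
        raise ValueError("allowed label set must be non-empty")
    sd = np.asarray(sd)
    if not allowed & set(np.unique(sd).tolist()):
        raise ValueError(f"allowed labels {sorted(allowed)} not present in mesh labels")
    mask = np.isin(sd, list(allowed))
    d = sp.diags(mask.astype(float))
    Q = (d @ gen.Q @ d).tocsr()
    Q = _set_diagonal(Q)
    return TransportGenerator(Q=Q, kind=gen.kind, clamped_mass=gen.clamped_mass)
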