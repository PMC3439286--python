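"""Diffusive Finite State Projection (DFSP) plug-in solver.

DFSP aggregates the many fast diffusion events of a macro time-step
``tau_D``: for every voxel the probability distribution of a single
molecule after ``tau_D`` is precomputed (restricted to a graph ball of
radius ``max_jump``, the finite state projection), and each step
redistributes the molecules of every voxel with one multinomial draw
from that row, followed by an in-voxel SSA for the reactions over the
same interval (Lie splitting, diffusion first).

The probability mass escaping the truncated ball, ``eps_i``, is the FSP
truncation error; rows are renormalized by ``1/(1 - eps_i)`` and the
computation refuses to proceed when any ``eps_i`` exceeds ``tol``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .assembly import TransportGenerator
from .binding import build_generators
from .model import RDMEModel, validate_model
from .trajectory import Trajectory

__all__ = ["DFSPTable", "compute_dfsp_table", "build_dfsp_tables", "simulate_dfsp", "DFSPTruncationError"]


class DFSPTruncationError(RuntimeError):
    pass


@dataclass
class DFSPTable:
    """Per-voxel single-molecule transition probabilities over one step."""

    tau_D: float
    max_jump: int
    rows: sp.csr_matrix  # (N, N): rows[i, j] = P(molecule in i ends in j)
    fsp_error: np.ndarray  # (N,) truncation mass per voxel (pre-renormalization)
    cache_key: str

    @property
    def n(self) -> int:
        return self.rows.shape[0]


def _cache_key(Q: sp.csr_matrix, gamma, tau_D, max_jump, tol) -> str:
    hsh = hashlib.sha256()
    Q = Q.tocsr()
    hsh.update(Q.indptr.tobytes())
    hsh.update(Q.indices.tobytes())
    hsh.update(Q.data.tobytes())
    hsh.update(np.array([gamma, tau_D, float(max_jump), tol]).tobytes())
    return hsh.hexdigest()[:24]


def _uniformized_exp_column(QT_ball: sp.csr_matrix, i_local: int, tau: float, rtol=1e-12):
    """exp(tau * Q_ball^T) e_i by uniformization (robust for generators)."""
    n = QT_ball.shape[0]
    lam = float(np.max(-QT_ball.diagonal())) if n else 0.0
    v = np.zeros(n)
    v[i_local] = 1.0
    if lam <= 0:
        return v
    P = sp.identity(n, format="csr") + QT_ball / lam
    mu = lam * tau
    # Poisson weights via stable recursion
    w = np.exp(-mu)
    out = w * v
    acc = w
    k = 0
    kmax = int(mu + 12 * np.sqrt(mu + 1) + 50)
    while acc < 1.0 - rtol and k < kmax:
        k += 1
        v = P @ v
        w = w * mu / k
        out = out + w * v
        acc += w
    return out


def compute_dfsp_table(
    generator: TransportGenerator | sp.csr_matrix,
    gamma: float,
    tau_D: float,
    max_jump: int,
    tol: float = 1e-3,
    cache_dir: str | Path | None = None,
) -> DFSPTable:
    """Single-molecule transition table exp(tau_D * gamma * Q) row by row.

    Each row ``i`` is computed on the BFS ball of graph radius
    ``max_jump`` around ``i``; outflow past the ball is lost (FSP), and
    the loss ``eps_i`` must stay below ``tol``.  Tables are cached to
    ``cache_dir`` keyed by (generator, gamma, tau_D, max_jump, tol).
    """
    if tau_D <= 0:
        raise ValueError("tau_D must be positive")
    if max_jump < 1:
        raise ValueError("max_jump must be >= 1")
    Q = generator.Q if isinstance(generator, TransportGenerator) else generator
    Q = (Q * gamma).tocsr()
    key = _cache_key(Q, gamma, tau_D, max_jump, tol)
    if cache_dir is not None:
        path = Path(cache_dir) / f"dfsp_{key}.npz"
        if path.exists():
            z = np.load(path)
            rows = sp.csr_matrix((z["data"], z["indices"], z["indptr"]), shape=tuple(z["shape"]))
            return DFSPTable(tau_D, max_jump, rows, z["fsp_error"], key)

    n = Q.shape[0]
    pattern = Q.copy()
    pattern.data = np.abs(pattern.data)
    adj = ((pattern + pattern.T) > 0).astype(np.int8).tocsr()

    indptr = [0]
    indices: list[np.ndarray] = []
    data: list[np.ndarray] = []
    eps = np.zeros(n)
    worst = (0.0, -1)
    for i in range(n):
        ball = _bfs_ball(adj, i, max_jump)
        sub = Q[np.ix_(ball, ball)].tocsr()
        i_local = int(np.searchsorted(ball, i))
        p = _uniformized_exp_column(sub.T.tocsr(), i_local, tau_D)
        p = np.maximum(p, 0.0)
        e = 1.0 - p.sum()
        eps[i] = max(e, 0.0)
        if eps[i] > worst[0]:
            worst = (eps[i], i)
        if eps[i] > tol:
            raise DFSPTruncationError(
                f"FSP truncation error {eps[i]:.3g} > tol {tol:.3g} in voxel {i}; "
                "increase max_jump or decrease tau_D"
            )
        p = p / p.sum()
        nz = p > 0
        indices.append(ball[nz])
        data.append(p[nz])
        indptr.append(indptr[-1] + int(nz.sum()))
    rows = sp.csr_matrix(
        (np.concatenate(data), np.concatenate(indices), np.array(indptr)), shape=(n, n)
    )
    table = DFSPTable(tau_D, max_jump, rows, eps, key)
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        np.savez(
            Path(cache_dir) / f"dfsp_{key}.npz",
            data=rows.data, indices=rows.indices, indptr=rows.indptr,
            shape=np.array(rows.shape), fsp_error=eps,
        )
    return table


def _bfs_ball(adj: sp.csr_matrix, i: int, radius: int) -> np.ndarray:
    seen = {i}
    frontier = [i]
    for _ in range(radius):
        nxt = []
        for v in frontier:
            for w in adj.indices[adj.indptr[v] : adj.indptr[v + 1]]:
                if w not in seen:
                    seen.add(int(w))
                    nxt.append(int(w))
        frontier = nxt
        if not frontier:
            break
    return np.array(sorted(seen), dtype=np.int64)


def build_dfsp_tables(
    model: RDMEModel,
    generators: dict[str, sp.csr_matrix],
    tau_D: float,
    max_jump: int,
    tol: float = 1e-3,
    cache_dir=None,
) -> dict[str, DFSPTable]:
    """One table per species; identical generators share one computation."""
    tables: dict[str, DFSPTable] = {}
    by_key: dict[str, DFSPTable] = {}
    for spc in model.species:
        Q = generators[spc.name]
        if Q.nnz == 0:
            continue
        key = _cache_key(Q.tocsr(), 1.0, tau_D, max_jump, tol)
        if key not in by_key:
            by_key[key] = compute_dfsp_table(Q, 1.0, tau_D, max_jump, tol, cache_dir)
        tables[spc.name] = by_key[key]
    return tables


def simulate_dfsp(
    model: RDMEModel,
    generators: dict[str, sp.csr_matrix] | None = None,
    tables: dict[str, DFSPTable] | None = None,
    seed: int | None = None,
    tau_D: float = 0.1,
    max_jump: int = 10,
    tol: float = 1e-3,
    cache_dir=None,
) -> Trajectory:
    """Approximate RDME trajectory by operator splitting with macro-step tau_D.

    Each step redistributes molecules by multinomial draws from the DFSP
    table rows (exact conservation), then runs an in-voxel SSA for the
    reactions over tau_D with the spatial state frozen.
    """
    import warnings as _warnings

    validate_model(model)
    if generators is None:
        generators = build_generators(model)
    if tables is None:
        tables = build_dfsp_tables(model, generators, tau_D, max_jump, tol, cache_dir)
    taus = {t.tau_D for t in tables.values()}
    if len(taus) > 1:
        raise ValueError("all species tables must share one tau_D")
    if tables:
        tau_D = taus.pop()
    if len(model.tspan) > 1 and np.min(np.diff(model.tspan)) < tau_D - 1e-12:
        _warnings.warn("tspan finer than tau_D: outputs snap to the macro-step grid")

    rng = np.random.default_rng(int(model.seed if seed is None else seed))
    M, N = model.n_species, model.n_voxels
    u = model.u0.copy()
    sd = model.mesh.vertex_subdomain
    vols = model.volumes
    S = model.stoichiometry_matrix()
    rmask = model.reaction_subdomain_mask()
    R = len(model.reactions)
    sink = (
        np.isin(sd, list(model.sink_subdomains)) if model.sink_subdomains else np.zeros(N, bool)
    )
    reac_voxels = np.flatnonzero(rmask.any(axis=0)) if R else np.array([], dtype=int)

    tspan = model.tspan
    T = len(tspan)
    states = np.empty((T, M, N), dtype=np.int64)
    states[0] = u
    out_ptr = 1
    t = float(tspan[0])
    t_end = float(tspan[-1])
    n_reac = 0
    n_diff = 0

    while t < t_end - 1e-12:
        # (1) diffusion: multinomial redistribution per species and voxel
        for m, spc in enumerate(model.species):
            tab = tables.get(spc.name)
            if tab is None:
                continue
            rows = tab.rows
            newu = np.zeros(N, dtype=np.int64)
            occupied = np.flatnonzero(u[m])
            for i in occupied:
                nmol = int(u[m, i])
                lo, hi = rows.indptr[i], rows.indptr[i + 1]
                probs = rows.data[lo:hi]
                targets = rows.indices[lo:hi]
                if len(probs) == 0:
                    newu[i] += nmol
                    continue
                draw = rng.multinomial(nmol, probs / probs.sum())
                np.add.at(newu, targets, draw)
                n_diff += nmol
            u[m] = newu
            if sink.any():
                u[m, sink] = 0
        # (2) reactions: independent in-voxel SSA for tau_D
        if R:
            for i in reac_voxels:
                n_reac += _voxel_ssa(model, u, i, t, tau_D, S, rmask, vols, sd, rng)
        t += tau_D
        while out_ptr < T and tspan[out_ptr] <= t + 1e-12:
            states[out_ptr] = u
            out_ptr += 1
    while out_ptr < T:
        states[out_ptr] = u
        out_ptr += 1
    return Trajectory(
        times=tspan.copy(),
        states=states,
        species_names=model.species_names,
        seed=int(model.seed if seed is None else seed),
        solver="dfsp",
        event_counts={"reaction_events": n_reac, "diffusion_events": n_diff},
        volumes=vols,
    )


def _voxel_ssa(model, u, i, t0, tau, S, rmask, vols, sd, rng) -> int:
    t_loc = 0.0
    fired = 0
    R = len(model.reactions)
    data_i = model.data_vector(i)
    while True:
        a = np.empty(R)
        for r in range(R):
            if rmask[r, i]:
                a[r] = model.reactions[r].propensity(
                    u[:, i].astype(float), vols[i], int(sd[i]), data_i, t0 + t_loc
                )
            else:
                a[r] = 0.0
        tot = a.sum()
        if tot <= 0:
            break
        dt = rng.exponential(1.0 / tot)
        if t_loc + dt > tau:
            break
        t_loc += dt
        r = int(np.searchsorted(np.cumsum(a), rng.random() * tot, side="right"))
        r = min(r, R - 1)
        u[:, i] += S[r]
        fired += 1
    return fired
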