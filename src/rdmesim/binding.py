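"""Bind per-species transport generators to a model.

One unit-diffusion generator is assembled per operator domain (volume /
surface) and shared; each species' generator is that operator scaled by
its diffusion constant and restricted to the species' allowed
subdomains.  Sink subdomains stay reachable as jump *targets* so that
absorbing voxels can delete arriving molecules.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .assembly import (
    TransportGenerator,
    apply_subdomain_restriction,
    assemble_fem_operators,
    jump_rates_from_operators,
)
from .model import RDMEModel

__all__ = ["build_generators", "bound_generator"]


def bound_generator(
    gen: TransportGenerator,
    gamma: float,
    model: RDMEModel,
    allowed: frozenset[int] | None,
) -> sp.csr_matrix:
    """Scale a unit generator by gamma and apply subdomain restriction."""
    if allowed is not None:
        allowed = frozenset(allowed) | model.sink_subdomains
        gen = apply_subdomain_restriction(gen, model.mesh.vertex_subdomain, allowed)
    return gen.scaled(gamma)


def build_generators(model: RDMEModel) -> dict[str, sp.csr_matrix]:
    """Default diffusion generators for every species of the model.

    Returns a dict species name -> gamma-scaled, subdomain-restricted
    sparse generator.  Species with zero diffusion get an empty matrix.
    """
    n = model.n_voxels
    cache: dict[str, TransportGenerator] = {}
    out: dict[str, sp.csr_matrix] = {}
    for spc in model.species:
        if spc.diffusion_const == 0.0:
            out[spc.name] = sp.csr_matrix((n, n))
            continue
        if spc.domain not in cache:
            ops = assemble_fem_operators(model.mesh, spc.domain)
            cache[spc.domain] = jump_rates_from_operators(ops)
        out[spc.name] = bound_generator(
            cache[spc.domain], spc.diffusion_const, model, spc.allowed_subdomains
        )
    return out


def generator_csr_arrays(Q: sp.csr_matrix):
    """Off-diagonal CSR arrays plus per-voxel total outflow rates."""
    Q = Q.tocsr()
    coo = Q.tocoo()
    off = coo.row != coo.col
    A = sp.coo_matrix((coo.data[off], (coo.row[off], coo.col[off])), shape=Q.shape).tocsr()
    A.sum_duplicates()
    qtot = np.asarray(A.sum(axis=1)).ravel()
    return A.indptr.astype(np.int64), A.indices.astype(np.int64), A.data.astype(np.float64), qtot
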