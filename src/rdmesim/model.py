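"""Model container: species, reactions, initial state and output grid.

This is the data contract of the solver layer.  Propensities are
interpreted in *molecule counts*: a propensity receives the per-voxel
count vector together with the voxel volume ``v_i`` so that bimolecular
rates can scale as ``k / v_i`` (the RDME convention).  Mass-action
reactions are best declared through :class:`MassActionReaction`, which
builds the propensity automatically and — because its rate law is fully
described by arrays — lets the solvers run a compiled event loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .mesh import Mesh

__all__ = [
    "Species",
    "Reaction",
    "MassActionReaction",
    "RDMEModel",
    "DependencyGraph",
    "build_dependency_graph",
    "validate_model",
    "ModelValidationError",
]


@dataclass(frozen=True)
class Species:
    """A chemical species with its transport properties.

    ``domain`` selects the transport operator ('volume' or 'surface');
    ``allowed_subdomains`` restricts where the species may live (``None``
    means everywhere the operator is defined).
    """

    name: str
    diffusion_const: float = 0.0  # um^2/s
    domain: str = "volume"
    allowed_subdomains: frozenset[int] | None = None

    def __post_init__(self):
        if not np.isfinite(self.diffusion_const) or self.diffusion_const < 0:
            raise ValueError(f"species {self.name}: diffusion constant must be finite and >= 0")
        if self.domain not in ("volume", "surface"):
            raise ValueError(f"species {self.name}: domain must be 'volume' or 'surface'")


@dataclass
class Reaction:
    """A reaction channel defined by an arbitrary propensity callable.

    ``propensity(x, vol, sd, data, t)`` receives the per-voxel species
    count vector ``x``, the voxel volume, the voxel subdomain label, the
    per-voxel auxiliary data vector and the current time, and must return
    a non-negative rate (1/s).  ``depends_on`` must list every species the
    propensity reads — a propensity silently reading an undeclared species
    is not detectable and breaks the dependency-graph update contract.
    """

    name: str
    propensity: Callable
    stoichiometry: Mapping[str, int]
    depends_on: frozenset[str] | set[str] = field(default_factory=frozenset)
    allowed_subdomains: frozenset[int] | None = None


class MassActionReaction(Reaction):
    """Mass-action channel ``k * prod_j falling(x_j, m_j) / v^(order-1)``.

    Parameters
    ----------
    rate
        Rate constant. Units depend on the order: 1/s for unimolecular,
        um^3/s (count convention) for bimolecular, molecules/s (or
        molecules/um^3/s with ``per_volume=True``) for creation.
    reactants, products
        Species name -> stoichiometric coefficient.
    per_volume
        For zeroth-order channels only: if True the rate is a density
        production rate and is multiplied by the voxel volume.
    rate_after, t_switch
        Optional second rate constant taking effect at ``t >= t_switch``
        (models mid-run parameter switches).
    local_factor
        Optional name of a per-voxel data entry multiplying the rate
        (e.g. a membrane area-to-volume ratio).
    """

    def __init__(
        self,
        name: str,
        rate: float,
        reactants: Mapping[str, int],
        products: Mapping[str, int],
        allowed_subdomains=None,
        per_volume: bool = False,
        rate_after: float | None = None,
        t_switch: float = np.inf,
        local_factor: str | None = None,
        species_order: Sequence[str] | None = None,
    ):
        self.rate = float(rate)
        self.rate_after = float(rate if rate_after is None else rate_after)
        self.t_switch = float(t_switch)
        self.reactants = dict(reactants)
        self.products = dict(products)
        self.per_volume = per_volume
        self.local_factor = local_factor
        order = sum(self.reactants.values())
        if order > 2:
            raise ValueError("mass-action propensities support order <= 2")
        stoich: dict[str, int] = {}
        for s, m in self.reactants.items():
            stoich[s] = stoich.get(s, 0) - m
        for s, m in self.products.items():
            stoich[s] = stoich.get(s, 0) + m
        stoich = {s: c for s, c in stoich.items() if c != 0}
        super().__init__(
            name=name,
            propensity=self._make_propensity(species_order),
            stoichiometry=stoich,
            depends_on=frozenset(self.reactants),
            allowed_subdomains=None if allowed_subdomains is None else frozenset(allowed_subdomains),
        )
        self._species_order = list(species_order) if species_order is not None else None

    def _make_propensity(self, species_order):
        def propensity(x, vol, sd, data, t, _self=self):
            names = _self._species_order
            k = _self.rate if t < _self.t_switch else _self.rate_after
            if _self.local_factor is not None:
                k = k * data[_self.local_factor]
            order = sum(_self.reactants.values())
            if order == 0:
                return k * vol if _self.per_volume else k
            a = k
            for s, m in _self.reactants.items():
                xi = x[names.index(s)]
                a *= xi if m == 1 else xi * (xi - 1) / 2.0
            if order == 2:
                a /= vol
            return a

        return propensity

    def bind_species(self, names: Sequence[str]) -> None:
        self._species_order = list(names)


@dataclass
class RDMEModel:
    """A reaction-diffusion model bound to a mesh.

    ``u0`` is the species-major ``(M_species, N_voxels)`` initial count
    matrix; ``volumes`` the lumped voxel volumes used for propensity
    scaling (um^3, or um^2 / um for surface-only / interval meshes);
    ``tspan`` the increasing output times; ``data`` named per-voxel
    auxiliary vectors available to propensities; ``sink_subdomains``
    labels of absorbing voxels that delete arriving molecules.
    """

    mesh: Mesh
    species: Sequence[Species]
    reactions: Sequence[Reaction]
    u0: np.ndarray
    tspan: np.ndarray
    volumes: np.ndarray | None = None
    data: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0
    sink_subdomains: frozenset[int] = frozenset()

    def __post_init__(self):
        self.u0 = np.asarray(self.u0, dtype=np.int64)
        self.tspan = np.asarray(self.tspan, dtype=float)
        if self.volumes is None:
            from .assembly import assemble_fem_operators

            self.volumes = assemble_fem_operators(self.mesh, "volume").M_lumped
        self.volumes = np.asarray(self.volumes, dtype=float)
        for r in self.reactions:
            if isinstance(r, MassActionReaction):
                r.bind_species(self.species_names)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_voxels(self) -> int:
        return self.mesh.n_vertices

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def stoichiometry_matrix(self) -> np.ndarray:
        """Dense (R, M) integer state-change matrix."""
        S = np.zeros((len(self.reactions), self.n_species), dtype=np.int64)
        for r, reac in enumerate(self.reactions):
            for s, c in reac.stoichiometry.items():
                S[r, self.species_index(s)] = c
        return S

    def reaction_subdomain_mask(self) -> np.ndarray:
        """(R, N) boolean: may reaction r fire in voxel i?"""
        sd = self.mesh.vertex_subdomain
        mask = np.ones((len(self.reactions), self.n_voxels), dtype=bool)
        for r, reac in enumerate(self.reactions):
            if reac.allowed_subdomains is not None:
                mask[r] = np.isin(sd, list(reac.allowed_subdomains))
        return mask

    def species_subdomain_mask(self) -> np.ndarray:
        """(M, N) boolean: may species s occupy voxel i?"""
        sd = self.mesh.vertex_subdomain
        mask = np.ones((self.n_species, self.n_voxels), dtype=bool)
        for m, sp in enumerate(self.species):
            if sp.allowed_subdomains is not None:
                mask[m] = np.isin(sd, list(sp.allowed_subdomains))
            elif sp.domain == "surface":
                mask[m] = self.mesh.surface_mask
        return mask

    def data_vector(self, i: int) -> dict[str, float]:
        return {k: v[i] for k, v in self.data.items()}


@dataclass
class DependencyGraph:
    """Which reaction propensities must be re-evaluated after an event.

    ``G`` is boolean ``(R, M + R)``: column ``s < M`` flags the reactions
    to update after the copy number of species ``s`` changes in a voxel
    (a diffusion event); column ``M + q`` flags the reactions to update
    after reaction ``q`` fires there.
    """

    G: np.ndarray
    n_species: int

    def reactions_after_species(self, s: int) -> np.ndarray:
        return np.flatnonzero(self.G[:, s])

    def reactions_after_reaction(self, q: int) -> np.ndarray:
        return np.flatnonzero(self.G[:, self.n_species + q])


def build_dependency_graph(model: RDMEModel) -> DependencyGraph:
    """Minimal dependency graph from declared ``depends_on`` sets.

    Reaction ``r`` depends on species ``s`` iff ``s`` is in
    ``depends_on(r)``; reaction ``r`` must be updated after reaction ``q``
    iff ``q == r`` or ``q``'s stoichiometry changes a species ``r`` reads.
    """
    M = model.n_species
    R = len(model.reactions)
    G = np.zeros((R, M + R), dtype=bool)
    reads = [set(r.depends_on) for r in model.reactions]
    for r in range(R):
        for s in reads[r]:
            G[r, model.species_index(s)] = True
        G[r, M + r] = True
        for q, reac_q in enumerate(model.reactions):
            if q != r and set(reac_q.stoichiometry) & reads[r]:
                G[r, M + q] = True
    return DependencyGraph(G=G, n_species=M)


class ModelValidationError(ValueError):
    pass


def validate_model(model: RDMEModel) -> list[str]:
    """Check model invariants; return non-fatal warnings, raise on fatal.

    Fatal: shape mismatches, negative initial counts, too-short tspan,
    initial molecules on disallowed voxels, propensities that are negative
    or non-finite at the initial state.
    """
    warnings: list[str] = []
    M, N = model.n_species, model.n_voxels
    if model.u0.shape != (M, N):
        raise ModelValidationError(f"u0 shape {model.u0.shape} != ({M}, {N})")
    if model.u0.min() < 0:
        raise ModelValidationError("u0 contains negative counts")
    if len(model.tspan) < 2 or np.any(np.diff(model.tspan) <= 0):
        raise ModelValidationError("tspan must contain >= 2 strictly increasing times")
    if len(model.volumes) != N:
        raise ModelValidationError("volumes length mismatch")
    names = model.species_names
    if len(set(names)) != len(names):
        raise ModelValidationError("species names must be unique")
    smask = model.species_subdomain_mask()
    for m in range(M):
        bad = np.flatnonzero((model.u0[m] > 0) & ~smask[m])
        if bad.size:
            raise ModelValidationError(
                f"species {names[m]} has initial molecules on disallowed voxel {int(bad[0])}"
            )
        if not smask[m].any():
            raise ModelValidationError(f"species {names[m]}: allowed subdomains empty on this mesh")
    rmask = model.reaction_subdomain_mask()
    sd = model.mesh.vertex_subdomain
    for r, reac in enumerate(model.reactions):
        vox = np.flatnonzero(rmask[r])
        if vox.size == 0:
            warnings.append(f"reaction {reac.name} can never fire (empty subdomain)")
            continue
        i = int(vox[0])
        a = reac.propensity(
            model.u0[:, i].astype(float), float(model.volumes[i]), int(sd[i]),
            model.data_vector(i), float(model.tspan[0]),
        )
        if not np.isfinite(a) or a < 0:
            raise ModelValidationError(
                f"reaction {reac.name}: propensity at the initial state is {a!r}"
            )
    return warnings
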