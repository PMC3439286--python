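"""Motor-driven cargo transport in a branched, neuron-like geometry.

A cargo species V is created in the cell body, diffuses, and binds
reversibly to microtubule filaments with either a kinesin motor (Vk,
moving along the +field direction, anterograde in the axon) or a dynein
motor (Vd, moving against the field).  Motors are modelled implicitly:
bound cargo simply advects with the corresponding velocity field, and
the bound state can switch between the two motors; the ratio
sigma_kd / sigma_dk of the switching rates dictates the direction of net
transport.  Halfway through the simulation the ratio is inverted, which
relocalizes the cargo from the axon terminus to the dendrites.

    (R1)   0   -> V     mu1        cell body only (per volume)
    (R2-5) V  <-> Vk,d  sigma_b / sigma_d
    (R6)   Vd  -> Vk    sigma_dk   (switched with R7 at t_switch)
    (R7)   Vk  -> Vd    sigma_kd
    (R8)   V   -> 0     mu2        everywhere

The shipped geometry is a synthetic branched tube look-alike (one soma,
one axon, two dendrites) built from capsule primitives — a stand-in
making the workflow runnable without external CAD/meshing tools, with no
claim of geometric fidelity to a real neuron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ..assembly import assemble_advection_rates, assemble_fem_operators, jump_rates_from_operators
from ..binding import bound_generator
from ..mesh import CapsuleSegment, Mesh, generate_capsule_union_mesh
from ..model import MassActionReaction, RDMEModel, Species

__all__ = [
    "SOMA",
    "AXON",
    "DENDRITE",
    "TransportParameters",
    "generate_neuron_mesh",
    "reference_point_velocity_field",
    "transport_model",
]

SOMA = 1
AXON = 3
DENDRITE = 4


@dataclass
class TransportParameters:
    """Rates of the implicit-motor cargo model (all >= 0).

    The dynein speed is half the kinesin speed in the axon, and the net
    dynein transport rate in the dendrites is one hundredth of the
    kinesin rate in the axon (mimicking mixed microtubule polarity).
    """

    mu1: float = 5.0  # cargo creation in the soma, molecules/um^3/s
    mu2: float = 0.1  # degradation of unbound cargo, 1/s
    sigma_b: float = 2.0  # binding to a filament, 1/s
    sigma_d: float = 1.0  # unbinding, 1/s
    sigma_kd: float = 0.1  # Vk -> Vd switch, 1/s (pre-switch value)
    sigma_dk: float = 1.0  # Vd -> Vk switch, 1/s (pre-switch value)
    kinesin_speed: float = 1.0  # um/s
    dynein_axon_factor: float = 0.5
    dendrite_attenuation: float = 0.01

    def __post_init__(self):
        for f, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"transport parameter {f} must be >= 0")


def generate_neuron_mesh(h: float = 0.35, seed: int = 0) -> Mesh:
    """Synthetic two-dendrite / one-axon branched geometry (um).

    Boundary triangles inherit the region labels so that soma/axon/
    dendrite structure is available on every voxel.
    """
    segments = [
        CapsuleSegment((0.0, 0.0, 0.0), (0.0, 0.0, 0.0), 1.2, label=SOMA),
        CapsuleSegment((1.0, 0.0, 0.0), (7.0, 0.0, 0.0), 0.55, label=AXON),
        CapsuleSegment((-0.8, 0.8, 0.0), (-3.2, 3.0, 0.0), 0.5, label=DENDRITE),
        CapsuleSegment((-0.8, -0.8, 0.0), (-3.2, -3.0, 0.0), 0.5, label=DENDRITE),
    ]
    return generate_capsule_union_mesh(segments, h, surface_label=None, seed=seed)


def reference_point_velocity_field(mesh: Mesh, reference_points, speed: float = 1.0, labels_for=None):
    """Velocity field from an interpolation table over surface centroids.

    For every surface triangle the table stores the unit vector from the
    triangle centroid towards its assigned reference point, scaled by
    ``speed``; queries are answered by nearest-neighbour lookup in the
    table.  ``labels_for`` optionally maps each reference point to the
    set of surface subdomain labels it serves (a triangle matching no
    set, or when ``labels_for`` is None, uses its nearest reference
    point).  With a reference point near the cell-body centre and one
    beyond the axon terminus this traces the axon/dendrite structure.
    """
    refs = np.atleast_2d(np.asarray(reference_points, dtype=float))
    if refs.size == 0 or refs.shape[1] != 3:
        raise ValueError("need at least one 3D reference point")
    if len(mesh.triangles) == 0:
        raise ValueError("mesh has no surface triangles")
    centroids = mesh.vertices[mesh.triangles].mean(axis=1)
    ref_tree = cKDTree(refs)
    _, nearest = ref_tree.query(centroids)
    if labels_for is not None:
        if len(labels_for) != len(refs):
            raise ValueError("labels_for must match reference_points")
        for k, labs in enumerate(labels_for):
            if labs:
                nearest[np.isin(mesh.tri_subdomain, list(labs))] = k
    dirs = refs[nearest] - centroids
    norm = np.linalg.norm(dirs, axis=1)
    dirs = dirs / np.maximum(norm, 1e-12)[:, None] * speed
    table = cKDTree(centroids)

    def field(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        _, idx = table.query(np.atleast_2d(x))
        v = dirs[idx]
        return v[0] if single else v

    return field


def transport_model(
    mesh: Mesh,
    params: TransportParameters | None = None,
    velocity_field=None,
    tspan: np.ndarray | None = None,
    t_switch: float | None = None,
    D_cargo: float = 0.5,
    seed: int = 0,
) -> tuple[RDMEModel, dict]:
    """Build the cargo model; returns (model, per-species generators).

    ``velocity_field`` defaults to the two-reference-point construction
    (soma centre and a point beyond the axon terminus).  ``t_switch``
    (default: half the simulated time) swaps sigma_kd and sigma_dk.
    """
    params = params or TransportParameters()
    if tspan is None:
        tspan = np.arange(0.0, 1601.0, 2.0)
    tspan = np.asarray(tspan, dtype=float)
    if t_switch is None:
        t_switch = 0.5 * (tspan[0] + tspan[-1])
    labels = set(np.unique(mesh.vertex_subdomain).tolist())
    for lab, what in ((SOMA, "soma"), (AXON, "axon"), (DENDRITE, "dendrite")):
        if lab not in labels:
            raise ValueError(f"mesh has no {what}-labelled voxels")
    if velocity_field is None:
        axon_tip = mesh.vertices[mesh.vertex_subdomain == AXON][:, 0].max()
        velocity_field = reference_point_velocity_field(
            mesh,
            [(0.0, 0.0, 0.0), (axon_tip + 3.0, 0.0, 0.0)],
            speed=1.0,
            labels_for=[{SOMA, DENDRITE}, {AXON}],
        )

    # dynein moves against the field at half the kinesin speed; in the
    # dendrites the mixed fibre polarity attenuates the net transport
    # rate of both motors to `dendrite_attenuation` of the axonal
    # kinesin rate
    vert_tree = cKDTree(mesh.vertices)

    def region_of(x):
        _, i = vert_tree.query(np.atleast_2d(x))
        return mesh.vertex_subdomain[i]

    def _motor_field(x, sign, base_factor):
        x2 = np.atleast_2d(np.asarray(x, dtype=float))
        v = sign * np.atleast_2d(np.asarray(velocity_field(x2)))
        fac = np.where(region_of(x2) == DENDRITE, params.dendrite_attenuation, base_factor)
        out = v * (params.kinesin_speed * fac)[:, None]
        return out[0] if np.asarray(x).ndim == 1 else out

    def kinesin_field(x):
        return _motor_field(x, +1.0, 1.0)

    def dynein_field(x):
        return _motor_field(x, -1.0, params.dynein_axon_factor)

    species = [
        Species("V", D_cargo, "volume"),
        Species("Vk", 0.0, "volume"),
        Species("Vd", 0.0, "volume"),
    ]
    soma = frozenset({SOMA})
    reactions = [
        MassActionReaction("create", params.mu1, {}, {"V": 1}, allowed_subdomains=soma, per_volume=True),
        MassActionReaction("bind_k", params.sigma_b, {"V": 1}, {"Vk": 1}),
        MassActionReaction("unbind_k", params.sigma_d, {"Vk": 1}, {"V": 1}),
        MassActionReaction("bind_d", params.sigma_b, {"V": 1}, {"Vd": 1}),
        MassActionReaction("unbind_d", params.sigma_d, {"Vd": 1}, {"V": 1}),
        MassActionReaction(
            "switch_dk", params.sigma_dk, {"Vd": 1}, {"Vk": 1},
            rate_after=params.sigma_kd, t_switch=t_switch,
        ),
        MassActionReaction(
            "switch_kd", params.sigma_kd, {"Vk": 1}, {"Vd": 1},
            rate_after=params.sigma_dk, t_switch=t_switch,
        ),
        MassActionReaction("degrade", params.mu2, {"V": 1}, {}),
    ]
    model = RDMEModel(
        mesh=mesh,
        species=species,
        reactions=reactions,
        u0=np.zeros((3, mesh.n_vertices), dtype=np.int64),
        tspan=tspan,
        seed=seed,
    )
    diff = jump_rates_from_operators(assemble_fem_operators(mesh, "volume"))
    generators = {
        "V": bound_generator(diff, D_cargo, model, None),
        "Vk": assemble_advection_rates(mesh, kinesin_field).Q.tocsr(),
        "Vd": assemble_advection_rates(mesh, dynein_field).Q.tocsr(),
    }
    return model, generators
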