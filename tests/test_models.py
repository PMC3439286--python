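"""Shipped example models: Min system, sphere absorption, cargo transport."""

import numpy as np
import pytest

from rdmesim.mesh import (
    generate_capsule_mesh,
    generate_fibonacci_sphere_surface,
    generate_icosphere_surface,
    generate_interval_mesh,
)
from rdmesim.model import validate_model
from rdmesim.models.minsystem import MinParameters, min_model
from rdmesim.models.sphere import (
    SINK,
    continuum_absorption_time,
    mesoscopic_absorption_time,
    sphere_absorption_model,
)
from rdmesim.models.transport import (
    AXON,
    DENDRITE,
    SOMA,
    TransportParameters,
    generate_neuron_mesh,
    reference_point_velocity_field,
    transport_model,
)


@pytest.fixture(scope="module")
def capsule():
    return generate_capsule_mesh(4.5, 0.5, 0.3, seed=1)


class TestMinModel:
    def test_valid_and_conserves_family_totals(self, capsule):
        model = min_model(capsule, seed=1)
        assert validate_model(model) == []
        params = MinParameters.from_fixture()
        # stoichiometry conserves MinD family and MinE family exactly
        S = model.stoichiometry_matrix()
        names = model.species_names
        d_family = [names.index(n) for n in ("MinD_c_atp", "MinD_c_adp", "MinD_m", "MinDE")]
        e_family = [names.index(n) for n in ("MinE", "MinDE")]
        assert (S[:, d_family].sum(axis=1) == 0).all()
        assert (S[:, e_family].sum(axis=1) == 0).all()
        assert model.u0.sum() == params.n_mind + params.n_mine

    def test_membrane_species_restricted(self, capsule):
        model = min_model(capsule, seed=1)
        smask = model.species_subdomain_mask()
        m = model.species_index("MinD_m")
        assert (smask[m] == (capsule.vertex_subdomain == 2)).all()
        assert (model.u0[m] == 0).all()  # starts cytosolic

    def test_requires_membrane_label(self):
        mesh = generate_interval_mesh(5, 1.0)
        with pytest.raises(ValueError):
            min_model(mesh)

    def test_initial_placement_seeded(self, capsule):
        a = min_model(capsule, seed=5).u0
        b = min_model(capsule, seed=5).u0
        c = min_model(capsule, seed=6).u0
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestSphereAbsorption:
    def test_continuum_matches_closed_form(self):
        # T(theta) = (2 r^2 / D) ln(sin(theta/2)/sin(a/2)), averaged
        from scipy.integrate import quad

        a, D = np.pi / 4, 2.0
        num, _ = quad(lambda th: 2 * np.log(np.sin(th / 2) / np.sin(a / 2)) * np.sin(th), a, np.pi)
        closed = num / (1 + np.cos(a)) / D
        assert np.isclose(continuum_absorption_time(a, D), closed, rtol=1e-8)

    def test_gamma_doubling_halves_both_oracles(self):
        mesh = generate_icosphere_surface(3, 1.0)
        cap = np.pi / 3
        m1 = sphere_absorption_model(mesh, cap, gamma=1.0, n_molecules=10)
        m2 = sphere_absorption_model(mesh, cap, gamma=2.0, n_molecules=10)
        assert np.isclose(mesoscopic_absorption_time(m1), 2 * mesoscopic_absorption_time(m2))
        assert np.isclose(
            continuum_absorption_time(cap, 1.0), 2 * continuum_absorption_time(cap, 2.0)
        )

    def test_mesoscopic_matches_continuum_at_resolved_cap(self):
        """Boundary-offset error shrinks when the cap is well resolved:
        ~0.1% at cap pi/3 on the 4343-voxel sphere, a few percent for the
        extreme hemisphere cap on the coarser icosphere."""
        mesh = generate_fibonacci_sphere_surface(4343)
        cap = np.pi / 3
        meso = mesoscopic_absorption_time(sphere_absorption_model(mesh, cap, 1.0, 10))
        cont = continuum_absorption_time(cap, 1.0)
        assert abs(meso - cont) / cont < 0.01
        ico = generate_icosphere_surface(4, 1.0)
        hemi = np.pi / 2 - 1e-9
        meso_h = mesoscopic_absorption_time(sphere_absorption_model(ico, hemi, 1.0, 10))
        cont_h = continuum_absorption_time(hemi, 1.0)
        assert abs(meso_h - cont_h) / cont_h < 0.05

    def test_unresolvable_cap_reports_minimum_angle(self):
        mesh = generate_fibonacci_sphere_surface(500)
        with pytest.raises(ValueError, match="minimum resolvable"):
            sphere_absorption_model(mesh, 1e-4, 1.0, 10)

    def test_sink_vertices_labelled(self):
        mesh = generate_icosphere_surface(3, 1.0)
        model = sphere_absorption_model(mesh, np.pi / 3, 1.0, 100, seed=1)
        sink = model.mesh.vertex_subdomain == SINK
        theta = np.arccos(np.clip(model.mesh.vertices[:, 2], -1, 1))
        assert sink.any()
        assert theta[sink].max() < np.pi / 3 + 0.3  # sink stays near the cap
        assert (model.u0[0, sink] == 0).all()


class TestVelocityField:
    def test_single_far_reference_gives_straight_field(self):
        # straight tube along x, reference far on +x: field ~ +x everywhere
        from rdmesim.mesh import CapsuleSegment, generate_capsule_union_mesh

        tube = generate_capsule_union_mesh(
            [CapsuleSegment((0.5, 0, 0), (7.5, 0, 0), 0.5)], 0.3, seed=0
        )
        field = reference_point_velocity_field(tube, [(100.0, 0.0, 0.0)])
        pts = tube.vertices[(tube.vertices[:, 0] > 1.5) & (tube.vertices[:, 0] < 6.5)]
        v = field(pts)
        cosang = v[:, 0] / np.linalg.norm(v, axis=1)
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))).mean() < 15.0

    def test_two_antipodal_references_flip_at_midplane(self):
        from rdmesim.mesh import CapsuleSegment, generate_capsule_union_mesh

        tube = generate_capsule_union_mesh(
            [CapsuleSegment((-3.5, 0, 0), (3.5, 0, 0), 0.5)], 0.3, seed=0
        )
        field = reference_point_velocity_field(tube, [(-100, 0, 0), (100, 0, 0)])
        left = field(np.array([-2.0, 0.0, 0.0]))
        right = field(np.array([2.0, 0.0, 0.0]))
        assert left[0] < 0 < right[0]

    def test_empty_reference_list_rejected(self, capsule):
        with pytest.raises(ValueError):
            reference_point_velocity_field(capsule, [])


class TestTransportModel:
    def test_neuron_mesh_has_all_regions(self):
        mesh = generate_neuron_mesh(h=0.45, seed=0)
        labels = set(np.unique(mesh.vertex_subdomain).tolist())
        assert {SOMA, AXON, DENDRITE} <= labels
        assert mesh.connected_components()[0] == 1

    def test_model_validates(self):
        mesh = generate_neuron_mesh(h=0.45, seed=0)
        model, gens = transport_model(mesh, seed=1)
        assert validate_model(model) == []
        assert set(gens) == {"V", "Vk", "Vd"}

    def test_closed_system_conserves_cargo(self):
        from rdmesim.nsm import simulate_nsm

        mesh = generate_neuron_mesh(h=0.45, seed=0)
        params = TransportParameters(mu1=0.0, mu2=0.0)
        model, gens = transport_model(
            mesh, params, tspan=np.arange(0.0, 50.0, 1.0), seed=1
        )
        model.u0[0] = 0
        soma = np.flatnonzero(mesh.vertex_subdomain == SOMA)
        model.u0[0, soma[:10]] = 10
        traj = simulate_nsm(model, gens)
        assert (traj.states.sum(axis=(1, 2)) == 100).all()

    def test_missing_region_rejected(self, capsule):
        with pytest.raises(ValueError, match="axon"):
            transport_model(capsule)

    def test_motor_generators_are_upwind(self):
        mesh = generate_neuron_mesh(h=0.45, seed=0)
        _, gens = transport_model(mesh, seed=1)
        for name in ("Vk", "Vd"):
            Q = gens[name].tocoo()
            off = Q.row != Q.col
            assert Q.data[off].min() >= 0
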