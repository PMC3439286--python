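"""FEM operators, diffusion jump rates and advection generators."""

import numpy as np
import pytest
import scipy.sparse as sp

from rdmesim.assembly import (
    apply_subdomain_restriction,
    assemble_advection_rates,
    assemble_fem_operators,
    jump_rates_from_operators,
)
from rdmesim.mesh import (
    generate_box_mesh,
    generate_capsule_mesh,
    generate_icosphere_surface,
    generate_interval_mesh,
)


class TestFemOperators:
    def test_1d_textbook_operators(self):
        ops = assemble_fem_operators(generate_interval_mesh(3, 2.0))
        np.testing.assert_allclose(
            ops.K.toarray(), [[1, -1, 0], [-1, 2, -1], [0, -1, 1]], atol=1e-12
        )
        np.testing.assert_allclose(ops.M_lumped, [0.5, 1.0, 0.5])

    def test_interval_lumped_volumes(self):
        ops = assemble_fem_operators(generate_interval_mesh(5, 1.0))
        np.testing.assert_allclose(ops.M_lumped, [0.125, 0.25, 0.25, 0.25, 0.125])

    def test_box_mass_partitions_volume(self):
        ops = assemble_fem_operators(generate_box_mesh(3, 3, 3, 1, 1, 1))
        assert np.isclose(ops.M_lumped.sum(), 1.0)
        assert (ops.M_lumped > 0).all()

    def test_surface_mass_equals_facet_area(self):
        mesh = generate_icosphere_surface(3, 1.0)
        ops = assemble_fem_operators(mesh, "surface")
        assert np.isclose(ops.M_lumped.sum(), mesh.tri_areas().sum())

    @pytest.mark.parametrize("builder, domain", [
        (lambda: generate_box_mesh(4, 3, 3, 2, 1, 1), "volume"),
        (lambda: generate_icosphere_surface(2, 1.0), "surface"),
        (lambda: generate_capsule_mesh(4.5, 0.5, 0.3, seed=1), "volume"),
    ])
    def test_stiffness_symmetric_with_null_constant(self, builder, domain):
        ops = assemble_fem_operators(builder(), domain)
        K = ops.K
        assert abs(K - K.T).max() < 1e-10 * max(1.0, abs(K).max())
        assert np.abs(np.asarray(K.sum(axis=1))).max() < 1e-8

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError):
            assemble_fem_operators(generate_interval_mesh(3, 1.0), "surface")


class TestJumpRates:
    def test_1d_uniform_recovers_cartesian_rate(self):
        # interior jump rate D/h^2 with unit diffusion constant
        mesh = generate_interval_mesh(11, 5.0)  # h = 0.5
        gen = jump_rates_from_operators(assemble_fem_operators(mesh))
        Q = gen.Q.toarray()
        assert np.isclose(Q[5, 4], 4.0) and np.isclose(Q[5, 6], 4.0)
        assert gen.clamped_mass == 0.0

    @pytest.mark.parametrize("builder, domain", [
        (lambda: generate_box_mesh(3, 3, 3, 1, 1, 1), "volume"),
        (lambda: generate_icosphere_surface(2, 1.0), "surface"),
        (lambda: generate_interval_mesh(7, 3.0), "volume"),
    ])
    def test_detailed_balance_and_stationarity(self, builder, domain):
        ops = assemble_fem_operators(builder(), domain)
        gen = jump_rates_from_operators(ops)
        assert gen.clamped_mass == 0.0  # 1D / structured / 2D Delaunay quality
        Q = gen.Q.toarray()
        v = ops.M_lumped
        flux = v[:, None] * Q
        np.testing.assert_allclose(flux, flux.T, atol=1e-10)  # detailed balance
        np.testing.assert_allclose(v @ Q, 0.0, atol=1e-8)  # pi ~ volumes
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-10)
        assert (Q - np.diag(np.diag(Q)) >= 0).all()

    def test_two_voxel_stationary_distribution(self):
        # pi Q = 0 with pi ~ volumes, solved by hand: q12/q21 = v2/v1
        ops = assemble_fem_operators(generate_interval_mesh(2, 1.0))
        Q = jump_rates_from_operators(ops).Q.toarray()
        v = ops.M_lumped
        assert np.isclose(v[0] * Q[0, 1], v[1] * Q[1, 0])


class TestAdvection:
    def test_zero_field_gives_zero_generator(self):
        mesh = generate_box_mesh(3, 3, 3, 1, 1, 1)
        gen = assemble_advection_rates(mesh, lambda x: np.zeros(3))
        assert gen.Q.nnz == 0 or abs(gen.Q).max() == 0

    def test_1d_upwind_closed_form(self):
        # uniform +x field, speed c: only forward jumps at rate c/h
        mesh = generate_interval_mesh(11, 10.0)  # h = 1
        c = 2.0
        gen = assemble_advection_rates(mesh, lambda x: np.array([c, 0, 0]))
        Q = gen.Q.toarray()
        for i in range(1, 10):  # interior voxels (boundary has half volume)
            assert np.isclose(Q[i, i + 1], c)
        assert np.allclose(Q[np.tril_indices(11, -1)], 0.0)

    def test_drift_recovery_on_box_interior(self):
        mesh = generate_box_mesh(7, 7, 7, 6, 6, 6)
        vel = np.array([1.0, 0.5, 0.0])
        gen = assemble_advection_rates(mesh, lambda x: vel)
        Q = gen.Q.tocoo()
        drift = np.zeros((mesh.n_vertices, 3))
        dx = mesh.vertices[Q.col] - mesh.vertices[Q.row]
        off = Q.row != Q.col
        np.add.at(drift, Q.row[off], Q.data[off, None] * dx[off])
        interior = np.all((mesh.vertices > 0.5) & (mesh.vertices < 5.5), axis=1)
        err = np.abs(drift[interior] - vel).max()
        assert err < 0.05 * np.linalg.norm(vel)

    def test_nan_velocity_rejected(self):
        mesh = generate_interval_mesh(5, 1.0)
        with pytest.raises(ValueError, match="vertex"):
            assemble_advection_rates(mesh, lambda x: np.array([np.nan, 0, 0]))


class TestSubdomainRestriction:
    def test_allow_all_is_identity(self):
        mesh = generate_capsule_mesh(4.5, 0.5, 0.3, seed=1)
        gen = jump_rates_from_operators(assemble_fem_operators(mesh))
        sd = mesh.vertex_subdomain
        out = apply_subdomain_restriction(gen, sd, set(np.unique(sd)))
        assert abs(out.Q - gen.Q).max() < 1e-12

    def test_membrane_only_restriction(self):
        mesh = generate_capsule_mesh(4.5, 0.5, 0.3, seed=1)
        gen = jump_rates_from_operators(assemble_fem_operators(mesh))
        sd = mesh.vertex_subdomain
        out = apply_subdomain_restriction(gen, sd, {2})
        Q = out.Q.tocoo()
        interior = sd != 2
        off = Q.row != Q.col
        # no jump touches an interior voxel
        assert not interior[Q.row[off]].any()
        assert not interior[Q.col[off]].any()

    def test_single_voxel_immobile(self):
        mesh = generate_interval_mesh(4, 1.0)
        gen = jump_rates_from_operators(assemble_fem_operators(mesh))
        sd = np.array([1, 2, 1, 1])
        out = apply_subdomain_restriction(gen, sd, {2})
        assert abs(out.Q).max() == 0

    def test_disjoint_labels_rejected(self):
        mesh = generate_interval_mesh(4, 1.0)
        gen = jump_rates_from_operators(assemble_fem_operators(mesh))
        with pytest.raises(ValueError):
            apply_subdomain_restriction(gen, np.ones(4, dtype=int), {5})
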