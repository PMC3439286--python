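"""Model container, dependency graph and validation."""

import numpy as np
import pytest

from rdmesim.mesh import generate_capsule_mesh, generate_interval_mesh
from rdmesim.model import (
    MassActionReaction,
    ModelValidationError,
    RDMEModel,
    Reaction,
    Species,
    build_dependency_graph,
    validate_model,
)


def birth_death_model(mesh, **kw):
    species = [Species("X", 1.0)]
    reactions = [
        MassActionReaction("birth", 2.0, {}, {"X": 1}),
        MassActionReaction("death", 1.0, {"X": 1}, {}),
    ]
    u0 = np.zeros((1, mesh.n_vertices), dtype=int)
    return RDMEModel(mesh, species, reactions, u0, np.array([0.0, 1.0]), **kw)


class TestMassAction:
    def test_propensity_scalings(self):
        mesh = generate_interval_mesh(2, 1.0)
        sp = [Species("A", 0.0), Species("B", 0.0)]
        r_uni = MassActionReaction("u", 3.0, {"A": 1}, {})
        r_bi = MassActionReaction("b", 3.0, {"A": 1, "B": 1}, {})
        r_dimer = MassActionReaction("d", 3.0, {"A": 2}, {})
        model = RDMEModel(mesh, sp, [r_uni, r_bi, r_dimer],
                          np.zeros((2, 2), dtype=int), np.array([0.0, 1.0]))
        x = np.array([4.0, 5.0])
        vol = 2.0
        assert r_uni.propensity(x, vol, 1, {}, 0.0) == 3.0 * 4
        assert r_bi.propensity(x, vol, 1, {}, 0.0) == 3.0 * 4 * 5 / vol
        assert r_dimer.propensity(x, vol, 1, {}, 0.0) == 3.0 * 4 * 3 / 2 / vol

    def test_rate_switch_at_t_switch(self):
        mesh = generate_interval_mesh(2, 1.0)
        r = MassActionReaction("s", 1.0, {"A": 1}, {}, rate_after=5.0, t_switch=10.0)
        RDMEModel(mesh, [Species("A", 0.0)], [r], np.zeros((1, 2), int), np.array([0.0, 1.0]))
        x = np.array([2.0])
        assert r.propensity(x, 1.0, 1, {}, 9.9) == 2.0
        assert r.propensity(x, 1.0, 1, {}, 10.0) == 10.0

    def test_stoichiometry_net_change(self):
        r = MassActionReaction("r", 1.0, {"A": 1, "B": 1}, {"B": 2})
        assert r.stoichiometry == {"A": -1, "B": 1}
        assert r.depends_on == frozenset({"A", "B"})

    def test_order_above_two_rejected(self):
        with pytest.raises(ValueError):
            MassActionReaction("x", 1.0, {"A": 2, "B": 1}, {})


class TestDependencyGraph:
    def test_birth_death_graph(self):
        mesh = generate_interval_mesh(2, 1.0)
        model = birth_death_model(mesh)
        g = build_dependency_graph(model)
        # columns: [X, birth, death]
        assert g.G.shape == (2, 3)
        assert list(g.reactions_after_species(0)) == [1]  # only death reads X
        assert g.G[0, 1] and g.G[1, 2]  # self columns
        assert g.G[1, 1]  # birth changes X, death reads X

    def test_disjoint_reactions_do_not_couple(self):
        mesh = generate_interval_mesh(2, 1.0)
        sp = [Species("A", 0.0), Species("B", 0.0)]
        rx = [
            MassActionReaction("dA", 1.0, {"A": 1}, {}),
            MassActionReaction("dB", 1.0, {"B": 1}, {}),
        ]
        model = RDMEModel(mesh, sp, rx, np.zeros((2, 2), int), np.array([0.0, 1.0]))
        g = build_dependency_graph(model)
        # brute-force expectation: reaction r after reaction q iff
        # stoich(q) intersects depends_on(r), plus the diagonal
        M = 2
        for r in range(2):
            for q in range(2):
                expected = (q == r) or bool(
                    set(rx[q].stoichiometry) & set(rx[r].depends_on)
                )
                assert g.G[r, M + q] == expected

    def test_declared_dependencies_drive_species_columns(self):
        mesh = generate_interval_mesh(2, 1.0)
        sp = [Species(n, 0.0) for n in ("V", "Vk", "Vd")]
        rx = [
            MassActionReaction("bind_k", 1.0, {"V": 1}, {"Vk": 1}),
            MassActionReaction("bind_d", 1.0, {"V": 1}, {"Vd": 1}),
            MassActionReaction("switch", 1.0, {"Vk": 1}, {"Vd": 1}),
        ]
        model = RDMEModel(mesh, sp, rx, np.zeros((3, 2), int), np.array([0.0, 1.0]))
        g = build_dependency_graph(model)
        assert set(g.reactions_after_species(model.species_index("V"))) == {0, 1}
        assert set(g.reactions_after_species(model.species_index("Vk"))) == {2}


class TestValidation:
    def test_valid_model_no_violations(self):
        mesh = generate_interval_mesh(3, 1.0)
        assert validate_model(birth_death_model(mesh)) == []

    def test_species_on_disallowed_voxel_fatal(self):
        mesh = generate_capsule_mesh(4.5, 0.5, 0.3, seed=1)
        interior = np.flatnonzero(~mesh.surface_mask)[0]
        u0 = np.zeros((1, mesh.n_vertices), dtype=int)
        u0[0, interior] = 1
        model = RDMEModel(
            mesh, [Species("M", 0.01, "surface", frozenset({2}))], [],
            u0, np.array([0.0, 1.0]),
        )
        with pytest.raises(ModelValidationError, match=str(interior)):
            validate_model(model)

    def test_negative_propensity_fatal_and_names_reaction(self):
        mesh = generate_interval_mesh(2, 1.0)
        bad = Reaction(
            "badone", lambda x, v, sd, d, t: -1.0, {"X": -1}, depends_on={"X"}
        )
        model = RDMEModel(
            mesh, [Species("X", 0.0)], [bad],
            np.ones((1, 2), dtype=int), np.array([0.0, 1.0]),
        )
        with pytest.raises(ModelValidationError, match="badone"):
            validate_model(model)

    def test_negative_u0_fatal(self):
        mesh = generate_interval_mesh(2, 1.0)
        model = birth_death_model(mesh)
        model.u0[0, 0] = -1
        with pytest.raises(ModelValidationError):
            validate_model(model)

    def test_bad_tspan_fatal(self):
        mesh = generate_interval_mesh(2, 1.0)
        model = birth_death_model(mesh)
        model.tspan = np.array([0.0])
        with pytest.raises(ModelValidationError):
            validate_model(model)
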