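"""Mass-action flux, stoichiometry, RHS assembly, conservation, validation."""

import numpy as np
import pytest

from gpersim import (
    DomainError,
    Model,
    RateConstant,
    Reaction,
    Rule,
    Species,
    StructuralError,
    conserved_moieties,
    mass_action_flux,
    ode_rhs,
    stoichiometry_matrix,
    validate_model,
)
from gpersim.synthetic_data import random_network

from conftest import make_reaction


def brute_force_rhs(model, state):
    """Independent oracle: iterate reactions, accumulate ±stoich·flux."""
    dx = np.zeros(model.n_species)
    state_map = {s.id: state[i] for i, s in enumerate(model.species)}
    for rxn in model.reactions:
        fwd = rxn.kf.value
        for sid, coef in rxn.reactants.items():
            fwd *= state_map[sid] ** coef
        rev = 0.0
        if rxn.reversible:
            rev = rxn.kr.value
            for sid, coef in rxn.products.items():
                rev *= state_map[sid] ** coef
        v = fwd - rev
        for sid, coef in rxn.reactants.items():
            dx[model.species_index(sid)] -= coef * v
        for sid, coef in rxn.products.items():
            dx[model.species_index(sid)] += coef * v
    for i, sp in enumerate(model.species):
        if sp.is_boundary:
            dx[i] = 0.0
    return dx


class TestMassActionFlux:
    def test_zero_substrate_gives_zero_flux(self):
        r = make_reaction("r", {"S": 1}, {"P": 1}, 3.7)
        assert mass_action_flux(r, {"S": 0.0, "P": 5.0}) == 0.0

    def test_symmetric_reversible_equilibrium(self):
        # v = k1[Akt][PIP3] - kr1[Aktm] vanishes at unit concentrations
        r = make_reaction("r", {"Akt": 1, "PIP3": 1}, {"Aktm": 1}, 1.0, 1.0)
        assert mass_action_flux(r, {"Akt": 1.0, "PIP3": 1.0, "Aktm": 1.0}) == 0.0

    def test_bimolecular_flux_value(self):
        # v = k2[S][R] = 0.5 * 2 * 3
        r = make_reaction("r", {"S": 1, "R": 1}, {"P": 1}, 0.5)
        assert mass_action_flux(r, {"S": 2.0, "R": 3.0, "P": 0.0}) == pytest.approx(3.0)

    def test_stoichiometric_power(self):
        # 2A -> B: v = k[A]^2
        r = make_reaction("r", {"A": 2}, {"B": 1}, 0.25)
        assert mass_action_flux(r, {"A": 3.0, "B": 0.0}) == pytest.approx(0.25 * 9.0)

    def test_missing_species_raises(self):
        r = make_reaction("r", {"S": 1}, {"P": 1}, 1.0)
        with pytest.raises(StructuralError):
            mass_action_flux(r, {"P": 1.0})

    def test_negative_concentration_raises(self):
        r = make_reaction("r", {"S": 1}, {"P": 1}, 1.0)
        with pytest.raises(DomainError):
            mass_action_flux(r, {"S": -0.1, "P": 0.0})


class TestStoichiometryMatrix:
    def test_single_conversion_column(self, decay_model):
        n = stoichiometry_matrix(decay_model).matrix
        assert n.tolist() == [[-1], [1]]

    def test_binding_column(self, akt_model):
        n = stoichiometry_matrix(akt_model).matrix
        assert n.tolist() == [[-1], [-1], [1]]

    def test_coefficient_two(self):
        m = Model(
            name="dimer",
            species=[Species("A", initial_concentration=1.0), Species("B")],
            reactions=[make_reaction("r", {"A": 2}, {"B": 1}, 0.1)],
        )
        assert stoichiometry_matrix(m).matrix.tolist() == [[-2], [1]]


class TestOdeRhs:
    def test_first_order_derivatives(self):
        m = Model(
            name="m",
            species=[Species("S", initial_concentration=2.0), Species("P")],
            reactions=[make_reaction("r", {"S": 1}, {"P": 1}, 0.5)],
        )
        dx = ode_rhs(m, np.array([2.0, 0.0]))
        assert dx == pytest.approx([-1.0, 1.0])

    def test_all_zero_state_is_stationary(self, cycle_model):
        dx = ode_rhs(cycle_model, np.zeros(3))
        assert np.all(dx == 0)

    def test_boundary_species_frozen(self):
        m = Model(
            name="m",
            species=[Species("S", initial_concentration=1.0, is_boundary=True), Species("P")],
            reactions=[make_reaction("r", {"S": 1}, {"P": 1}, 0.5)],
        )
        dx = ode_rhs(m, np.array([1.0, 0.0]))
        assert dx[0] == 0.0 and dx[1] == pytest.approx(0.5)

    def test_nonfinite_state_raises(self, decay_model):
        with pytest.raises(DomainError):
            ode_rhs(decay_model, np.array([np.nan, 0.0]))

    @pytest.mark.parametrize("seed", range(100))
    def test_oracle_equivalence_random_networks(self, seed):
        """RHS equals the per-reaction accumulation oracle to 1e-12."""
        rng = np.random.default_rng(seed)
        n_sp = int(rng.integers(3, 16))
        n_rx = int(rng.integers(1, 2 * n_sp))
        model, _ = random_network(n_sp, n_rx, frac_reversible=0.4, seed=seed)
        state = rng.uniform(0.0, 3.0, size=n_sp)
        np.testing.assert_allclose(
            ode_rhs(model, state), brute_force_rhs(model, state), atol=1e-12, rtol=1e-12
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_sign_sanity_at_zero_concentration(self, seed):
        """A species at zero concentration cannot be consumed."""
        model, _ = random_network(8, 12, frac_reversible=0.3, seed=seed)
        rng = np.random.default_rng(seed + 1000)
        state = rng.uniform(0.0, 2.0, size=8)
        zero_idx = rng.integers(0, 8, size=3)
        state[zero_idx] = 0.0
        dx = ode_rhs(model, state)
        assert np.all(dx[zero_idx] >= -1e-15)


class TestRules:
    def test_assignment_rule_sets_target_and_freezes_it(self):
        m = Model(
            name="m",
            species=[
                Species("S", initial_concentration=2.0),
                Species("P"),
                Species("total"),
            ],
            reactions=[make_reaction("r", {"S": 1}, {"P": 1}, 0.5)],
            rules=[Rule("ru1", "assignment", "total", "S + P")],
        )
        x = m.apply_assignment_rules(np.array([2.0, 1.0, 0.0]))
        assert x[2] == pytest.approx(3.0)
        assert ode_rhs(m, np.array([2.0, 1.0, 0.0]))[2] == 0.0

    def test_rate_rule_overrides_derivative(self):
        m = Model(
            name="m",
            species=[Species("S", initial_concentration=1.0), Species("D")],
            reactions=[make_reaction("r", {"S": 1}, {"D": 1}, 0.5)],
            rules=[Rule("ru1", "rate", "D", "0.25 * S")],
        )
        dx = ode_rhs(m, np.array([1.0, 0.0]))
        assert dx[1] == pytest.approx(0.25)


class TestConservedMoieties:
    def test_two_state_exchange(self):
        m = Model(
            name="m",
            species=[Species("S", initial_concentration=1.0), Species("P")],
            reactions=[make_reaction("r", {"S": 1}, {"P": 1}, 0.5, 0.1)],
        )
        vecs = conserved_moieties(m)
        assert len(vecs) == 1
        assert vecs[0].tolist() == [1, 1]

    def test_receptor_cycle_total(self, cycle_model):
        vecs = conserved_moieties(cycle_model)
        assert len(vecs) == 1
        assert vecs[0].tolist() == [1, 1, 1]

    @pytest.mark.parametrize("seed", range(20))
    def test_vectors_annihilate_stoichiometry(self, seed):
        model, _ = random_network(10, 14, frac_reversible=0.3, seed=seed)
        n = stoichiometry_matrix(model).matrix
        for c in conserved_moieties(model):
            assert np.all(c @ n == 0)


class TestValidateModel:
    def test_well_formed_model_passes(self, akt_model):
        assert validate_model(akt_model).ok

    def test_unknown_species_reported(self):
        m = Model(
            name="m",
            species=[Species("S", initial_concentration=1.0)],
            reactions=[make_reaction("r", {"S": 1}, {"Ghost": 1}, 0.5)],
        )
        rep = validate_model(m)
        assert not rep.ok and len(rep.structural) == 1

    def test_order_units_mismatch_reported(self):
        rxn = Reaction(
            id="r",
            reactants={"A": 1, "B": 1},
            products={"C": 1},
            kf=RateConstant("r_kf", 0.5, order=1),  # bimolecular needs order 2
        )
        m = Model(
            name="m",
            species=[Species("A"), Species("B"), Species("C")],
            reactions=[rxn],
        )
        rep = validate_model(m)
        assert len(rep.units) == 1

    def test_duplicate_species_rejected_at_construction(self):
        with pytest.raises(StructuralError):
            Model(name="m", species=[Species("S"), Species("S")], reactions=[])

    def test_undeclared_rule_symbol_reported(self):
        m = Model(
            name="m",
            species=[Species("S"), Species("T")],
            reactions=[],
            rules=[Rule("ru", "assignment", "T", "S + Ghost")],
        )
        rep = validate_model(m)
        assert any("Ghost" in msg for msg in rep.structural)
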