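"""Mass-action core: model assembly, rate law, simulation, conserved pools."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catpot import (
    KineticModel,
    ModelStructureError,
    Reaction,
    Species,
    build_model,
    conserved_pools,
    mass_action_rate,
    simulate,
)
from catpot.core import pool_value


def _ab_model(k=1.0, keq=1.0, a0=2.0, b0=0.0):
    return build_model(
        [Species("A", initial_concentration=a0), Species("B", initial_concentration=b0)],
        [Reaction("R", {"A": -1, "B": 1}, k=k, keq=keq)],
    )


class TestBuildModel:
    def test_species_only_model_has_empty_s(self):
        m = build_model([Species("A", initial_concentration=1.0)], [])
        assert m.S.shape == (1, 0)

    def test_single_reversible_reaction_column(self):
        m = _ab_model()
        assert m.S.tolist() == [[-1.0], [1.0]]

    def test_unknown_species_rejected(self):
        with pytest.raises(ModelStructureError, match="unknown species"):
            build_model([Species("A")], [Reaction("R", {"A": -1, "Z": 1})])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ModelStructureError, match="duplicate"):
            build_model([Species("A"), Species("A")], [])
        with pytest.raises(ModelStructureError, match="duplicate"):
            build_model(
                [Species("A"), Species("B")],
                [Reaction("R", {"A": -1, "B": 1}), Reaction("R", {"B": -1, "A": 1})],
            )

    def test_reaction_needs_a_reactant(self):
        with pytest.raises(ModelStructureError, match="no reactant"):
            Reaction("R", {"A": 1})

    def test_stoichiometric_matrix_matches_reactions(self, base_model):
        for j, r in enumerate(base_model.reactions):
            col = {
                base_model.species_ids[i]: base_model.S[i, j]
                for i in range(len(base_model.species))
                if base_model.S[i, j] != 0
            }
            assert col == r.stoichiometry


class TestMassActionRate:
    def test_zero_at_equilibrium(self):
        r = Reaction("R", {"A": -1, "B": 1}, k=3.0, keq=2.0)
        assert mass_action_rate(r, {"A": 1.0, "B": 2.0}) == pytest.approx(0.0)

    def test_irreversible_forward_product(self):
        r = Reaction("R", {"A": -1, "B": 1}, k=2.0, keq=math.inf)
        assert mass_action_rate(r, {"A": 3.0, "B": 100.0}) == 6.0

    def test_bimolecular_reversible(self):
        # v = 1 * (2*3 - 4/2) = 4
        r = Reaction("R", {"A": -1, "B": -1, "C": 1}, k=1.0, keq=2.0)
        assert mass_action_rate(r, {"A": 2.0, "B": 3.0, "C": 4.0}) == pytest.approx(4.0)

    def test_missing_species_and_negative_concentration(self):
        r = Reaction("R", {"A": -1, "B": 1}, k=1.0)
        with pytest.raises(KeyError):
            mass_action_rate(r, {"A": 1.0})
        with pytest.raises(ValueError, match="negative"):
            mass_action_rate(r, {"A": -0.1, "B": 1.0})

    @given(
        k=st.floats(0.01, 100),
        keq=st.floats(0.01, 100),
        a=st.floats(1e-6, 50),
        b=st.floats(1e-6, 50),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_sign_consistent_with_thermodynamic_driving_force(self, k, keq, a, b):
        """The net rate is positive exactly when Gamma < Keq."""
        r = Reaction("R", {"A": -1, "B": 1}, k=k, keq=keq)
        v = mass_action_rate(r, {"A": a, "B": b})
        gamma = b / a
        if gamma < keq:
            assert v > 0
        elif gamma > keq:
            assert v < 0


class TestSimulate:
    def test_symmetric_equilibrium(self):
        traj = simulate(_ab_model(), t_end=50.0)
        assert traj.conc("A")[-1] == pytest.approx(1.0, abs=1e-6)
        assert traj.conc("B")[-1] == pytest.approx(1.0, abs=1e-6)

    def test_closed_system_mass_conservation(self):
        traj = simulate(_ab_model(k=5.0, keq=0.3, a0=1.2, b0=0.4), t_end=10.0)
        totals = traj.concentrations.sum(axis=0)
        assert np.all(np.abs(totals - totals[0]) < 1e-8)

    def test_fluxes_match_pointwise_rate_reevaluation(self, full_perturbation):
        traj = full_perturbation.trajectory
        model = full_perturbation.model
        for j in (0, len(traj.times) // 2, -1):
            np.testing.assert_array_equal(
                traj.fluxes[:, j], model.rates(traj.concentrations[:, j])
            )

    def test_fixed_species_are_clamped(self, base_model):
        traj = simulate(base_model, t_end=5.0)
        for s in base_model.species:
            if s.fixed:
                assert np.all(traj.conc(s.id) == s.initial_concentration)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate(_ab_model(), t_end=-1.0)


class TestConservedPools:
    def test_single_moiety(self):
        pools = conserved_pools(_ab_model())
        assert len(pools) == 1
        assert pools[0] == {"A": 1.0, "B": 1.0}

    def test_base_model_pools_include_adenylate_and_nad(self, base_model):
        pools = conserved_pools(base_model)
        sets = [frozenset(p) for p in pools]
        assert frozenset({"amp", "adp", "atp"}) in sets
        assert frozenset({"nad", "nadh"}) in sets
        assert frozenset({"hb", "hb_dpg23"}) in sets

    def test_pools_constant_along_trajectory(self, full_model, full_perturbation):
        traj = full_perturbation.trajectory
        model = full_perturbation.model
        for pool in conserved_pools(model):
            vals = np.array([
                pool_value(pool, model, traj.concentrations[:, j])
                for j in range(0, len(traj.times), 50)
            ])
            assert np.max(np.abs(vals - vals[0])) <= 1e-6 * abs(vals[0])


class TestSerialization:
    def test_json_round_trip(self, base_model, tmp_path):
        path = tmp_path / "model.json"
        base_model.save_json(path)
        clone = KineticModel.load_json(path)
        assert clone.species_ids == base_model.species_ids
        assert clone.reaction_ids == base_model.reaction_ids
        for r1, r2 in zip(base_model.reactions, clone.reactions):
            assert r1.stoichiometry == r2.stoichiometry
            assert r1.k == r2.k
            assert r1.keq == r2.keq or (not r1.reversible and not r2.reversible)
        x = base_model.initial_state()
        np.testing.assert_allclose(clone.rates(x), base_model.rates(x))

    def test_trajectory_csv_export(self, tmp_path):
        traj = simulate(_ab_model(), t_end=1.0)
        conc_csv = tmp_path / "conc.csv"
        flux_csv = tmp_path / "flux.csv"
        traj.to_csv(conc_csv, flux_csv)
        import pandas as pd

        conc = pd.read_csv(conc_csv)
        assert list(conc.columns) == ["time", "A", "B"]
        assert len(conc) == len(traj.times)
        assert list(pd.read_csv(flux_csv).columns) == ["time", "R"]
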