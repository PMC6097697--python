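"""PERC solving and enzyme-module parameterization."""

import math

import numpy as np
import pytest

import catpot as cp
from catpot import (
    ModelStructureError,
    Reaction,
    Species,
    ThermodynamicError,
    build_model,
    default_module_spec,
    generate_module,
    parameterize_module,
    parameterize_network,
    perc,
)
from catpot.network import ReferenceState
from catpot.parameterize import quasi_equilibrium_distribution


class TestPerc:
    def test_irreversible(self):
        assert perc(1.0, 2.0, 123.0, math.inf) == 0.5

    def test_reversible(self):
        # 5 / (3 - 1/2) = 2
        assert perc(5.0, 3.0, 1.0, 2.0) == pytest.approx(2.0)

    def test_equilibrium_denominator_with_flux_is_an_error(self):
        with pytest.raises(ThermodynamicError, match="equilibrium"):
            perc(1.0, 1.0, 2.0, 2.0)

    def test_sign_mismatch_is_an_error(self):
        with pytest.raises(ThermodynamicError, match="infeasible"):
            perc(1.0, 1.0, 4.0, 2.0)   # denominator negative, flux positive


class TestParameterizeNetwork:
    def test_linear_chain(self):
        m = build_model(
            [Species("A", initial_concentration=2.0),
             Species("B", initial_concentration=1.0),
             Species("C", initial_concentration=0.5, fixed=True)],
            [Reaction("R1", {"A": -1, "B": 1}, keq=math.inf),
             Reaction("R2", {"B": -1, "C": 1}, keq=math.inf)],
        )
        ref = ReferenceState({"A": 2.0, "B": 1.0, "C": 0.5},
                             {"R1": 1.0, "R2": 1.0}, {"R1": math.inf, "R2": math.inf})
        table = parameterize_network(m, ref)
        assert table.ks == {"R1": 0.5, "R2": 1.0}

    def test_round_trip_is_exact_at_reference(self, nominal_ref, base_model):
        """mass_action_rate with the solved k returns the reference flux to
        round-off for every flux-carrying reaction."""
        for r in base_model.reactions:
            v = cp.mass_action_rate(r, nominal_ref.concentrations)
            assert v == pytest.approx(nominal_ref.fluxes[r.id], abs=1e-12)

    def test_infeasible_reference_names_the_reaction(self):
        m = build_model(
            [Species("A", initial_concentration=1.0),
             Species("B", initial_concentration=5.0)],
            [Reaction("R1", {"A": -1, "B": 1}, keq=2.0)],
        )
        ref = ReferenceState({"A": 1.0, "B": 5.0}, {"R1": 1.0}, {"R1": 2.0})
        with pytest.raises(ThermodynamicError, match="R1"):
            parameterize_network(m, ref)


class TestParameterizeModule:
    def test_all_tense_limit_is_an_error(self, nominal_ref):
        mod = generate_module(default_module_spec("PFK", transition_constant=1e14))
        with pytest.raises(ModelStructureError, match="vanishingly"):
            parameterize_module(mod, nominal_ref)

    def test_monomer_equal_kd_distribution(self):
        """Kd = ligand concentration for both sites: E, E.S and E.SA occupy
        1 : 1 : 1 and f_A = 1 (no inhibitors bound)."""
        spec = cp.EnzymeModuleSpec(
            enzyme="HEX", n_sites=0,
            substrate="glc", kd_substrate=2.0,
            cofactor="atp", kd_cofactor=1.6,
            ordered_binding=False,
            products={"g6p": 1.0, "adp": 1.0, "h": 1.0},
            e_total=1e-4,
        )
        mod = generate_module(spec)
        conc = {"glc": 2.0, "atp": 1.6, "g6p": 1.0, "adp": 1.0, "h": 1.0}
        dist = quasi_equilibrium_distribution(mod, conc)
        assert dist["HEX_E"] == pytest.approx(dist["HEX_E_GLC"])
        assert dist["HEX_E"] == pytest.approx(dist["HEX_E_ATP"])
        assert dist["HEX_E"] == pytest.approx(dist["HEX_E_GLC_ATP"])
        fa = cp.active_fraction(dist, mod.active_set, spec.e_total)
        assert fa == pytest.approx(1.0)

    @pytest.mark.parametrize("enzyme", ["HEX", "PFK", "PYK"])
    def test_e_total_conserved_and_flux_matched(self, nominal_ref, enzyme):
        spec = default_module_spec(enzyme)
        mod = generate_module(spec)
        conc0 = parameterize_module(mod, nominal_ref)
        assert sum(conc0.values()) == pytest.approx(spec.e_total, rel=1e-9)
        tern = sum(conc0[t] for t in mod.ternary_forms)
        flux = mod.kcat * tern
        assert flux == pytest.approx(nominal_ref.fluxes[enzyme], rel=1e-6)

    def test_spliced_model_is_a_steady_state(self, full_model):
        rep = cp.verify_steady_state(full_model)
        assert rep.passed

    def test_fast_binding_scale_does_not_move_metabolite_trajectories(self, nominal_ref):
        """10x kappa_fast: quasi-equilibrium insensitivity, metabolite
        trajectories change by < 1%."""
        runs = {}
        for kf in (1e6, 1e7):
            model = cp.build_rbc_model(
                nominal_ref, ("PFK",), module_overrides={"PFK": {"kappa_fast": kf}})
            runs[kf] = cp.perturb_atp_utilization(model, 1.5, t_end=200.0)
        met_rows = [i for i, s in enumerate(runs[1e6].trajectory.species_ids)
                    if not s.startswith("PFK_")]
        a = runs[1e6].trajectory.concentrations[met_rows, :]
        b = runs[1e7].trajectory.concentrations[met_rows, :]
        rel = np.abs(a - b) / np.maximum(np.abs(a), 1e-9)
        assert rel.max() < 0.01

    def test_zero_flux_gives_zero_kcat_with_warning(self, nominal_ref):
        ref = cp.ReferenceState(nominal_ref.concentrations,
                                {**nominal_ref.fluxes, "PFK": 0.0},
                                nominal_ref.keqs, nominal_ref.rate_constants)
        mod = generate_module(default_module_spec("PFK"))
        with pytest.warns(UserWarning, match="kcat set to 0"):
            parameterize_module(mod, ref)
        assert mod.kcat == 0.0
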