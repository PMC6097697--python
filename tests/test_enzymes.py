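"""Enzyme-module enumeration: MWC state space, reaction counts, splicing."""

import itertools

import numpy as np
import pytest

import catpot as cp
from catpot import ModelStructureError, default_module_spec, generate_module, splice_module
from catpot.enzymes import EnzymeModuleSpec


@pytest.fixture(scope="module")
def modules():
    return {e: generate_module(default_module_spec(e)) for e in ("HEX", "PFK", "PYK")}


class TestEnumeration:
    @pytest.mark.parametrize(
        "enzyme, n_reactions, n_forms, n_active",
        [("PFK", 24, 20, 15), ("HEX", 8, 7, 4), ("PYK", 34, 25, 20)],
    )
    def test_counts(self, modules, enzyme, n_reactions, n_forms, n_active):
        mod = modules[enzyme]
        assert len(mod.reactions) == n_reactions
        assert len(mod.forms) == n_forms
        assert len(mod.active_set) == n_active

    def test_tense_forms_never_active(self, modules):
        for mod in modules.values():
            for form in mod.forms:
                if form.conformation == "T":
                    assert form.id not in mod.active_set

    def test_inhibitor_complexes_never_active(self, modules):
        for mod in modules.values():
            for form in mod.forms:
                if form.inhibitor is not None:
                    assert form.id not in mod.active_set

    def test_mwc_form_list_matches_combinatorial_oracle(self, modules):
        """Independent enumeration of conformation x activator occupancy x
        catalytic-site occupancy reproduces the generated form list."""
        for enzyme in ("PFK", "PYK"):
            spec = default_module_spec(enzyme)
            site_states = (
                [(), (spec.cofactor,), (spec.cofactor, spec.substrate)]
                if spec.ordered_binding
                else [(), (spec.substrate,), (spec.cofactor,),
                      (spec.substrate, spec.cofactor)]
            )
            expected = {("R", i, s) for i, s in itertools.product(range(5), site_states)}
            expected |= {("T", j, ()) for j in range(5)}
            got = set()
            for f in modules[enzyme].forms:
                level = (f.activator_count if f.conformation == "R"
                         else len(f.weight_factors))
                got.add((f.conformation, level, tuple(f.catalytic_ligands)))
            assert got == expected

    def test_unknown_enzyme_and_bad_constants_rejected(self):
        with pytest.raises(ModelStructureError):
            default_module_spec("LDH")
        with pytest.raises(ModelStructureError, match="positive"):
            generate_module(default_module_spec("PFK", kd_activator=-1.0))


class TestCatalyticCycle:
    @pytest.mark.parametrize("enzyme, lumped", [
        ("PFK", {"f6p": -1, "atp": -1, "fdp": 1, "adp": 1, "h": 1}),
        ("HEX", {"glc": -1, "atp": -1, "g6p": 1, "adp": 1, "h": 1}),
        ("PYK", {"pep": -1, "adp": -1, "h": -1, "pyr": 1, "atp": 1}),
    ])
    def test_cycle_reproduces_lumped_reaction(self, modules, enzyme, lumped):
        net = modules[enzyme].net_catalytic_stoichiometry()
        assert net == {k: float(v) for k, v in lumped.items()}


class TestSplicing:
    def test_stoichiometry_mismatch_refused(self, base_model):
        bad = generate_module(default_module_spec("PFK", products={"fdp": 2.0}))
        with pytest.raises(ModelStructureError, match="refusing to splice"):
            splice_module(base_model, bad, "PFK")

    def test_missing_lumped_reaction_refused(self, base_model, modules):
        with pytest.raises(ModelStructureError, match="not in model"):
            splice_module(base_model, modules["PFK"], "NOT_A_REACTION")

    def test_splice_removes_lumped_and_adds_forms(self, nominal_ref, base_model):
        spec = default_module_spec("PFK")
        mod = generate_module(spec)
        cp.parameterize_module(mod, nominal_ref)
        spliced = splice_module(base_model, mod, "PFK")
        assert not spliced.has_reaction("PFK")
        assert spliced.has_reaction("PFK_CAT0")
        for f in mod.forms:
            assert f.id in spliced.species_ids

    def test_enzyme_total_is_a_conserved_pool(self, nominal_ref, base_model):
        """The unit-weight indicator over the module's forms lies in the left
        null space of S and sums to E_total at the spliced initial state."""
        spec = default_module_spec("PFK")
        mod = generate_module(spec)
        cp.parameterize_module(mod, nominal_ref)
        spliced = splice_module(base_model, mod, "PFK")
        w = np.zeros(len(spliced.species))
        for f in mod.forms:
            w[spliced.species_index(f.id)] = 1.0
        np.testing.assert_allclose(w @ spliced.S, 0.0, atol=1e-12)
        assert w @ spliced.initial_state() == pytest.approx(spec.e_total, rel=1e-9)
        # and conserved_pools finds a basis spanning it: dimension check
        pools = cp.conserved_pools(spliced)
        assert len(pools) == 4  # NAD, Hb, adenylate(+bound), PFK forms

    def test_ten_model_variants(self, nominal_ref):
        variants = cp.model_variants(nominal_ref)
        assert len(variants) == 10
        full = variants["glycolysis+shunt+hb+PFK+HEX+PYK"]
        assert len(full.parameters["enzyme_modules"]) == 3
        assert "dpg23" not in variants["glycolysis"].species_ids


class TestActiveForms:
    def test_active_forms_accessor(self, modules):
        assert cp.active_forms(modules["HEX"]) == {
            "HEX_E", "HEX_E_GLC", "HEX_E_ATP", "HEX_E_GLC_ATP"
        }
        pfk_active = cp.active_forms(modules["PFK"])
        assert len(pfk_active) == 15
        assert all(not f.startswith("PFK_T") for f in pfk_active)
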