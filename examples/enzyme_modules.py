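"""Enumerate the three kinase enzyme modules and splice one into the network.

Each module replaces a lumped one-step reaction with every ligand-binding
event of the enzyme.  PFK and PYK are MWC homotetramers (activator binds the
relaxed conformation, ATP inhibits the tense one); HEX is a monomer with
three dead-end inhibitor complexes.
"""

import catpot as cp

ref = cp.nominal_reference_state()

for enzyme in ("HEX", "PFK", "PYK"):
    spec = cp.default_module_spec(enzyme)
    module = cp.generate_module(spec)
    active = cp.active_forms(module)
    print(f"{enzyme}: {len(module.reactions)} elementary reactions, "
          f"{len(module.forms)} enzyme forms ({len(active)} catalytically active), "
          f"E_total = {spec.e_total:.2e} mM")
    print(f"   one catalytic cycle nets: {module.net_catalytic_stoichiometry()}")

# parameterize the PFK module against the reference state and splice it in
base = cp.build_rbc_model(ref)
module = cp.generate_module(cp.default_module_spec("PFK"))
forms = cp.parameterize_module(module, ref)
print(f"\nPFK kcat solved from the reference flux: {module.kcat:.3g} /hr "
      f"({module.kcat / 3600:.1f} /s)")
fa = cp.active_fraction(forms, module.active_set, module.e_total)
print(f"resting active fraction f_A(PFK) = {fa:.3f} "
      "(share of enzyme in R-state, inhibitor-free forms)")

spliced = cp.splice_module(base, module, "PFK")
print(f"spliced model: {len(spliced.species)} species; steady state still "
      f"verified: {cp.verify_steady_state(spliced).passed}")
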