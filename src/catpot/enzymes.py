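"""Explicit elementary-reaction modules for the three regulated kinases.

An "enzyme module" replaces a lumped one-step reaction with every
ligand-binding event of the enzyme, enumerated as mass-action reactions over
explicit enzyme-form species.  PFK and PYK are Monod-Wyman-Changeux (MWC)
homotetramers: the protein toggles between a relaxed (R, catalytically
competent) and a tense (T, inactive) conformation, the allosteric activator
binds only R and the allosteric inhibitor only T, and the four allosteric
sites are independent (no statistical multiplicity factors on the sequential
binding steps).  HEX is a monomer with random-order substrate/cofactor
binding and three dead-end inhibitor complexes.

Mechanism summary (reaction counts match the enumeration):

* PFK  (24 reactions, 20 forms): R0<->T0; R_i + AMP <-> R_{i+1} (4);
  T_j + ATP <-> T_{j+1} (4); for each R_i (i = 0..4) ordered catalytic
  binding ATP then F6P plus one irreversible termolecular release
  R_i.ATP.F6P -> R_i + FDP + ADP + H (15).
* HEX  (8 reactions, 7 forms): random-order GLC/ATP binding (4), one
  irreversible catalysis step, and dead-end complexes E.G6P, E.23DPG and
  E.ATP.23DPG (3).
* PYK  (34 reactions, 25 forms): R0<->T0; R_i + FDP <-> R_{i+1} (4);
  T_j + ATP <-> T_{j+1} (4); for each R_i random-order PEP/ADP binding
  (4) plus irreversible catalysis R_i.PEP.ADP + H -> R_i + PYR + ATP (5x5).

The catalytically active set is every R-conformation (or monomer) form that
carries no dead-end inhibitor; T forms are never active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core import ModelStructureError, Reaction

__all__ = [
    "EnzymeForm",
    "EnzymeModuleSpec",
    "EnzymeModule",
    "generate_module",
    "splice_module",
    "active_forms",
    "default_module_spec",
    "DEFAULT_SPECS",
]


@dataclass(frozen=True)
class EnzymeForm:
    """One microstate of a regulated enzyme.

    ``weight_factors`` lists ``(ligand id, dissociation constant)`` pairs for
    every bound ligand; together with the R/T prefactor they define the
    form's statistical weight in the quasi-equilibrium binding polynomial:
    ``w = L^[is T] * prod([ligand]/Kd)``.
    """

    id: str
    enzyme: str
    conformation: str            # "R", "T", or "none" (monomer)
    activator_count: int = 0
    catalytic_ligands: tuple[str, ...] = ()
    inhibitor: str | None = None
    weight_factors: tuple[tuple[str, float], ...] = ()


@dataclass
class EnzymeModuleSpec:
    """Mechanism constants for one enzyme module.

    Dissociation constants are mmol/L; ``transition_constant`` is the
    dimensionless R0 <-> T0 equilibrium L = [T0]/[R0]; ``e_total`` is the
    total enzyme concentration in mmol/L; ``kappa_fast`` (hr^-1) is the
    dissociation-rate scale used for every binding step (binding
    equilibration is assumed fast relative to catalytic turnover).
    """

    enzyme: str
    n_sites: int                          # 4 for the tetramers, 0 for a monomer
    cofactor: str = ""
    kd_cofactor: float = 1.0
    substrate: str = ""
    kd_substrate: float = 1.0
    ordered_binding: bool = True          # cofactor first, then substrate
    products: dict[str, float] = field(default_factory=dict)
    consumed_cosubstrates: dict[str, float] = field(default_factory=dict)
    activator: str | None = None
    kd_activator: float = 1.0
    inhibitor: str | None = None
    kd_inhibitor: float = 1.0
    transition_constant: float = 1.0
    dead_end: list[tuple[tuple[str, ...], str, float]] = field(default_factory=list)
    e_total: float = 1e-4
    kappa_fast: float = 1e6

    def validate(self) -> None:
        pos = {
            "kd_cofactor": self.kd_cofactor,
            "kd_substrate": self.kd_substrate,
            "e_total": self.e_total,
            "kappa_fast": self.kappa_fast,
        }
        if self.activator:
            pos["kd_activator"] = self.kd_activator
        if self.inhibitor:
            pos["kd_inhibitor"] = self.kd_inhibitor
        if self.n_sites > 0:
            pos["transition_constant"] = self.transition_constant
        for name, v in pos.items():
            if not (v > 0 and math.isfinite(v)):
                raise ModelStructureError(f"{self.enzyme}: {name} must be positive, got {v}")
        for _, _, ki in self.dead_end:
            if not ki > 0:
                raise ModelStructureError(f"{self.enzyme}: inhibitor Kd must be positive")


@dataclass
class EnzymeModule:
    """Enumerated forms, elementary reactions and the active-form set."""

    enzyme: str
    spec: EnzymeModuleSpec
    forms: list[EnzymeForm]
    reactions: list[Reaction]
    active_set: set[str]
    ternary_forms: list[str]
    catalysis_reactions: list[str]
    cycle_reactions: list[str]           # one representative catalytic cycle
    e_total: float
    initial_concentrations: dict[str, float] = field(default_factory=dict)
    kcat: float = 0.0

    def form_ids(self) -> list[str]:
        return [f.id for f in self.forms]

    def net_catalytic_stoichiometry(self) -> dict[str, float]:
        """Net metabolite stoichiometry of one full catalytic cycle.

        Summing one representative path (binding steps to the ternary complex
        plus the release step) cancels all enzyme forms and leaves the lumped
        reaction the module stands in for.
        """
        form_ids = set(self.form_ids())
        net: dict[str, float] = {}
        by_id = {r.id: r for r in self.reactions}
        for rid in self.cycle_reactions:
            for sid, c in by_id[rid].stoichiometry.items():
                net[sid] = net.get(sid, 0.0) + c
        return {s: c for s, c in net.items() if s not in form_ids and abs(c) > 1e-12}

    def set_kcat(self, kcat: float) -> None:
        self.kcat = kcat
        by_id = {r.id: r for r in self.reactions}
        for rid in self.catalysis_reactions:
            by_id[rid].k = kcat


def _binding_reaction(rid: str, free: str, ligand: str, bound: str, kd: float,
                      kappa_fast: float) -> Reaction:
    # rate convention: v = k([free][ligand] - [bound]/Keq) with Keq = 1/Kd,
    # so k = k_on = kappa_fast / Kd and k_off = kappa_fast.
    return Reaction(rid, {free: -1.0, ligand: -1.0, bound: 1.0},
                    k=kappa_fast / kd, keq=1.0 / kd)


def generate_module(spec: EnzymeModuleSpec) -> EnzymeModule:
    """Enumerate forms and elementary reactions for one enzyme mechanism."""
    spec.validate()
    if spec.n_sites > 0:
        return _generate_mwc(spec)
    return _generate_monomer(spec)


def _generate_mwc(spec: EnzymeModuleSpec) -> EnzymeModule:
    E = spec.enzyme
    n = spec.n_sites
    kf = spec.kappa_fast
    cof, sub = spec.cofactor.upper(), spec.substrate.upper()
    forms: list[EnzymeForm] = []
    reactions: list[Reaction] = []
    active: set[str] = set()
    ternary: list[str] = []
    cats: list[str] = []

    def r_id(i: int) -> str:
        return f"{E}_R{i}"

    for i in range(n + 1):
        act_factors = ((spec.activator, spec.kd_activator),) * i
        base = EnzymeForm(r_id(i), E, "R", i, (), None, act_factors)
        c_form = EnzymeForm(f"{r_id(i)}_{cof}", E, "R", i, (spec.cofactor,), None,
                            act_factors + ((spec.cofactor, spec.kd_cofactor),))
        forms.append(base)
        active.add(base.id)
        if spec.ordered_binding:
            t_form = EnzymeForm(
                f"{r_id(i)}_{cof}_{sub}", E, "R", i, (spec.cofactor, spec.substrate), None,
                act_factors + ((spec.cofactor, spec.kd_cofactor),
                               (spec.substrate, spec.kd_substrate)))
            forms += [c_form, t_form]
            active |= {c_form.id, t_form.id}
            reactions.append(_binding_reaction(
                f"{E}_BIND_{cof}{i}", base.id, spec.cofactor, c_form.id,
                spec.kd_cofactor, kf))
            reactions.append(_binding_reaction(
                f"{E}_BIND_{sub}{i}", c_form.id, spec.substrate, t_form.id,
                spec.kd_substrate, kf))
        else:
            s_form = EnzymeForm(f"{r_id(i)}_{sub}", E, "R", i, (spec.substrate,), None,
                                act_factors + ((spec.substrate, spec.kd_substrate),))
            t_form = EnzymeForm(
                f"{r_id(i)}_{sub}_{cof}", E, "R", i, (spec.substrate, spec.cofactor), None,
                act_factors + ((spec.substrate, spec.kd_substrate),
                               (spec.cofactor, spec.kd_cofactor)))
            forms += [s_form, c_form, t_form]
            active |= {s_form.id, c_form.id, t_form.id}
            reactions.append(_binding_reaction(
                f"{E}_BIND_{sub}{i}", base.id, spec.substrate, s_form.id,
                spec.kd_substrate, kf))
            reactions.append(_binding_reaction(
                f"{E}_BIND_{cof}{i}", base.id, spec.cofactor, c_form.id,
                spec.kd_cofactor, kf))
            reactions.append(_binding_reaction(
                f"{E}_BIND_{sub}_{cof}{i}", s_form.id, spec.cofactor, t_form.id,
                spec.kd_cofactor, kf))
            reactions.append(_binding_reaction(
                f"{E}_BIND_{cof}_{sub}{i}", c_form.id, spec.substrate, t_form.id,
                spec.kd_substrate, kf))
        ternary.append(t_form.id)
        stoich: dict[str, float] = {t_form.id: -1.0, base.id: 1.0}
        for sid, c in spec.consumed_cosubstrates.items():
            stoich[sid] = stoich.get(sid, 0.0) - c
        for sid, c in spec.products.items():
            stoich[sid] = stoich.get(sid, 0.0) + c
        cat = Reaction(f"{E}_CAT{i}", stoich, k=0.0, keq=math.inf)
        reactions.append(cat)
        cats.append(cat.id)

    # sequential activator binding on the R conformation
    for i in range(n):
        reactions.append(_binding_reaction(
            f"{E}_ACT{i}", r_id(i), spec.activator, r_id(i + 1),
            spec.kd_activator, kf))

    # T-conformation chain: inhibitor binding only, no catalytic-site ligands.
    for j in range(n + 1):
        forms.append(EnzymeForm(
            f"{E}_T{j}", E, "T", 0, (), spec.inhibitor if j else None,
            ((spec.inhibitor, spec.kd_inhibitor),) * j))
    reactions.append(Reaction(f"{E}_RT", {r_id(0): -1.0, f"{E}_T0": 1.0},
                              k=kf, keq=spec.transition_constant))
    for j in range(n):
        reactions.append(_binding_reaction(
            f"{E}_TI{j}", f"{E}_T{j}", spec.inhibitor, f"{E}_T{j + 1}",
            spec.kd_inhibitor, kf))

    if spec.ordered_binding:
        cycle = [f"{E}_BIND_{cof}0", f"{E}_BIND_{sub}0", f"{E}_CAT0"]
    else:
        cycle = [f"{E}_BIND_{sub}0", f"{E}_BIND_{sub}_{cof}0", f"{E}_CAT0"]
    return EnzymeModule(E, spec, forms, reactions, active, ternary, cats, cycle,
                        spec.e_total)


def _generate_monomer(spec: EnzymeModuleSpec) -> EnzymeModule:
    E = spec.enzyme
    kf = spec.kappa_fast
    sub, cof = spec.substrate.upper(), spec.cofactor.upper()
    base = EnzymeForm(f"{E}_E", E, "none")
    s_form = EnzymeForm(f"{E}_E_{sub}", E, "none", 0, (spec.substrate,), None,
                        ((spec.substrate, spec.kd_substrate),))
    c_form = EnzymeForm(f"{E}_E_{cof}", E, "none", 0, (spec.cofactor,), None,
                        ((spec.cofactor, spec.kd_cofactor),))
    t_form = EnzymeForm(f"{E}_E_{sub}_{cof}", E, "none", 0,
                        (spec.substrate, spec.cofactor), None,
                        ((spec.substrate, spec.kd_substrate),
                         (spec.cofactor, spec.kd_cofactor)))
    forms = [base, s_form, c_form, t_form]
    active = {f.id for f in forms}
    reactions = [
        _binding_reaction(f"{E}_BIND_{sub}", base.id, spec.substrate, s_form.id,
                          spec.kd_substrate, kf),
        _binding_reaction(f"{E}_BIND_{cof}", base.id, spec.cofactor, c_form.id,
                          spec.kd_cofactor, kf),
        _binding_reaction(f"{E}_BIND_{sub}_{cof}", s_form.id, spec.cofactor,
                          t_form.id, spec.kd_cofactor, kf),
        _binding_reaction(f"{E}_BIND_{cof}_{sub}", c_form.id, spec.substrate,
                          t_form.id, spec.kd_substrate, kf),
    ]
    stoich: dict[str, float] = {t_form.id: -1.0, base.id: 1.0}
    for sid, c in spec.consumed_cosubstrates.items():
        stoich[sid] = stoich.get(sid, 0.0) - c
    for sid, c in spec.products.items():
        stoich[sid] = stoich.get(sid, 0.0) + c
    reactions.append(Reaction(f"{E}_CAT", stoich, k=0.0, keq=math.inf))

    # dead-end inhibitor complexes
    form_by_ligands = {f.catalytic_ligands: f for f in forms}
    for ligands, inhibitor, ki in spec.dead_end:
        parent = form_by_ligands.get(tuple(ligands))
        if parent is None:
            raise ModelStructureError(
                f"{E}: dead-end parent form with ligands {ligands} not found")
        inh_id = f"{parent.id}_{inhibitor.upper()}"
        forms.append(EnzymeForm(inh_id, E, "none", 0, parent.catalytic_ligands,
                                inhibitor,
                                parent.weight_factors + ((inhibitor, ki),)))
        reactions.append(_binding_reaction(
            f"{E}_INH_{'_'.join([*(l.upper() for l in ligands), inhibitor.upper()]) if ligands else inhibitor.upper()}",
            parent.id, inhibitor, inh_id, ki, kf))
    cycle = [f"{E}_BIND_{sub}", f"{E}_BIND_{sub}_{cof}", f"{E}_CAT"]
    return EnzymeModule(E, spec, forms, reactions, active, [t_form.id],
                        [f"{E}_CAT"], cycle, spec.e_total)


def active_forms(module: EnzymeModule) -> set[str]:
    """Catalytically competent forms: R-state / monomer, no dead-end inhibitor."""
    return set(module.active_set)


def splice_module(model, module: EnzymeModule, lumped_reaction_id: str):
    """Replace a lumped reaction with an enzyme module.

    The module's net catalytic-cycle stoichiometry must match the lumped
    reaction exactly; otherwise the splice is refused.  Enzyme forms are added
    as ordinary species (initialized from the module's parameterized steady
    state) and the enzyme total becomes a conserved pool of the new model.
    """
    from .core import KineticModel, Species

    if not model.has_reaction(lumped_reaction_id):
        raise ModelStructureError(f"lumped reaction {lumped_reaction_id!r} not in model")
    lumped = model.get_reaction(lumped_reaction_id)
    net = module.net_catalytic_stoichiometry()
    lump_st = {s: c for s, c in lumped.stoichiometry.items() if abs(c) > 1e-12}
    if {s: round(c, 9) for s, c in net.items()} != {s: round(c, 9) for s, c in lump_st.items()}:
        raise ModelStructureError(
            f"module {module.enzyme} net stoichiometry {net} does not match "
            f"lumped reaction {lumped_reaction_id!r} {lump_st}; refusing to splice")
    species = [Species(s.id, s.name, s.initial_concentration, s.fixed) for s in model.species]
    species += [
        Species(f.id, f"{module.enzyme} form {f.id}",
                module.initial_concentrations.get(f.id, 0.0), fixed=False)
        for f in module.forms
    ]
    reactions = [Reaction(r.id, dict(r.stoichiometry), r.k, r.keq)
                 for r in model.reactions if r.id != lumped_reaction_id]
    reactions += [Reaction(r.id, dict(r.stoichiometry), r.k, r.keq)
                  for r in module.reactions]
    out = KineticModel(species, reactions)
    out.parameters = dict(model.parameters)
    out.parameters.setdefault("enzyme_modules", {})
    out.parameters["enzyme_modules"] = {
        **out.parameters["enzyme_modules"],
        module.enzyme: {
            "e_total": module.e_total,
            "active_set": sorted(module.active_set),
            "forms": [f.id for f in module.forms],
            "kcat": module.kcat,
        },
    }
    return out


def default_module_spec(enzyme: str, **overrides) -> EnzymeModuleSpec:
    """Default mechanism constants for HEX, PFK and PYK.

    Dissociation constants sit in the physiological ranges reported for the
    human erythrocyte isozymes (e.g. micromolar G6P inhibition of HEX,
    micromolar FDP activation of PYK, millimolar allosteric ATP inhibition);
    enzyme totals are tens of nanomolar.  The R/T transition constants are
    chosen so that the reference-state active fraction leaves room to move in
    both directions.  Any field can be overridden by keyword.
    """
    enzyme = enzyme.upper()
    if enzyme == "PFK":
        spec = EnzymeModuleSpec(
            enzyme="PFK", n_sites=4,
            cofactor="atp", kd_cofactor=0.06,
            substrate="f6p", kd_substrate=0.05,
            ordered_binding=True,
            products={"fdp": 1.0, "adp": 1.0, "h": 1.0},
            activator="amp", kd_activator=0.05,
            inhibitor="atp", kd_inhibitor=0.1,
            transition_constant=0.0036,
            e_total=9.5e-5,
        )
    elif enzyme == "PYK":
        spec = EnzymeModuleSpec(
            enzyme="PYK", n_sites=4,
            substrate="pep", kd_substrate=0.3,
            cofactor="adp", kd_cofactor=0.3,
            ordered_binding=False,
            products={"pyr": 1.0, "atp": 1.0},
            consumed_cosubstrates={"h": 1.0},
            activator="fdp", kd_activator=0.02,
            inhibitor="atp", kd_inhibitor=2.5,
            transition_constant=2.0,
            e_total=9.0e-5,
            # PYK's catalytic site is far from saturation ([PEP] << Kd), so its
            # turnover number is large; binding must equilibrate faster than
            # catalysis or the mechanism cannot carry the reference flux.
            kappa_fast=1e8,
        )
    elif enzyme == "HEX":
        spec = EnzymeModuleSpec(
            enzyme="HEX", n_sites=0,
            substrate="glc", kd_substrate=0.05,
            cofactor="atp", kd_cofactor=0.5,
            ordered_binding=False,
            products={"g6p": 1.0, "adp": 1.0, "h": 1.0},
            # dead-end complexes: tight (micromolar) G6P product inhibition,
            # weak millimolar 2,3-DPG binding at the same site, and ADP
            # product inhibition at the ATP subsite of the glucose complex
            dead_end=[
                ((), "g6p", 0.01),
                ((), "dpg23", 10.0),
                (("glc",), "adp", 1.0),
            ],
            e_total=2.4e-5,
        )
    else:
        raise ModelStructureError(f"unknown enzyme {enzyme!r} (expected HEX, PFK or PYK)")
    for key, val in overrides.items():
        if not hasattr(spec, key):
            raise ModelStructureError(f"unknown spec field {key!r}")
        setattr(spec, key, val)
    return spec


DEFAULT_SPECS = ("HEX", "PFK", "PYK")
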