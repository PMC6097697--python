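"""Pseudo-elementary rate-constant (PERC) parameterization.

A reaction's PERC is solved from its reference steady-state flux and the
mass-action rate law:

    k_i = v_i / (prod_reactants [X]^|n| - prod_products [X]^n / Keq)

For an irreversible reaction the product term is dropped.  The sign of the
denominator must match the sign of the flux; a mismatch means the reference
state is thermodynamically infeasible for that reaction and is reported as
an error rather than silently producing a negative rate constant.

Enzyme modules are parameterized in two stages: a quasi-equilibrium
distribution of the enzyme forms from the binding polynomial seeds the form
concentrations, then the module's internal steady state (with metabolites
clamped at the reference) is solved numerically and the catalytic constant
is rescaled until the module's cycle flux matches the reference flux of the
lumped reaction it replaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


from .core import KineticModel, ModelStructureError, Species
from .enzymes import EnzymeModule
from .network import ReferenceState

__all__ = [
    "PercTable",
    "ThermodynamicError",
    "perc",
    "parameterize_network",
    "parameterize_module",
]

#: fluxes smaller than this (mmol/L/hr) are treated as zero
ZERO_FLUX_TOL = 1e-12


class ThermodynamicError(ValueError):
    """Reference state infeasible for one or more reactions."""

    def __init__(self, message: str, reactions: list[str] | None = None):
        super().__init__(message)
        self.reactions = reactions or []


@dataclass
class PercTable:
    """Solved rate constants plus the steady-state residual they achieve."""

    ks: dict[str, float]
    residual: float = 0.0
    notes: dict[str, str] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"reaction": list(self.ks), "k": list(self.ks.values()),
             "note": [self.notes.get(r, "") for r in self.ks]}
        ).set_index("reaction")


def perc(v_i: float, reactant_product: float, product_product: float,
         keq: float) -> float:
    """Solve ``k = v / (reactant_product - product_product / Keq)``.

    ``keq = inf`` drops the product term.  Errors on an equilibrium
    denominator with nonzero flux and on a thermodynamic sign mismatch.
    """
    denom = reactant_product
    if np.isfinite(keq):
        denom = reactant_product - product_product / keq
    if denom == 0.0:
        raise ThermodynamicError(
            "reaction is at equilibrium (zero denominator) but carries nonzero flux"
        )
    k = v_i / denom
    if k < 0:
        raise ThermodynamicError(
            f"flux sign ({v_i:+g}) opposes the thermodynamic driving force "
            f"({denom:+g}); reference state infeasible"
        )
    return k


def _concentration_products(reaction, conc: dict[str, float]) -> tuple[float, float]:
    fwd = 1.0
    for sid, n in reaction.reactants.items():
        fwd *= conc[sid] ** n
    rev = 1.0
    for sid, n in reaction.products.items():
        rev *= conc[sid] ** n
    return fwd, rev


def parameterize_network(model: KineticModel, ref: ReferenceState) -> PercTable:
    """Set every reaction's PERC from the reference state, in place.

    Zero-flux reactions (exchanges at equilibrium, adenylate kinase,
    hemoglobin binding) take their rate constants from
    ``ref.rate_constants``; their mass-action ratio must already equal their
    Keq or the model cannot start at steady state.
    """
    ref.validate(model.reaction_ids)
    ks: dict[str, float] = {}
    notes: dict[str, str] = {}
    errors: list[str] = []
    for r in model.reactions:
        missing = [s for s in r.stoichiometry if s not in ref.concentrations]
        if missing:
            errors.append(f"{r.id}: missing concentrations {missing}")
            continue
        v = ref.fluxes[r.id]
        fwd, rev = _concentration_products(r, ref.concentrations)
        if abs(v) <= ZERO_FLUX_TOL:
            if r.id in ref.rate_constants:
                denom = fwd - (rev / r.keq if r.reversible else 0.0)
                scale = max(fwd, rev, 1e-300)
                if abs(denom) > 1e-6 * scale:
                    errors.append(
                        f"{r.id}: zero reference flux but mass-action ratio is not "
                        f"at Keq (relative imbalance {denom / scale:.2e})")
                    continue
                ks[r.id] = ref.rate_constants[r.id]
                notes[r.id] = "equilibrium reaction; rate constant taken from reference data"
            else:
                ks[r.id] = 0.0
                notes[r.id] = "zero flux and no supplied rate constant; k = 0"
        else:
            try:
                ks[r.id] = perc(v, fwd, rev, r.keq)
            except ThermodynamicError as exc:
                errors.append(f"{r.id}: {exc}")
    if errors:
        raise ThermodynamicError(
            "parameterization failed for %d reaction(s):\n  %s"
            % (len(errors), "\n  ".join(errors)),
            reactions=[e.split(":")[0] for e in errors],
        )
    for rid, k in ks.items():
        model.set_rate_constant(rid, k)
    # residual of S v at the reference concentrations
    x = np.array([ref.concentrations[s.id] for s in model.species])
    model.set_initial_state({s.id: ref.concentrations[s.id] for s in model.species})
    dx = model.ode_rhs(0.0, x)
    v = model.rates(x)
    residual = float(np.max(np.abs(dx))) if dx.size else 0.0
    return PercTable(ks, residual, notes)


def quasi_equilibrium_distribution(module: EnzymeModule,
                                   conc: dict[str, float]) -> dict[str, float]:
    """Binding-polynomial distribution of the enzyme forms.

    Each form's statistical weight is ``L^[T] * prod([ligand]/Kd)`` along its
    binding path; weights are normalized to the total enzyme concentration.
    This is the exact steady state in the limit of infinitely fast binding
    and zero catalytic turnover, and a very good starting point otherwise.
    """
    L = module.spec.transition_constant
    weights = {}
    for f in module.forms:
        w = L if f.conformation == "T" else 1.0
        for ligand, kd in f.weight_factors:
            if ligand not in conc:
                raise ModelStructureError(
                    f"{module.enzyme}: ligand {ligand!r} missing from reference state")
            w *= conc[ligand] / kd
        weights[f.id] = w
    total = sum(weights.values())
    if not total > 0:
        raise ModelStructureError(f"{module.enzyme}: degenerate binding polynomial")
    return {fid: module.e_total * w / total for fid, w in weights.items()}


def _module_submodel(module: EnzymeModule, conc: dict[str, float]) -> KineticModel:
    """The module's reactions with every metabolite clamped at the reference."""
    form_ids = set(module.form_ids())
    met_ids = sorted(
        {s for r in module.reactions for s in r.stoichiometry} - form_ids
    )
    species = [Species(fid, "", 0.0, fixed=False) for fid in module.form_ids()]
    species += [Species(m, "", conc[m], fixed=True) for m in met_ids]
    return KineticModel(species, list(module.reactions))


def _solve_module_steady_state(sub: KineticModel, module: EnzymeModule,
                               y0: np.ndarray) -> np.ndarray:
    """Solve the clamped-metabolite steady state of the enzyme forms.

    The form balances are rank-deficient by one (total enzyme is conserved),
    so one balance is replaced by the conservation constraint.
    """
    n_forms = len(module.forms)
    x_template = sub.initial_state()
    e_tot = module.e_total
    # nondimensionalize: fractions of E_total, residuals per binding-rate scale
    rate_scale = module.spec.kappa_fast * e_tot

    def assemble(u):
        x = x_template.copy()
        x[:n_forms] = u * e_tot
        return x

    def fun(u):
        res = sub.ode_rhs(0.0, assemble(u))[:n_forms] / rate_scale
        res[0] = float(np.sum(u)) - 1.0
        return res

    def jac(u):
        J = sub.ode_jac(0.0, assemble(u))[:n_forms, :n_forms] * (e_tot / rate_scale)
        J[0, :] = 1.0
        return J

    # the form balances are linear in the form concentrations (every module
    # reaction is first order in exactly one enzyme form), so Newton
    # converges in one step; the loop guards round-off.
    u = y0 / e_tot
    for _ in range(25):
        f = fun(u)
        if np.max(np.abs(f)) < 1e-13:
            break
        try:
            u = u - np.linalg.solve(jac(u), f)
        except np.linalg.LinAlgError as exc:
            raise ModelStructureError(
                f"{module.enzyme}: singular module balance ({exc})") from exc
    else:
        raise ModelStructureError(
            f"{module.enzyme}: module steady-state solve did not converge")
    if np.any(u < -1e-9):
        raise ModelStructureError(
            f"{module.enzyme}: module steady state has negative form concentrations")
    return np.maximum(u, 0.0) * e_tot


def parameterize_module(module: EnzymeModule, ref: ReferenceState,
                        flux_rel_tol: float = 1e-9,
                        max_iter: int = 60) -> dict[str, float]:
    """Parameterize an enzyme module against a reference state, in place.

    Sets the shared catalytic constant so the module's catalytic cycle flux
    (with metabolites clamped at the reference concentrations) equals the
    reference flux of the lumped reaction, and stores the solved steady-state
    form concentrations as the module's initial conditions.  Returns the form
    concentrations.
    """
    v_ss = ref.fluxes.get(module.enzyme)
    if v_ss is None:
        raise ModelStructureError(
            f"reference has no flux for lumped reaction {module.enzyme!r}")
    conc = ref.concentrations
    dist = quasi_equilibrium_distribution(module, conc)
    tern0 = sum(dist[t] for t in module.ternary_forms)
    if abs(v_ss) <= ZERO_FLUX_TOL:
        warnings.warn(f"{module.enzyme}: zero reference flux, kcat set to 0")
        module.set_kcat(0.0)
        module.initial_concentrations = dist
        return dist
    if tern0 <= 1e-12 * module.e_total:
        raise ModelStructureError(
            f"{module.enzyme}: catalytic (ternary) complex is vanishingly "
            "populated at the reference state; cannot carry the reference flux")
    module.set_kcat(v_ss / tern0)
    sub = _module_submodel(module, conc)
    y = np.array([dist[f] for f in module.form_ids()])
    for _ in range(max_iter):
        y = _solve_module_steady_state(sub, module, y)
        tern = sum(y[module.form_ids().index(t)] for t in module.ternary_forms)
        flux = module.kcat * tern
        if abs(flux - v_ss) <= flux_rel_tol * abs(v_ss):
            break
        module.set_kcat(module.kcat * v_ss / flux)
        # rebuild the clamped submodel so the updated kcat is picked up
        sub = _module_submodel(module, conc)
    else:
        raise ModelStructureError(
            f"{module.enzyme}: kcat refinement did not converge in {max_iter} iterations")
    out = dict(zip(module.form_ids(), y))
    module.initial_concentrations = out
    return out
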