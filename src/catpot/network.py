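"""The base erythrocyte glycolysis network.

Glycolysis (10 enzymes plus lactate dehydrogenase), adenylate kinase, an ATP
hydrolysis load, phosphate exchange, boundary exchanges, and optionally the
Rapoport-Luebering shunt with a minimal hemoglobin/2,3-DPG binding
equilibrium.  Protons and water are carried in the stoichiometries but
clamped at unit activity (biochemical standard state at constant pH), so all
equilibrium constants are apparent constants.

The network is parameterized from a :class:`ReferenceState` (steady-state
concentrations, net fluxes and equilibrium constants) via pseudo-elementary
rate constants, so a freshly built model sits exactly at its reference
steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np

from .core import KineticModel, ModelStructureError, Reaction, Species

__all__ = [
    "ReferenceState",
    "NetworkConfig",
    "SteadyStateReport",
    "build_base_model",
    "set_atp_load",
    "verify_steady_state",
    "SPECIES_TABLE",
    "REACTION_TABLE",
    "SHUNT_REACTIONS",
    "HEMOGLOBIN_REACTIONS",
    "ATP_HYDROLYSIS_ID",
]

# id -> (name, fixed)
SPECIES_TABLE: dict[str, tuple[str, bool]] = {
    "glc": ("glucose", False),
    "g6p": ("glucose 6-phosphate", False),
    "f6p": ("fructose 6-phosphate", False),
    "fdp": ("fructose 1,6-bisphosphate", False),
    "dhap": ("dihydroxyacetone phosphate", False),
    "g3p": ("glyceraldehyde 3-phosphate", False),
    "dpg13": ("1,3-bisphosphoglycerate", False),
    "dpg23": ("2,3-bisphosphoglycerate", False),
    "pg3": ("3-phosphoglycerate", False),
    "pg2": ("2-phosphoglycerate", False),
    "pep": ("phosphoenolpyruvate", False),
    "pyr": ("pyruvate", False),
    "lac": ("lactate", False),
    "nad": ("NAD+", False),
    "nadh": ("NADH", False),
    "amp": ("AMP", False),
    "adp": ("ADP", False),
    "atp": ("ATP", False),
    "pi": ("inorganic phosphate", False),
    "hb": ("hemoglobin (2,3-DPG free)", False),
    "hb_dpg23": ("hemoglobin:2,3-DPG complex", False),
    "glc_ext": ("plasma glucose", True),
    "pyr_ext": ("plasma pyruvate", True),
    "lac_ext": ("plasma lactate", True),
    "pi_ext": ("plasma inorganic phosphate", True),
    "h": ("proton (unit activity)", True),
    "h2o": ("water (unit activity)", True),
}

REACTION_TABLE: dict[str, dict[str, float]] = {
    "GLC_IN": {"glc_ext": -1, "glc": 1},
    "HEX": {"glc": -1, "atp": -1, "g6p": 1, "adp": 1, "h": 1},
    "PGI": {"g6p": -1, "f6p": 1},
    "PFK": {"f6p": -1, "atp": -1, "fdp": 1, "adp": 1, "h": 1},
    "ALD": {"fdp": -1, "dhap": 1, "g3p": 1},
    "TPI": {"dhap": -1, "g3p": 1},
    "GAPDH": {"g3p": -1, "nad": -1, "pi": -1, "dpg13": 1, "nadh": 1, "h": 1},
    "PGK": {"dpg13": -1, "adp": -1, "pg3": 1, "atp": 1},
    "PGM": {"pg3": -1, "pg2": 1},
    "ENO": {"pg2": -1, "pep": 1, "h2o": 1},
    "PYK": {"pep": -1, "adp": -1, "h": -1, "pyr": 1, "atp": 1},
    "LDH": {"pyr": -1, "nadh": -1, "h": -1, "lac": 1, "nad": 1},
    "AK": {"adp": -2, "atp": 1, "amp": 1},
    "ATPASE": {"atp": -1, "h2o": -1, "adp": 1, "h": 1, "pi": 1},
    "PIX": {"pi_ext": -1, "pi": 1},
    "PYRX": {"pyr": -1, "pyr_ext": 1},
    "LACX": {"lac": -1, "lac_ext": 1},
    "DPGM": {"dpg13": -1, "dpg23": 1},
    "DPGASE": {"dpg23": -1, "h2o": -1, "pg3": 1, "pi": 1},
    "HBDPG": {"hb": -1, "dpg23": -1, "hb_dpg23": 1},
}

SHUNT_REACTIONS = ("DPGM", "DPGASE")
HEMOGLOBIN_REACTIONS = ("HBDPG",)
ATP_HYDROLYSIS_ID = "ATPASE"


@dataclass
class ReferenceState:
    """Steady-state data used to parameterize a model.

    ``rate_constants`` supplies rate constants for reactions that carry zero
    net flux at the reference state (adenylate kinase, the exchange
    reactions, hemoglobin binding); their constants cannot be recovered from
    a zero flux, so they are data.  ``source`` tags provenance
    (``nominal``, ``personalized:<id>`` or ``randomized:<seed>``).
    """

    concentrations: dict[str, float]
    fluxes: dict[str, float]
    keqs: dict[str, float]
    rate_constants: dict[str, float] = field(default_factory=dict)
    source: str = "nominal"

    def validate(self, reaction_ids=None) -> None:
        for sid, c in self.concentrations.items():
            if not (math.isfinite(c) and c >= 0):
                raise ModelStructureError(f"reference concentration {sid!r} = {c}")
        rids = reaction_ids if reaction_ids is not None else self.fluxes.keys()
        for rid in rids:
            if rid not in self.fluxes:
                raise ModelStructureError(f"reference is missing a flux for {rid!r}")
            if rid not in self.keqs:
                raise ModelStructureError(f"reference is missing a Keq for {rid!r}")


@dataclass
class NetworkConfig:
    """Which optional parts of the network to include.

    Hemoglobin requires the RL shunt (2,3-DPG must exist).  ``k_atp_scale``
    scales the ATP-hydrolysis rate constant after parameterization.
    """

    include_rl_shunt: bool = True
    include_hemoglobin: bool = True
    k_atp_scale: float = 1.0
    fixed_species: frozenset[str] = frozenset(
        s for s, (_, fixed) in SPECIES_TABLE.items() if fixed
    )

    def __post_init__(self):
        if self.include_hemoglobin and not self.include_rl_shunt:
            raise ModelStructureError("hemoglobin requires the RL shunt (2,3-DPG)")
        if not self.k_atp_scale > 0:
            raise ModelStructureError("k_atp_scale must be positive")

    def reaction_ids(self) -> list[str]:
        out = [r for r in REACTION_TABLE
               if r not in SHUNT_REACTIONS + HEMOGLOBIN_REACTIONS]
        if self.include_rl_shunt:
            out += list(SHUNT_REACTIONS)
        if self.include_hemoglobin:
            out += list(HEMOGLOBIN_REACTIONS)
        return out


def _network_fluxes(ref: ReferenceState, cfg: NetworkConfig) -> dict[str, float]:
    """Reference fluxes for the configured subnetwork.

    With the shunt disabled its throughput is rerouted through PGK so the
    reduced network still satisfies S v = 0.
    """
    fluxes = dict(ref.fluxes)
    if not cfg.include_rl_shunt:
        shunt = fluxes.get("DPGM", 0.0)
        # the shunt bypasses PGK and hydrolyzes one phosphate per transit;
        # without it the extra PGK ATP yield is routed into the ATP load
        fluxes["PGK"] = fluxes["PGK"] + shunt
        fluxes[ATP_HYDROLYSIS_ID] = fluxes[ATP_HYDROLYSIS_ID] + shunt
        for rid in SHUNT_REACTIONS + HEMOGLOBIN_REACTIONS:
            fluxes.pop(rid, None)
    elif not cfg.include_hemoglobin:
        fluxes.pop("HBDPG", None)
    return fluxes


def build_base_model(ref: ReferenceState, cfg: NetworkConfig | None = None) -> KineticModel:
    """Assemble and parameterize the base RBC model from a reference state.

    Every rate constant is a pseudo-elementary rate constant solved from the
    reference flux (zero-flux reactions take their constants from
    ``ref.rate_constants``), so the returned model starts at a verified
    steady state.
    """
    from .parameterize import parameterize_network

    cfg = cfg or NetworkConfig()
    rids = cfg.reaction_ids()
    fluxes = _network_fluxes(ref, cfg)
    missing = [r for r in rids if r not in fluxes or r not in ref.keqs]
    if missing:
        raise ModelStructureError(f"reference does not cover reactions: {missing}")

    used_species: set[str] = set()
    for rid in rids:
        used_species |= set(REACTION_TABLE[rid])
    species = []
    for sid in SPECIES_TABLE:
        if sid not in used_species:
            continue
        if sid not in ref.concentrations:
            raise ModelStructureError(f"reference is missing a concentration for {sid!r}")
        name, _ = SPECIES_TABLE[sid]
        species.append(Species(sid, name, ref.concentrations[sid],
                               fixed=sid in cfg.fixed_species))
    reactions = [
        Reaction(rid, dict(REACTION_TABLE[rid]), k=0.0, keq=ref.keqs[rid])
        for rid in rids
    ]
    model = KineticModel(species, reactions)
    sub_ref = ReferenceState(ref.concentrations, fluxes, ref.keqs,
                             ref.rate_constants, ref.source)
    table = parameterize_network(model, sub_ref)
    model.parameters["perc_residual"] = table.residual
    model.parameters["reference_source"] = ref.source
    model.parameters["k_atp_reference"] = model.get_reaction(ATP_HYDROLYSIS_ID).k
    if cfg.k_atp_scale != 1.0:
        model.set_rate_constant(
            ATP_HYDROLYSIS_ID, cfg.k_atp_scale * model.get_reaction(ATP_HYDROLYSIS_ID).k
        )
    model.parameters["k_atp_scale"] = cfg.k_atp_scale
    return model


def set_atp_load(model: KineticModel, factor: float) -> KineticModel:
    """Return a copy with the ATP-hydrolysis rate constant scaled by ``factor``.

    This is the perturbation handle: raising the load drains the adenylate
    pool, lowering it lets the pool recharge; inorganic phosphate stays a
    dynamic variable so the system can absorb the disturbance.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if not model.has_reaction(ATP_HYDROLYSIS_ID):
        raise ModelStructureError("model has no ATP hydrolysis reaction")
    out = model.copy()
    out.set_rate_constant(ATP_HYDROLYSIS_ID,
                          factor * model.get_reaction(ATP_HYDROLYSIS_ID).k)
    out.parameters["k_atp_scale"] = factor * model.parameters.get("k_atp_scale", 1.0)
    return out


@dataclass
class SteadyStateReport:
    """Per-species |S v| residuals at the model's initial state."""

    residuals: dict[str, float]
    max_residual: float
    flux_scale: float
    tol: float

    @property
    def passed(self) -> bool:
        if not self.residuals:
            return True
        return self.max_residual <= self.tol * max(self.flux_scale, 1e-300)

    def worst(self, n: int = 5) -> list[tuple[str, float]]:
        return sorted(self.residuals.items(), key=lambda kv: -kv[1])[:n]


def verify_steady_state(model: KineticModel, tol: float = 1e-8) -> SteadyStateReport:
    """Evaluate ``S v`` at the initial state and compare against ``tol``
    (relative to the largest flux magnitude)."""
    if not model.species:
        return SteadyStateReport({}, 0.0, 0.0, tol)
    x0 = model.initial_state()
    v = model.rates(x0)
    dx = model.ode_rhs(0.0, x0)
    residuals = {
        s.id: abs(dx[i]) for i, s in enumerate(model.species) if not s.fixed
    }
    max_res = max(residuals.values(), default=0.0)
    return SteadyStateReport(residuals, max_res, float(np.max(np.abs(v))) if v.size else 0.0, tol)
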