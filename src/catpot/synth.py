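"""Synthetic reference data: nominal steady state, cohorts, S1-style tables.

The nominal reference state is a curated, thermodynamically consistent
erythrocyte glycolytic steady state: concentrations sit at standard
literature values for the human RBC, the flux vector is constructed in the
null space of the stoichiometric matrix (glycolytic throughput 1.12
mmol/L/hr with 20% of the triose flux routed through the Rapoport-Luebering
shunt), and every flux-carrying reaction satisfies the feasibility predicate
sign(v) * (1 - Gamma/Keq) > 0.  It is a test scaffold with physiological
numbers, not a measurement.

Cohorts emulate inter-individual variation: each individual's metabolite
concentrations are multiplied by log-normal factors and every reaction's
equilibrium constant is re-derived so that the individual's disequilibrium
ratio rho = Gamma/Keq is a jittered power of the nominal one.  Because
rho^t stays in (0, 1) for any t > 0, every generated individual is
automatically thermodynamically feasible and zero-flux reactions stay at
equilibrium.  One designated individual can carry fold-changed enzyme-module
dissociation constants (the outlier used by the Dixon screen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ModelStructureError
from .network import (
    REACTION_TABLE,
    SPECIES_TABLE,
    ReferenceState,
)

__all__ = [
    "Individual",
    "CohortSpec",
    "OutlierSpec",
    "nominal_reference_state",
    "generate_cohort",
    "sample_feasible_state",
    "feasibility_ok",
    "write_s1_layout",
    "read_s1_layout",
    "BORDBAR_INDIVIDUAL_LABELS",
]

#: our individual index (1-based) -> individual id in the source cohort dataset
BORDBAR_INDIVIDUAL_LABELS = (2, 4, 5, 6, 7, 8, 10, 16, 18)

# mmol/L; standard human-RBC steady-state values
_NOMINAL_CONC: dict[str, float] = {
    # intracellular glucose runs below plasma but well above the hexokinase
    # Km; the transport gradient buffers throughput changes
    "glc": 2.0,
    "g6p": 0.0486,
    "f6p": 0.0198,
    "fdp": 0.0146,
    "dhap": 0.16,
    "g3p": 0.00728,
    "dpg13": 0.000243,
    # the 2,3-DPG reservoir is large and turns over slowly (tens of hours);
    # it is the dominant slow mode of the perturbation response
    "dpg23": 4.0,
    "pg3": 0.0773,
    "pg2": 0.0113,
    "pep": 0.017,
    "pyr": 0.060301,
    "lac": 1.36,
    "nad": 0.0589,
    "nadh": 0.0301,
    "amp": 0.0867281,
    "adp": 0.29,
    "atp": 1.6,
    "pi": 2.5,
    # oxygenated hemoglobin binds 2,3-DPG weakly; only a modest fraction of
    # the pool is complexed under arterial conditions
    "hb": 2.0,
    "hb_dpg23": 1.5,
    # clamped boundary species
    "glc_ext": 5.0,
    "pyr_ext": 0.060301,
    "lac_ext": 1.36,
    "pi_ext": 2.5,
    "h": 1.0,     # unit activity (constant pH)
    "h2o": 1.0,   # unit activity
}

# apparent equilibrium constants (pH 7, mmol/L units) for the flux-carrying
# reactions; equilibrium-only reactions get Keq = Gamma(nominal) below.
_NOMINAL_KEQ: dict[str, float] = {
    "GLC_IN": 1.0,
    "HEX": 850.0,
    "PGI": 0.41,
    "PFK": 310.0,
    "ALD": 0.082,
    "TPI": 0.0571429,
    "GAPDH": 0.02,
    "PGK": 1800.0,
    "PGM": 0.147465,
    "ENO": 1.69,
    "PYK": 363000.0,
    "LDH": 26300.0,
    "ATPASE": math.inf,
    "LACX": math.inf,
    "DPGM": math.inf,
    "DPGASE": math.inf,
    "PIX": 1.0,
    "PYRX": 1.0,
    # AK and HBDPG are derived from the nominal concentrations (equilibrium)
}

#: glycolytic throughput (upper glycolysis) and shunt flux, mmol/L/hr
GLYCOLYTIC_FLUX = 1.12
SHUNT_FLUX = 0.25

#: rate constants for reactions that carry zero net flux at reference
_EQUILIBRIUM_RATE_CONSTANTS: dict[str, float] = {
    "AK": 1000.0,     # adenylate kinase is fast (L/mmol/hr)
    "PIX": 1.0,       # transmembrane phosphate exchange is slow (1/hr)
    "PYRX": 1.0,      # pyruvate exchange (1/hr)
    "HBDPG": 1e4,     # hemoglobin/2,3-DPG binding equilibrates quickly (L/mmol/hr)
}


def _nominal_fluxes() -> dict[str, float]:
    """Flux vector built reaction-by-reaction so that S v = 0 exactly."""
    v = GLYCOLYTIC_FLUX
    s = SHUNT_FLUX
    return {
        "GLC_IN": v, "HEX": v, "PGI": v, "PFK": v, "ALD": v, "TPI": v,
        "GAPDH": 2 * v,
        "PGK": 2 * v - s,
        "DPGM": s, "DPGASE": s,
        "PGM": 2 * v, "ENO": 2 * v, "PYK": 2 * v,
        "LDH": 2 * v, "LACX": 2 * v,
        "PYRX": 0.0,
        "AK": 0.0,
        "ATPASE": 2 * v - s,   # PGK + PYK - HEX - PFK
        "PIX": 0.0,
        "HBDPG": 0.0,
    }


def _mass_action_ratio(rid: str, conc: dict[str, float]) -> float:
    gamma_num, gamma_den = 1.0, 1.0
    for sid, c in REACTION_TABLE[rid].items():
        if c > 0:
            gamma_num *= conc[sid] ** c
        else:
            gamma_den *= conc[sid] ** (-c)
    return gamma_num / gamma_den


def nominal_reference_state() -> ReferenceState:
    """The packaged nominal erythrocyte reference state."""
    conc = dict(_NOMINAL_CONC)
    keqs = dict(_NOMINAL_KEQ)
    # zero-flux reactions sit exactly at equilibrium
    keqs["AK"] = _mass_action_ratio("AK", conc)
    keqs["HBDPG"] = _mass_action_ratio("HBDPG", conc)
    return ReferenceState(
        concentrations=conc,
        fluxes=_nominal_fluxes(),
        keqs=keqs,
        rate_constants=dict(_EQUILIBRIUM_RATE_CONSTANTS),
        source="nominal",
    )


def feasibility_ok(ref: ReferenceState, rid: str) -> bool:
    """Thermodynamic feasibility predicate sign(v) * (1 - Gamma/Keq) > 0.

    Zero-flux reactions are feasible by convention (they must instead sit at
    equilibrium, which the parameterizer checks).
    """
    v = ref.fluxes[rid]
    if abs(v) <= 1e-12:
        return True
    keq = ref.keqs[rid]
    if not np.isfinite(keq):
        return v > 0
    gamma = _mass_action_ratio(rid, ref.concentrations)
    return v * (1.0 - gamma / keq) > 0


@dataclass
class OutlierSpec:
    """One individual whose enzyme-module binding constants deviate."""

    individual_index: int = 0             # 0-based position in the cohort
    enzyme: str = "PFK"
    fields: tuple[str, ...] = ("kd_cofactor", "kd_substrate")
    fold_change: float = 3.0

    def __post_init__(self):
        if not self.fold_change > 0:
            raise ModelStructureError("fold-change must be positive")


@dataclass
class CohortSpec:
    """Controls for synthetic-cohort generation."""

    n: int = 9
    sigma: float = 0.2                    # log-normal scale on concentrations
    sigma_rho: float = 0.2                # log-scale jitter on disequilibrium ratios
    outlier: OutlierSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0 or self.sigma_rho < 0:
            raise ModelStructureError("sigma must be non-negative")
        if self.outlier is not None and not (0 <= self.outlier.individual_index < max(self.n, 1)):
            raise ModelStructureError("outlier index must be < n")


@dataclass
class Individual:
    """One cohort member: reference state plus module-constant overrides."""

    label: str
    source_label: str
    ref: ReferenceState
    module_overrides: dict[str, dict[str, float]] = field(default_factory=dict)


def _personalize(nominal: ReferenceState, rng: np.random.Generator,
                 sigma: float, sigma_rho: float, tag: str) -> ReferenceState:
    conc = dict(nominal.concentrations)
    for sid, (_, fixed) in SPECIES_TABLE.items():
        if not fixed:
            conc[sid] = nominal.concentrations[sid] * math.exp(sigma * rng.standard_normal())
    keqs = {}
    for rid, keq in nominal.keqs.items():
        if not np.isfinite(keq):
            keqs[rid] = math.inf
            continue
        gamma_nom = _mass_action_ratio(rid, nominal.concentrations)
        gamma_new = _mass_action_ratio(rid, conc)
        v = nominal.fluxes.get(rid, 0.0)
        if abs(v) <= 1e-12:
            # equilibrium reactions stay at equilibrium
            keqs[rid] = gamma_new
        else:
            if v < 0:
                raise ModelStructureError("cohort generation assumes forward fluxes")
            rho = gamma_nom / keq
            rho_new = rho ** math.exp(sigma_rho * rng.standard_normal())
            keqs[rid] = gamma_new / rho_new
    return ReferenceState(conc, dict(nominal.fluxes), keqs,
                          dict(nominal.rate_constants), source=tag)


def generate_cohort(spec: CohortSpec,
                    nominal: ReferenceState | None = None) -> list[Individual]:
    """Generate a cohort of personalized reference states.

    Deterministic under a fixed seed.  Every individual is thermodynamically
    feasible by construction (disequilibrium ratios are preserved up to a
    positive power).
    """
    nominal = nominal or nominal_reference_state()
    rng = np.random.default_rng(spec.seed)
    individuals = []
    from .enzymes import default_module_spec

    for i in range(spec.n):
        ref = _personalize(nominal, rng, spec.sigma, spec.sigma_rho,
                           tag=f"personalized:{i + 1}")
        overrides: dict[str, dict[str, float]] = {}
        if spec.outlier is not None and i == spec.outlier.individual_index:
            base_spec = default_module_spec(spec.outlier.enzyme)
            overrides[spec.outlier.enzyme] = {
                f: getattr(base_spec, f) * spec.outlier.fold_change
                for f in spec.outlier.fields
            }
        source = (str(BORDBAR_INDIVIDUAL_LABELS[i])
                  if i < len(BORDBAR_INDIVIDUAL_LABELS) else f"synthetic-{i + 1}")
        individuals.append(Individual(f"Individual #{i + 1}", source, ref, overrides))
    return individuals


def sample_feasible_state(
    ranges: dict[str, tuple[float, float]],
    keqs: dict[str, float],
    flux_signs: dict[str, float],
    rng_seed: int | np.random.Generator = 0,
    nominal: ReferenceState | None = None,
    max_attempts: int = 100_000,
) -> ReferenceState:
    """Accept/reject sampling of a thermodynamically feasible state.

    Concentrations are drawn log-uniformly within per-metabolite bounds until
    every flux-carrying reaction satisfies ``sign(v) * (1 - Gamma/Keq) > 0``.
    Zero-flux reversible reactions are then re-centred at equilibrium
    (``Keq := Gamma``) so the sampled state can be parameterized.
    """
    nominal = nominal or nominal_reference_state()
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    for lo, hi in ranges.values():
        if not (0 < lo <= hi):
            raise ModelStructureError("bounds must be positive with lo <= hi")
    sids = list(ranges)
    lo = np.log([ranges[s][0] for s in sids])
    hi = np.log([ranges[s][1] for s in sids])
    check_rids = [r for r, sgn in flux_signs.items() if sgn != 0]
    for attempt in range(max_attempts):
        conc = dict(nominal.concentrations)
        draw = np.exp(lo + (hi - lo) * rng.random(len(sids)))
        conc.update(zip(sids, draw))
        ok = True
        for rid in check_rids:
            keq = keqs[rid]
            if not np.isfinite(keq):
                if flux_signs[rid] < 0:
                    ok = False
                    break
                continue
            gamma = _mass_action_ratio(rid, conc)
            if not flux_signs[rid] * (1.0 - gamma / keq) > 0:
                ok = False
                break
        if ok:
            out_keqs = dict(keqs)
            for rid, keq in keqs.items():
                if np.isfinite(keq) and flux_signs.get(rid, 0) == 0:
                    out_keqs[rid] = _mass_action_ratio(rid, conc)
            return ReferenceState(conc, dict(nominal.fluxes), out_keqs,
                                  dict(nominal.rate_constants),
                                  source=f"randomized:{attempt}")
    raise ModelStructureError(
        f"no feasible state within {max_attempts} attempts; widen the "
        "concentration bounds or check the equilibrium constants")


def randomized_reference(fold: float = 2.0, seed: int | np.random.Generator = 0,
                         nominal: ReferenceState | None = None) -> ReferenceState:
    """Convenience wrapper: sample within [nominal/fold, nominal*fold]."""
    nominal = nominal or nominal_reference_state()
    ranges = {
        sid: (nominal.concentrations[sid] / fold, nominal.concentrations[sid] * fold)
        for sid, (_, fixed) in SPECIES_TABLE.items() if not fixed
    }
    signs = {rid: float(np.sign(v)) for rid, v in nominal.fluxes.items()}
    return sample_feasible_state(ranges, nominal.keqs, signs, seed, nominal)


# ---------------------------------------------------------------------------
# S1-layout serialization (sheets A-G, XLSX workbook or CSV bundle)
# ---------------------------------------------------------------------------

_SHEETS = {
    "A": "A_parameters",
    "B": "B_fluxes",
    "C": "C_personalized_parameters",
    "D": "D_personalized_fluxes",
    "E": "E_S_matrix",
    "F": "F_metabolites",
    "G": "G_reactions",
}


def _keq_str(x: float) -> str:
    return "inf" if not np.isfinite(x) else repr(float(x))


def _parameter_rows(ref: ReferenceState) -> pd.DataFrame:
    rows = [("concentration", sid, repr(float(v)))
            for sid, v in ref.concentrations.items()]
    rows += [("keq", rid, _keq_str(v)) for rid, v in ref.keqs.items()]
    rows += [("rate_constant", rid, repr(float(v)))
             for rid, v in ref.rate_constants.items()]
    return pd.DataFrame(rows, columns=["parameter_type", "id", "value"])


def write_s1_layout(path, nominal: ReferenceState,
                    individuals: list[Individual] | None = None) -> None:
    """Write the reference tables in the seven-sheet S1 layout.

    ``path`` ending in ``.xlsx`` produces a workbook; otherwise a directory
    of CSV files (one per sheet) is created.  The layout round-trips through
    :func:`read_s1_layout`.
    """
    individuals = individuals or []
    frames: dict[str, pd.DataFrame] = {}
    frames["A"] = _parameter_rows(nominal)
    frames["B"] = pd.DataFrame(
        [(rid, repr(float(v))) for rid, v in nominal.fluxes.items()],
        columns=["reaction", "flux"])

    prows = []
    for ind in individuals:
        for sid, v in ind.ref.concentrations.items():
            prows.append((ind.label, ind.source_label, "concentration", sid, repr(float(v))))
        for rid, v in ind.ref.keqs.items():
            prows.append((ind.label, ind.source_label, "keq", rid, _keq_str(v)))
        for rid, v in ind.ref.rate_constants.items():
            prows.append((ind.label, ind.source_label, "rate_constant", rid, repr(float(v))))
        for enzyme, over in ind.module_overrides.items():
            for fname, v in over.items():
                prows.append((ind.label, ind.source_label, "module_kd",
                              f"{enzyme}.{fname}", repr(float(v))))
    frames["C"] = pd.DataFrame(
        prows, columns=["individual", "source_individual", "parameter_type", "id", "value"])
    frames["D"] = pd.DataFrame(
        [(ind.label, rid, repr(float(v)))
         for ind in individuals for rid, v in ind.ref.fluxes.items()],
        columns=["individual", "reaction", "flux"])

    sids = list(SPECIES_TABLE)
    rids = list(REACTION_TABLE)
    S = pd.DataFrame(0.0, index=sids, columns=rids)
    for rid, st in REACTION_TABLE.items():
        for sid, c in st.items():
            S.loc[sid, rid] = c
    frames["E"] = S.reset_index().rename(columns={"index": "metabolite"})
    frames["F"] = pd.DataFrame(
        [(i, sid, SPECIES_TABLE[sid][0], SPECIES_TABLE[sid][1])
         for i, sid in enumerate(sids)],
        columns=["index", "id", "name", "fixed"])
    frames["G"] = pd.DataFrame(
        [(j, rid, " + ".join(f"{-c:g} {s}" for s, c in st.items() if c < 0)
          + " --> " + " + ".join(f"{c:g} {s}" for s, c in st.items() if c > 0))
         for j, (rid, st) in enumerate(REACTION_TABLE.items())],
        columns=["index", "id", "equation"])

    path = Path(path)
    if path.suffix == ".xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            for key, name in _SHEETS.items():
                frames[key].to_excel(xl, sheet_name=name, index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for key, name in _SHEETS.items():
            frames[key].to_csv(path / f"{name}.csv", index=False)


def _read_sheet(path: Path, key: str) -> pd.DataFrame:
    name = _SHEETS[key]
    if path.suffix == ".xlsx":
        book = pd.ExcelFile(path)
        if name not in book.sheet_names:
            raise ModelStructureError(f"S1 layout is missing sheet {name!r}")
        return book.parse(name, dtype=str)
    f = path / f"{name}.csv"
    if not f.exists():
        raise ModelStructureError(f"S1 layout is missing sheet {name!r} ({f})")
    return pd.read_csv(f, dtype=str)


def _parse_parameters(df: pd.DataFrame) -> tuple[dict, dict, dict, dict]:
    conc, keqs, rate_constants, module_kds = {}, {}, {}, {}
    for _, row in df.iterrows():
        ptype, pid, val = row["parameter_type"], row["id"], row["value"]
        if ptype == "concentration":
            conc[pid] = float(val)
        elif ptype == "keq":
            keqs[pid] = math.inf if val == "inf" else float(val)
        elif ptype == "rate_constant":
            rate_constants[pid] = float(val)
        elif ptype == "module_kd":
            enzyme, fname = pid.split(".", 1)
            module_kds.setdefault(enzyme, {})[fname] = float(val)
        else:
            raise ModelStructureError(f"unknown parameter_type {ptype!r}")
    return conc, keqs, rate_constants, module_kds


def read_s1_layout(path) -> tuple[ReferenceState, list[Individual]]:
    """Read an S1-layout workbook or CSV bundle back into reference objects.

    Validates that the sheets are present and that ids cross-reference the
    metabolite and reaction lists.
    """
    path = Path(path)
    dfs = {key: _read_sheet(path, key) for key in _SHEETS}
    known_species = set(dfs["F"]["id"])
    known_reactions = set(dfs["G"]["id"])

    conc, keqs, rate_constants, _ = _parse_parameters(dfs["A"])
    bad = (set(conc) - known_species) | (set(keqs) - known_reactions)
    if bad:
        raise ModelStructureError(f"sheet A references unknown ids: {sorted(bad)}")
    fluxes = {r["reaction"]: float(r["flux"]) for _, r in dfs["B"].iterrows()}
    if set(fluxes) - known_reactions:
        raise ModelStructureError("sheet B references unknown reactions")
    nominal = ReferenceState(conc, fluxes, keqs, rate_constants, source="nominal")

    individuals: list[Individual] = []
    if len(dfs["C"]):
        pflux = {}
        for _, row in dfs["D"].iterrows():
            pflux.setdefault(row["individual"], {})[row["reaction"]] = float(row["flux"])
        for label, group in dfs["C"].groupby("individual", sort=False):
            c, k, rc, mkd = _parse_parameters(group)
            src = group["source_individual"].iloc[0]
            individuals.append(Individual(
                label, str(src),
                ReferenceState(c, pflux.get(label, dict(fluxes)), k, rc,
                               source=f"personalized:{label}"),
                mkd))
    return nominal, individuals
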