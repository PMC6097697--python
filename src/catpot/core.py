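"""Mass-action reaction networks and stiff ODE simulation.

The representation is deliberately minimal: a model is a list of species, a
list of elementary (or lumped) mass-action reactions, and the stoichiometric
matrix ``S`` assembled from them.  Every reaction carries a single rate
constant ``k`` and an equilibrium constant ``Keq``; the net rate law is

    v = k * (prod_reactants [X]^|n| - prod_products [X]^n / Keq)

with exponents equal to absolute stoichiometric coefficients.  Irreversible
reactions are flagged with ``Keq = inf``, which drops the reverse term.  This
convention makes the rate constant directly solvable from a steady-state
flux and concentration set (see :mod:`catpot.parameterize`).

Concentrations are mmol/L and time is hours throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import sympy
from scipy.integrate import solve_ivp

__all__ = [
    "Species",
    "Reaction",
    "KineticModel",
    "Trajectory",
    "ModelStructureError",
    "SimulationError",
    "build_model",
    "mass_action_rate",
    "simulate",
    "conserved_pools",
]


class ModelStructureError(ValueError):
    """Raised when a model violates a structural invariant."""


class SimulationError(RuntimeError):
    """Raised when the ODE integration fails.

    Attributes
    ----------
    last_good_time : float
        The last time point the solver reached before failing.
    """

    def __init__(self, message: str, last_good_time: float = 0.0):
        super().__init__(message)
        self.last_good_time = last_good_time


@dataclass
class Species:
    """A chemical species.

    ``fixed`` marks boundary species whose concentration is clamped during
    simulation (their ODE row is zeroed); they still enter rate laws at their
    constant concentration.
    """

    id: str
    name: str = ""
    initial_concentration: float = 0.0
    fixed: bool = False

    def __post_init__(self):
        if not self.id or not isinstance(self.id, str):
            raise ModelStructureError("species id must be a non-empty string")
        if not math.isfinite(self.initial_concentration) or self.initial_concentration < 0:
            raise ModelStructureError(
                f"species {self.id!r}: initial concentration must be finite and >= 0"
            )


@dataclass
class Reaction:
    """A mass-action reaction.

    ``stoichiometry`` maps species id to a signed coefficient (negative for
    reactants).  ``keq`` is the equilibrium constant in concentration units;
    ``math.inf`` marks an irreversible reaction.
    """

    id: str
    stoichiometry: dict[str, float]
    k: float = 0.0
    keq: float = math.inf

    def __post_init__(self):
        if not any(c < 0 for c in self.stoichiometry.values()):
            raise ModelStructureError(f"reaction {self.id!r} has no reactant")
        if self.k < 0 or not math.isfinite(self.k):
            raise ModelStructureError(f"reaction {self.id!r}: k must be finite and >= 0")
        if not self.keq > 0:
            raise ModelStructureError(f"reaction {self.id!r}: Keq must be positive (or inf)")

    @property
    def reversible(self) -> bool:
        return math.isfinite(self.keq)

    @property
    def reactants(self) -> dict[str, float]:
        return {s: -c for s, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {s: c for s, c in self.stoichiometry.items() if c > 0}


class KineticModel:
    """A reaction network with its stoichiometric matrix.

    Use :func:`build_model` to construct instances; it validates id
    uniqueness and cross-references.
    """

    def __init__(self, species: list[Species], reactions: list[Reaction]):
        ids = [s.id for s in species]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelStructureError(f"duplicate species ids: {dupes}")
        rids = [r.id for r in reactions]
        if len(set(rids)) != len(rids):
            dupes = sorted({i for i in rids if rids.count(i) > 1})
            raise ModelStructureError(f"duplicate reaction ids: {dupes}")
        known = set(ids)
        for r in reactions:
            unknown = set(r.stoichiometry) - known
            if unknown:
                raise ModelStructureError(
                    f"reaction {r.id!r} references unknown species: {sorted(unknown)}"
                )
        self.species: list[Species] = list(species)
        self.reactions: list[Reaction] = list(reactions)
        self.parameters: dict = {}
        self._sidx = {s.id: i for i, s in enumerate(self.species)}
        self._ridx = {r.id: j for j, r in enumerate(self.reactions)}
        n, m = len(species), len(reactions)
        S = np.zeros((n, m))
        for j, r in enumerate(reactions):
            for sid, c in r.stoichiometry.items():
                S[self._sidx[sid], j] = c
        self.S = S
        self._cache = None

    # -- lookups -----------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def species_index(self, sid: str) -> int:
        return self._sidx[sid]

    def reaction_index(self, rid: str) -> int:
        return self._ridx[rid]

    def get_species(self, sid: str) -> Species:
        return self.species[self._sidx[sid]]

    def get_reaction(self, rid: str) -> Reaction:
        return self.reactions[self._ridx[rid]]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._ridx

    def set_rate_constant(self, rid: str, k: float) -> None:
        if k < 0 or not math.isfinite(k):
            raise ModelStructureError(f"reaction {rid!r}: k must be finite and >= 0")
        self.reactions[self._ridx[rid]].k = k
        self._cache = None

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species])

    def set_initial_state(self, x0: dict[str, float] | np.ndarray) -> None:
        if isinstance(x0, dict):
            for sid, v in x0.items():
                self.species[self._sidx[sid]].initial_concentration = float(v)
        else:
            for s, v in zip(self.species, x0):
                s.initial_concentration = float(v)

    def copy(self) -> "KineticModel":
        species = [Species(s.id, s.name, s.initial_concentration, s.fixed) for s in self.species]
        reactions = [Reaction(r.id, dict(r.stoichiometry), r.k, r.keq) for r in self.reactions]
        m = KineticModel(species, reactions)
        m.parameters = dict(self.parameters)
        return m

    # -- vectorized rate law ----------------------------------------------
    def _arrays(self):
        """Precompute exponent matrices and constant vectors for rate evaluation."""
        if self._cache is None:
            n, m = self.S.shape
            Ar = np.zeros((m, n))  # reactant exponents
            Ap = np.zeros((m, n))  # product exponents
            k = np.zeros(m)
            inv_keq = np.zeros(m)
            for j, r in enumerate(self.reactions):
                k[j] = r.k
                inv_keq[j] = 0.0 if not r.reversible else 1.0 / r.keq
                for sid, c in r.stoichiometry.items():
                    i = self._sidx[sid]
                    if c < 0:
                        Ar[j, i] = -c
                    else:
                        Ap[j, i] = c
            dyn = np.array([not s.fixed for s in self.species])
            self._cache = (Ar, Ap, k, inv_keq, dyn)
        return self._cache

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Net mass-action rate of every reaction at state ``x`` (mmol/L/hr).

        Small negative excursions from the solver are clipped to zero before
        exponentiation.
        """
        Ar, Ap, k, inv_keq, _ = self._arrays()
        xc = np.maximum(np.asarray(x, dtype=float), 0.0)
        fwd = np.prod(xc[None, :] ** Ar, axis=1)
        rev = np.prod(xc[None, :] ** Ap, axis=1)
        return k * (fwd - inv_keq * rev)

    def ode_rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        _, _, _, _, dyn = self._arrays()
        dx = self.S @ self.rates(x)
        dx[~dyn] = 0.0
        return dx

    def ode_jac(self, t: float, x: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of :meth:`ode_rhs`.

        Exact whenever all concentrations are strictly positive; at zero
        concentrations the off-diagonal contribution of that species is
        dropped (a measure-zero edge the implicit solver tolerates).
        """
        Ar, Ap, k, inv_keq, dyn = self._arrays()
        xc = np.maximum(np.asarray(x, dtype=float), 0.0)
        xs = np.maximum(xc, 1e-300)
        fwd = np.prod(xc[None, :] ** Ar, axis=1)
        rev = np.prod(xc[None, :] ** Ap, axis=1)
        dv = (k[:, None] * (Ar * fwd[:, None] - inv_keq[:, None] * Ap * rev[:, None])) / xs[None, :]
        J = self.S @ dv
        J[~dyn, :] = 0.0
        return J

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "catpot-model-v1",
            "species": [
                {
                    "id": s.id,
                    "name": s.name,
                    "initial_concentration": s.initial_concentration,
                    "fixed": s.fixed,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": r.stoichiometry,
                    "k": r.k,
                    "keq": ("inf" if not r.reversible else r.keq),
                }
                for r in self.reactions
            ],
            "parameters": self.parameters,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticModel":
        species = [
            Species(s["id"], s.get("name", ""), s["initial_concentration"], s["fixed"])
            for s in d["species"]
        ]
        reactions = [
            Reaction(
                r["id"],
                {k: float(v) for k, v in r["stoichiometry"].items()},
                r["k"],
                math.inf if r["keq"] == "inf" else float(r["keq"]),
            )
            for r in d["reactions"]
        ]
        m = cls(species, reactions)
        m.parameters = dict(d.get("parameters", {}))
        return m

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "KineticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Trajectory:
    """Simulation output: time grid plus concentration and flux matrices."""

    times: np.ndarray                 # (T,) hr, strictly increasing
    concentrations: np.ndarray        # (n_species, T) mmol/L
    fluxes: np.ndarray                # (n_reactions, T) mmol/L/hr
    species_ids: list[str] = field(default_factory=list)
    reaction_ids: list[str] = field(default_factory=list)

    def conc(self, sid: str) -> np.ndarray:
        return self.concentrations[self.species_ids.index(sid)]

    def flux(self, rid: str) -> np.ndarray:
        return self.fluxes[self.reaction_ids.index(rid)]

    def final_state(self) -> np.ndarray:
        return self.concentrations[:, -1]

    def to_csv(self, conc_path, flux_path=None) -> None:
        """One row per timepoint; columns are time plus species (reaction) ids."""
        import pandas as pd

        pd.DataFrame(
            np.column_stack([self.times, self.concentrations.T]),
            columns=["time"] + self.species_ids,
        ).to_csv(conc_path, index=False)
        if flux_path is not None:
            pd.DataFrame(
                np.column_stack([self.times, self.fluxes.T]),
                columns=["time"] + self.reaction_ids,
            ).to_csv(flux_path, index=False)


def build_model(species: list[Species], reactions: list[Reaction]) -> KineticModel:
    """Assemble a :class:`KineticModel`, validating ids and stoichiometry."""
    return KineticModel(species, reactions)


def mass_action_rate(reaction: Reaction, state: dict[str, float]) -> float:
    """Net mass-action rate of a single reaction at the given concentrations.

    Raises if a participating species is missing from ``state`` or carries a
    negative concentration.
    """
    for sid in reaction.stoichiometry:
        if sid not in state:
            raise KeyError(f"species {sid!r} missing from state")
        if state[sid] < 0:
            raise ValueError(f"species {sid!r} has negative concentration {state[sid]}")
    fwd = 1.0
    for sid, n in reaction.reactants.items():
        fwd *= state[sid] ** n
    if not reaction.reversible:
        return reaction.k * fwd
    rev = 1.0
    for sid, n in reaction.products.items():
        rev *= state[sid] ** n
    return reaction.k * (fwd - rev / reaction.keq)


def default_time_grid(t_end: float, n_log: int = 300, n_lin: int = 400) -> np.ndarray:
    """Output grid for stiff relaxations: log-spaced early points (the fast
    binding transients) merged with a uniform grid over the full window."""
    log = np.geomspace(max(t_end * 1e-12, 1e-9), t_end, n_log)
    lin = np.linspace(0.0, t_end, n_lin)
    return np.unique(np.concatenate([[0.0], log, lin]))


def simulate(
    model: KineticModel,
    t_end: float,
    reltol: float = 1e-9,
    abstol: float = 1e-12,
    t_eval: np.ndarray | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate ``dx/dt = S v(x; k)`` to ``t_end`` with a stiff solver.

    Fixed species are clamped via zeroed ODE rows.  Kinetic models with
    explicit enzyme forms are stiff (rate constants span many orders of
    magnitude), so an implicit method with an analytic Jacobian is the
    default.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    x0 = model.initial_state()
    if np.any(x0 < 0):
        raise ValueError("negative initial concentration")
    if t_eval is None:
        t_eval = default_time_grid(t_end)
    sol = solve_ivp(
        model.ode_rhs,
        (0.0, float(t_end)),
        x0,
        method=method,
        t_eval=np.asarray(t_eval, dtype=float),
        rtol=reltol,
        atol=abstol,
        jac=model.ode_jac,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise SimulationError(f"integration failed: {sol.message}", last_good_time=last)
    conc = sol.y
    floor = -max(1e3 * abstol, 1e-9) * max(1.0, float(np.max(x0)))
    if conc.min() < floor:
        i, j = np.unravel_index(np.argmin(conc), conc.shape)
        raise SimulationError(
            f"negative concentration excursion for {model.species_ids[i]} "
            f"({conc[i, j]:.3e} at t={sol.t[j]:.3g} hr)",
            last_good_time=float(sol.t[j]),
        )
    conc = np.maximum(conc, 0.0)
    fluxes = np.empty((len(model.reactions), conc.shape[1]))
    for jt in range(conc.shape[1]):
        fluxes[:, jt] = model.rates(conc[:, jt])
    return Trajectory(sol.t, conc, fluxes, model.species_ids, model.reaction_ids)


def conserved_pools(model: KineticModel) -> list[dict[str, float]]:
    """Conserved moieties: a basis of the left null space of ``S`` restricted
    to non-clamped species.

    Each returned pool maps species id to a weight; the weighted concentration
    sum is invariant along any trajectory.  Weights are scaled to small
    integers when the rational basis allows it.
    """
    dyn = [i for i, s in enumerate(model.species) if not s.fixed]
    if not dyn:
        return []
    S_dyn = model.S[dyn, :]
    # exact rational arithmetic: float row reduction mis-detects rank
    M = sympy.Matrix(
        [[sympy.nsimplify(x, rational=True) for x in row] for row in S_dyn.T.tolist()]
    )
    basis = M.nullspace()
    pools = []
    for vec in basis:
        denoms = [sympy.fraction(sympy.nsimplify(v))[1] for v in vec]
        scale = sympy.lcm([sympy.Integer(d) for d in denoms]) if denoms else 1
        v = [sympy.nsimplify(val) * scale for val in vec]
        # flip so the first nonzero weight is positive
        first = next((x for x in v if x != 0), 1)
        if first < 0:
            v = [-x for x in v]
        pool = {
            model.species[dyn[i]].id: float(v[i]) for i in range(len(v)) if v[i] != 0
        }
        pools.append(pool)
    return pools


def pool_value(pool: dict[str, float], model: KineticModel, x: np.ndarray) -> float:
    """Weighted concentration sum of a conserved pool at state ``x``."""
    return float(sum(w * x[model.species_index(sid)] for sid, w in pool.items()))
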