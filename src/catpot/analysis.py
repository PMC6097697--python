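"""Catalytic-potential analytics.

The two systemic coordinates are the adenylate energy charge

    EC = ([ATP] + [ADP]/2) / ([ATP] + [ADP] + [AMP])

and, for each enzyme module, the catalytically active fraction

    f_A = sum(active forms) / E_total

where the active forms are every R-conformation (or monomer) species
carrying no dead-end inhibitor.  Plotting f_A against EC along a simulated
response to a step change in ATP utilization is the catalytic-potential
plot; the net rate of ATP usage (production minus consumption rate pools)
and its sum of squared deviations from the zero setpoint quantify
disturbance rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import KineticModel, Trajectory, simulate
from .network import set_atp_load

__all__ = [
    "energy_charge",
    "active_fraction",
    "energy_charge_series",
    "active_fraction_series",
    "net_atp_usage",
    "sse_disturbance",
    "CatPotCurve",
    "PerturbationResult",
    "perturb_atp_utilization",
    "phase_portrait",
    "fa_ec_correlation",
]


def energy_charge(atp: float, adp: float, amp: float) -> float:
    """Adenylate energy charge, in [0, 1]."""
    if atp < 0 or adp < 0 or amp < 0:
        raise ValueError("adenylate concentrations must be non-negative")
    pool = atp + adp + amp
    if pool == 0:
        raise ValueError("empty adenylate pool: energy charge undefined")
    return (atp + 0.5 * adp) / pool


def active_fraction(form_concentrations: dict[str, float], active_set,
                    e_total: float, tol: float = 1e-3) -> float:
    """Fraction of total enzyme in catalytically competent forms.

    Errors when the summed form concentrations break enzyme conservation by
    more than ``tol`` (relative).
    """
    total = sum(form_concentrations.values())
    if abs(total - e_total) > tol * e_total:
        raise ValueError(
            f"enzyme conservation breach: forms sum to {total:.6g}, "
            f"expected {e_total:.6g}")
    return sum(form_concentrations[f] for f in active_set) / e_total


def _module_info(model: KineticModel, enzyme: str) -> dict:
    mods = model.parameters.get("enzyme_modules", {})
    if enzyme not in mods:
        raise KeyError(f"model has no {enzyme!r} enzyme module")
    return mods[enzyme]


def energy_charge_series(traj: Trajectory) -> np.ndarray:
    atp, adp, amp = traj.conc("atp"), traj.conc("adp"), traj.conc("amp")
    return (atp + 0.5 * adp) / (atp + adp + amp)


def active_fraction_series(model: KineticModel, traj: Trajectory,
                           enzyme: str, tol: float = 1e-3) -> np.ndarray:
    info = _module_info(model, enzyme)
    rows = [traj.species_ids.index(f) for f in info["forms"]]
    total = traj.concentrations[rows, :].sum(axis=0)
    drift = np.max(np.abs(total - info["e_total"])) / info["e_total"]
    if drift > tol:
        raise ValueError(
            f"{enzyme}: enzyme conservation breach along trajectory "
            f"(relative drift {drift:.2e})")
    act_rows = [traj.species_ids.index(f) for f in info["active_set"]]
    return traj.concentrations[act_rows, :].sum(axis=0) / info["e_total"]


def net_atp_usage(model: KineticModel, traj: Trajectory,
                  species: str = "atp") -> np.ndarray:
    """Net rate of ATP formation minus consumption along a trajectory.

    Rate pools sum each reaction's net contribution to the metabolite's ODE
    (reverse microscopic fluxes are not split out); negative values mean net
    ATP consumption.  Zero at any steady state.
    """
    row = model.S[model.species_index(species), :]
    contrib = row[:, None] * traj.fluxes
    production = np.where(contrib > 0, contrib, 0.0).sum(axis=0)
    consumption = np.where(contrib < 0, -contrib, 0.0).sum(axis=0)
    return production - consumption


def sse_disturbance(series: np.ndarray, setpoint: float = 0.0) -> float:
    """Sum of squared deviations from the setpoint over an evaluation grid.

    Smaller means better disturbance rejection."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    return float(np.sum((series - setpoint) ** 2))


@dataclass
class CatPotCurve:
    """A catalytic-potential plot: f_A per enzyme against energy charge.

    Quadrants are defined relative to the initial (homeostatic) point:
    I  more enzyme active, higher energy charge;
    II more active, lower charge; III less active, lower charge;
    IV less active, higher charge.
    """

    times: np.ndarray
    energy_charge: np.ndarray
    fa: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def reference_point(self) -> dict[str, tuple[float, float]]:
        return {e: (float(self.energy_charge[0]), float(f[0]))
                for e, f in self.fa.items()}

    def quadrants(self, enzyme: str) -> np.ndarray:
        ec0, fa0 = self.energy_charge[0], self.fa[enzyme][0]
        more_active = self.fa[enzyme] > fa0
        higher_ec = self.energy_charge > ec0
        out = np.empty(self.times.shape, dtype="<U3")
        out[more_active & higher_ec] = "I"
        out[more_active & ~higher_ec] = "II"
        out[~more_active & ~higher_ec] = "III"
        out[~more_active & higher_ec] = "IV"
        return out


@dataclass
class PerturbationResult:
    """Outcome of one ATP-utilization step experiment."""

    factor: float
    trajectory: Trajectory
    curve: CatPotCurve
    net_atp: np.ndarray          # on the trajectory grid, mmol/L/hr
    sse: float                   # (mmol/L/hr)^2, on the uniform SSE grid
    sse_times: np.ndarray
    model: KineticModel


def perturb_atp_utilization(
    model: KineticModel,
    factor: float,
    t_end: float = 1000.0,
    n_uniform: int = 1000,
    reltol: float = 1e-9,
    abstol: float = 1e-12,
    pulse_duration: float | None = None,
) -> PerturbationResult:
    """Step the ATP-hydrolysis rate constant by ``factor`` at t = 0 and
    simulate to ``t_end`` (hours).

    The step is sustained for the whole window unless ``pulse_duration`` is
    given, in which case the rate constant reverts at that time and the
    remainder of the window shows the recovery.  The SSE of the net ATP
    usage is evaluated on a fixed uniform grid (``n_uniform`` points) so
    values are comparable across models; the trajectory itself is stored on
    a log+linear grid that resolves the fast binding transients.
    """
    perturbed = set_atp_load(model, factor)
    if pulse_duration is not None:
        if not 0 < pulse_duration < t_end:
            raise ValueError("pulse_duration must lie inside (0, t_end)")
        first = simulate(perturbed, pulse_duration, reltol=reltol, abstol=abstol)
        recovered = model.copy()
        recovered.set_initial_state(first.final_state())
        second = simulate(recovered, t_end - pulse_duration,
                          reltol=reltol, abstol=abstol)
        times = np.concatenate([first.times, pulse_duration + second.times[1:]])
        conc = np.concatenate([first.concentrations,
                               second.concentrations[:, 1:]], axis=1)
        flux = np.concatenate([first.fluxes, second.fluxes[:, 1:]], axis=1)
        traj = type(first)(times, conc, flux, first.species_ids, first.reaction_ids)
    else:
        traj = simulate(perturbed, t_end, reltol=reltol, abstol=abstol)
    ec = energy_charge_series(traj)
    fa = {e: active_fraction_series(perturbed, traj, e)
          for e in perturbed.parameters.get("enzyme_modules", {})}
    curve = CatPotCurve(traj.times, ec, fa)
    net = net_atp_usage(perturbed, traj)
    sse_times = np.linspace(0.0, t_end, n_uniform)
    sse = sse_disturbance(np.interp(sse_times, traj.times, net))
    return PerturbationResult(factor, traj, curve, net, sse, sse_times, perturbed)


def fa_ec_correlation(result: PerturbationResult, enzyme: str) -> float:
    """Spearman rank correlation between f_A(enzyme) and the energy charge
    over the post-perturbation trajectory."""
    rho = stats.spearmanr(result.curve.fa[enzyme], result.curve.energy_charge).statistic
    return float(rho)


@dataclass
class PhasePortrait:
    enzymes: tuple[str, str]
    fa_x: np.ndarray
    fa_y: np.ndarray
    correlation: float

    @property
    def association_sign(self) -> int:
        return int(np.sign(self.correlation))


def phase_portrait(result: PerturbationResult,
                   enzyme_pair: tuple[str, str]) -> PhasePortrait:
    """Pairwise f_A trajectory for two kinases plus their rank correlation."""
    e1, e2 = enzyme_pair
    for e in (e1, e2):
        if e not in result.curve.fa:
            raise KeyError(f"enzyme {e!r} has no module in this model")
    x, y = result.curve.fa[e1], result.curve.fa[e2]
    if e1 == e2:
        rho = 1.0
    else:
        rho = float(stats.spearmanr(x, y).statistic)
    return PhasePortrait((e1, e2), x, y, rho)
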