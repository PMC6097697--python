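"""Catalytic-potential and phase-portrait figures."""

from __future__ import annotations

import numpy as np

from .analysis import PerturbationResult, PhasePortrait


def plot_catalytic_potential(result: PerturbationResult, enzyme: str, ax=None,
                             **kwargs):
    """f_A against energy charge, with the homeostatic reference point marked.

    Quadrant guides (relative to the initial steady state) follow the usual
    reading: I more active/higher charge, II more active/lower charge,
    III less active/lower charge, IV less active/higher charge.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ec = result.curve.energy_charge
    fa = result.curve.fa[enzyme]
    ax.plot(ec, fa, **{"lw": 1.2, **kwargs})
    ax.axvline(ec[0], color="0.6", lw=0.8)
    ax.axhline(fa[0], color="0.6", lw=0.8)
    ax.plot([ec[0]], [fa[0]], "o", color="k", ms=4)
    ax.set_xlabel("energy charge")
    ax.set_ylabel(f"$f_A$ ({enzyme})")
    ax.set_title(f"{enzyme}, ATP load x{result.factor:g}")
    return ax


def plot_phase_portrait(portrait: PhasePortrait, ax=None, **kwargs):
    """Pairwise active-fraction trajectory for two kinases."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(portrait.fa_x, portrait.fa_y, **{"lw": 1.2, **kwargs})
    ax.plot([portrait.fa_x[0]], [portrait.fa_y[0]], "o", color="k", ms=4)
    e1, e2 = portrait.enzymes
    ax.set_xlabel(f"$f_A$ ({e1})")
    ax.set_ylabel(f"$f_A$ ({e2})")
    sign = "+" if portrait.correlation >= 0 else "-"
    ax.set_title(f"{e1} vs {e2} ({sign})")
    return ax


def plot_net_atp(result: PerturbationResult, ax=None, t_max: float | None = None,
                 **kwargs):
    """Net rate of ATP usage against time (zero setpoint dashed)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = result.trajectory.times
    mask = np.ones_like(t, dtype=bool) if t_max is None else t <= t_max
    ax.plot(t[mask], result.net_atp[mask], **{"lw": 1.2, **kwargs})
    ax.axhline(0.0, color="0.6", ls="--", lw=0.8)
    ax.set_xlabel("time (hr)")
    ax.set_ylabel("net ATP usage (mmol/L/hr)")
    ax.set_title(f"SSE = {result.sse:.3g}")
    return ax
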