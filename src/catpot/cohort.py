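"""Cohort robustness analysis and Dixon's Q outlier screening.

A cohort is a set of individuals (personalized or randomized reference
states), each parameterized into its own glycolysis + RL shunt + hemoglobin
+ PFK-module model.  Collecting each reaction's pseudo-elementary rate
constant across individuals gives per-reaction PERC vectors; Dixon's Q test

    Q = gap / range

(gap: distance from the suspect point to its nearest neighbour; range: full
spread) flags rate constants for which one individual deviates from the
rest.  Critical values for the two-sided test are estimated by Monte-Carlo
simulation of the null (iid standard normal samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline import build_rbc_model
from .synth import Individual

__all__ = [
    "CohortTable",
    "DixonResult",
    "build_cohort",
    "dixon_q",
    "dixon_critical_value",
    "screen_outlier_percs",
]


@dataclass
class DixonResult:
    parameter: str
    q: float
    suspect: str                 # individual label
    critical_value: float | None = None
    outlier: bool = False
    note: str = ""


@dataclass
class CohortTable:
    """Per-individual models and the PERC matrix across the cohort."""

    individuals: list[Individual]
    perc_tables: dict[str, dict[str, float]]       # label -> reaction -> k
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return [ind.label for ind in self.individuals]

    def perc_matrix(self) -> pd.DataFrame:
        """Rows: reactions/parameters; columns: individuals."""
        return pd.DataFrame(self.perc_tables)

    def perc_vector(self, parameter: str) -> pd.Series:
        return self.perc_matrix().loc[parameter]


def build_cohort(source, enzyme_modules: tuple[str, ...] = ("PFK",)) -> CohortTable:
    """Parameterize one model per individual and assemble the PERC table.

    ``source`` is a list of :class:`~catpot.synth.Individual`.  Individuals
    whose reference state cannot be parameterized (thermodynamic
    infeasibility, module solve failure) are excluded with a logged reason
    rather than aborting the cohort.
    """
    individuals: list[Individual] = list(source)
    kept: list[Individual] = []
    tables: dict[str, dict[str, float]] = {}
    excluded: dict[str, str] = {}
    for ind in individuals:
        try:
            model = build_rbc_model(ind.ref, enzyme_modules,
                                    module_overrides=ind.module_overrides)
        except Exception as exc:  # noqa: BLE001 - any failure excludes, with reason
            excluded[ind.label] = str(exc)
            continue
        kept.append(ind)
        tables[ind.label] = {r.id: r.k for r in model.reactions}
    return CohortTable(kept, tables, excluded)


def dixon_q(values, suspect_index: int | None = None) -> tuple[float, int]:
    """Dixon's Q = gap/range for the suspect point.

    The suspect defaults to the value farthest from the median.  Returns
    ``(Q, suspect_index)``.  Errors for fewer than three values or zero
    range.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Dixon's Q needs at least 3 values")
    rng = float(np.max(x) - np.min(x))
    if rng == 0:
        raise ValueError("zero range: Dixon's Q undefined")
    if suspect_index is None:
        suspect_index = int(np.argmax(np.abs(x - np.median(x))))
    others = np.delete(x, suspect_index)
    gap = float(np.min(np.abs(others - x[suspect_index])))
    return gap / rng, suspect_index


def dixon_critical_value(n: int, confidence: float = 0.99,
                         reps: int = 1_000_000,
                         rng_seed: int | np.random.Generator = 0) -> float:
    """Monte-Carlo critical value of the two-sided Dixon Q statistic.

    Draws ``reps`` samples of ``n`` iid standard normals, computes
    ``Q = max(x(2)-x(1), x(n)-x(n-1)) / (x(n)-x(1))`` for each and returns
    the ``confidence`` quantile of the null distribution.  For n = 9 at 99%
    this reproduces the tabulated two-sided value 0.598 to within Monte-Carlo
    error.
    """
    if n < 3:
        raise ValueError("n must be at least 3")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    qs = np.empty(reps)
    # chunked so memory stays modest at 1e6 reps
    chunk = max(1, min(reps, 200_000))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        x = np.sort(rng.standard_normal((m, n)), axis=1)
        span = x[:, -1] - x[:, 0]
        qs[done:done + m] = np.maximum(x[:, 1] - x[:, 0],
                                       x[:, -1] - x[:, -2]) / span
        done += m
    return float(np.quantile(qs, confidence))


def screen_outlier_percs(cohort: CohortTable, confidence: float = 0.99,
                         critical_value: float | None = None,
                         reps: int = 200_000,
                         rng_seed: int = 0,
                         constant_rtol: float = 1e-9) -> list[DixonResult]:
    """Dixon-screen every per-reaction PERC vector across the cohort.

    Vectors that are numerically constant across individuals carry no
    information for the test and are reported with a note instead of a Q
    value.  Returns one :class:`DixonResult` per parameter, outliers flagged
    when Q exceeds the critical value at the requested confidence.
    """
    if len(cohort.individuals) < 3:
        raise ValueError("outlier screening needs at least 3 individuals")
    mat = cohort.perc_matrix()
    n = mat.shape[1]
    if critical_value is None:
        critical_value = dixon_critical_value(n, confidence, reps, rng_seed)
    results: list[DixonResult] = []
    labels = list(mat.columns)
    for param, row in mat.iterrows():
        x = row.to_numpy(dtype=float)
        scale = np.max(np.abs(x))
        if scale == 0 or (np.max(x) - np.min(x)) <= constant_rtol * scale:
            results.append(DixonResult(param, np.nan, "", critical_value,
                                       False, "constant across cohort; skipped"))
            continue
        q, idx = dixon_q(x)
        results.append(DixonResult(param, q, labels[idx], critical_value,
                                   q > critical_value))
    return results
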