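"""Fixation-time analysis for an advantageous clone in the HSC compartment.

The headline quantity is the expected time for a single mutant cell of
relative fitness r > 1 to take over a compartment of N stem cells,
conditioned on takeover. For large compartments it is evaluated with the
closed-form sweep approximation

    T(N, r) ~= N * ln(N) * (r + 1) / (r - 1)   iterations,

obtained from the deterministic limit of the Moran chain (integrating the
expected per-iteration frequency change from 1/N to 1 - 1/N). The
expression requires r > 1 and a single founder; it approximates the
*conditional* fixation time (see ``approximation_quality_report``, which
measures its signed deviation from the exact conditional solver and, for
reference, from the unconditional absorption time). Calendar time attaches
via one iteration = 1 / (division_rate * N) years, i.e. the whole
compartment turns over in 1/division_rate.

The per-sample scenario compares fixation times with and without
CXCL8-mediated suppression of wild-type cells: CXCL8 lowers the healthy
mean growth rate, raising the mutant's relative fitness and shortening the
predicted takeover time. The sensitivity grid quantifies |dT/dr| and shows
that, across the plausible compartment sizes, fixation times respond most
strongly to fitness changes just above r = 1 — exactly the range observed
for CMML CD34+ cells (r < 2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .growth import HealthyCohortSummary
from . import moran
from .moran import MoranParameters

__all__ = [
    "ScenarioResult",
    "NO_TAKEOVER",
    "approximate_fixation_time",
    "iterations_to_years",
    "fixation_years",
    "fixation_for_sample",
    "scenario_from_fitness",
    "sensitivity_grid",
    "approximation_quality_report",
    "DEFAULT_N_GRID",
    "DEFAULT_R_GRID",
]

#: Sentinel for branches with r <= 1, where no takeover is predicted.
NO_TAKEOVER = "no takeover predicted"

DEFAULT_N_GRID = (25_000, 100_000, 1_300_000)
DEFAULT_R_GRID = tuple(np.round(np.arange(1.05, 2.0001, 0.05), 2))
DEFAULT_DIVISION_RATES = (1.0,)


@dataclass(frozen=True)
class ScenarioResult:
    """Per-sample with/without-CXCL8 fixation comparison.

    ``fixation_years_*`` hold the sentinel string ``NO_TAKEOVER`` when the
    corresponding fitness does not exceed 1; ``speedup_factor`` (time
    without / time with CXCL8) is defined only when both branches predict
    takeover.
    """

    sample_id: str
    r_without_cxcl8: float
    r_with_cxcl8: float
    fixation_years_without: float | str
    fixation_years_with: float | str
    speedup_factor: float | None
    method: str


def approximate_fixation_time(params: MoranParameters) -> float:
    """Closed-form fixation time N*ln(N)*(r+1)/(r-1), in iterations.

    Valid only for an advantageous single founder (r > 1, one initial
    mutant).
    """
    if params.r <= 1.0:
        raise InvalidParameterError(
            "the closed-form fixation time requires r > 1 "
            f"(got r = {params.r}); neutral or deleterious clones are not expected to fix"
        )
    if params.initial_mutants != 1:
        raise InvalidParameterError(
            "the closed-form fixation time assumes a single founder cell "
            f"(initial_mutants = 1, got {params.initial_mutants})"
        )
    N, r = params.N, params.r
    return N * math.log(N) * (r + 1.0) / (r - 1.0)


def iterations_to_years(iterations: float, params: MoranParameters) -> float:
    """Convert Moran iterations to years: one iteration = 1/(division_rate*N)."""
    if iterations < 0:
        raise InvalidParameterError("iterations must be >= 0")
    return iterations / (params.division_rate * params.N)


def fixation_years(
    params: MoranParameters,
    method: str = "auto",
    replicates: int = 2_000,
    rng_seed: int = 0,
) -> float:
    """Conditional fixation time in years by the requested method.

    ``auto`` uses the exact chain solver up to its size limit and the
    analytic approximation above it; ``exact``/``mc``/``analytic`` force a
    method. Monte-Carlo conditions on the fixing replicates.
    """
    if method == "auto":
        method = "exact" if params.N <= moran.EXACT_SOLVER_LIMIT else "analytic"
    if method in ("analytic", "analytic_eq2"):
        iterations = approximate_fixation_time(params)
    elif method in ("exact", "exact_chain"):
        iterations = moran.exact_conditional_fixation_time(params)
    elif method in ("mc", "monte_carlo"):
        est = moran.simulate_fixation(params, replicates, rng_seed)
        if est.mean_conditional_iterations is None:
            raise InvalidParameterError("no fixing replicate; increase replicates or r")
        iterations = est.mean_conditional_iterations
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    return iterations_to_years(iterations, params)


def fixation_for_sample(
    g_cmml: float,
    healthy_with: HealthyCohortSummary,
    healthy_without: HealthyCohortSummary,
    params_template: MoranParameters | None = None,
    method: str = "auto",
    sample_id: str = "sample",
    replicates: int = 2_000,
    rng_seed: int = 0,
) -> ScenarioResult:
    """Fixation scenario for one CMML growth rate against both conditions.

    The same measured growth rate ``g_cmml`` is normalised by the healthy
    mean with and without CXCL8 (CXCL8 suppresses healthy but not CMML
    cells, so the mutant rate itself is unchanged while its relative
    fitness rises). Branches with r <= 1 report ``NO_TAKEOVER``.
    """
    if params_template is None:
        params_template = MoranParameters(N=moran.DEFAULT_N, r=1.5)
    r_with = g_cmml / healthy_with.mean_rate
    r_without = g_cmml / healthy_without.mean_rate
    return scenario_from_fitness(
        sample_id, r_without, r_with, params_template, method, replicates, rng_seed
    )


def scenario_from_fitness(
    sample_id: str,
    r_without: float,
    r_with: float,
    params_template: MoranParameters,
    method: str = "auto",
    replicates: int = 2_000,
    rng_seed: int = 0,
) -> ScenarioResult:
    """Build a :class:`ScenarioResult` from already-computed fitness values."""

    def branch(r: float, seed: int) -> float | str:
        if r <= 1.0:
            return NO_TAKEOVER
        params = replace(params_template, r=r, initial_mutants=1)
        return fixation_years(params, method=method, replicates=replicates, rng_seed=seed)

    years_without = branch(r_without, rng_seed)
    years_with = branch(r_with, rng_seed + 1)
    speedup = (
        years_without / years_with
        if isinstance(years_without, float) and isinstance(years_with, float)
        else None
    )
    resolved = method
    if method == "auto":
        resolved = "exact_chain" if params_template.N <= moran.EXACT_SOLVER_LIMIT else "analytic_eq2"
    return ScenarioResult(
        sample_id=sample_id,
        r_without_cxcl8=r_without,
        r_with_cxcl8=r_with,
        fixation_years_without=years_without,
        fixation_years_with=years_with,
        speedup_factor=speedup,
        method=resolved,
    )


def sensitivity_grid(
    r_values: tuple[float, ...] = DEFAULT_R_GRID,
    N_values: tuple[int, ...] = DEFAULT_N_GRID,
    division_rates: tuple[float, ...] = DEFAULT_DIVISION_RATES,
    method: str = "analytic",
) -> pd.DataFrame:
    """Fixation years over an (r, N, division-rate) grid with |dT/dr|.

    ``local_sensitivity`` is the central finite difference of fixation
    years with respect to r (one-sided at the grid edges; NaN with a
    warning on a single-point r axis). The r value maximising |dT/dr| is
    flagged per (N, division_rate) cell in ``max_sensitivity_flag``.
    """
    r_arr = np.asarray(r_values, dtype=float)
    N_arr = np.asarray(N_values)
    d_arr = np.asarray(division_rates, dtype=float)
    if np.any(r_arr <= 1.0):
        raise InvalidParameterError("all r values on the sensitivity grid must exceed 1")
    for name, arr in (("r_values", r_arr), ("N_values", N_arr), ("division_rates", d_arr)):
        if arr.size > 1 and np.any(np.diff(arr.astype(float)) <= 0):
            raise InvalidParameterError(f"{name} must be strictly ascending")
    if r_arr.size < 2:
        warnings.warn(
            "single-point r axis: local sensitivity to r is undefined",
            RuntimeWarning,
            stacklevel=2,
        )

    frames = []
    for N in N_arr:
        for d in d_arr:
            years = np.array(
                [
                    fixation_years(MoranParameters(N=int(N), r=float(r), division_rate=float(d)), method=method)
                    for r in r_arr
                ]
            )
            sens = np.full(r_arr.size, np.nan) if r_arr.size < 2 else np.abs(np.gradient(years, r_arr))
            frame = pd.DataFrame(
                {
                    "N": int(N),
                    "division_rate": float(d),
                    "r": r_arr,
                    "fixation_years": years,
                    "local_sensitivity": sens,
                }
            )
            frame["max_sensitivity_flag"] = False
            if r_arr.size >= 2:
                frame.loc[frame["local_sensitivity"].idxmax(), "max_sensitivity_flag"] = True
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def approximation_quality_report(
    N_values: tuple[int, ...] = (50, 100, 200, 500),
    r_values: tuple[float, ...] = (1.1, 1.2, 1.35, 1.5, 1.75, 2.0),
) -> pd.DataFrame:
    """Signed relative deviation of the closed form from the exact solvers.

    For each (N, r), reports the approximation, the exact conditional
    fixation time, the exact unconditional absorption time, and the signed
    relative deviation of the approximation from each. Used to document
    that the closed form approximates the conditional time and that its
    error varies smoothly (no sign-flipping noise) across the grid.
    """
    rows = []
    for N in N_values:
        for r in r_values:
            params = MoranParameters(N=int(N), r=float(r))
            approx = approximate_fixation_time(params)
            exact_cond = moran.exact_conditional_fixation_time(params)
            exact_uncond = moran.exact_unconditional_absorption_time(params)
            rows.append(
                {
                    "N": int(N),
                    "r": float(r),
                    "approx_iterations": approx,
                    "exact_conditional_iterations": exact_cond,
                    "exact_unconditional_iterations": exact_uncond,
                    "rel_dev_conditional": (approx - exact_cond) / exact_cond,
                    "rel_dev_unconditional": (approx - exact_uncond) / exact_uncond,
                }
            )
    return pd.DataFrame(rows)
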