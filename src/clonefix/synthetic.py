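"""Synthetic liquid-culture cohorts with known ground truth.

Emulates the study design the estimators assume: CD34+ cells seeded at
0.75e5 cells/mL, counted at 0 and 72 h, for a small healthy cohort
(3 donors per CXCL8 condition) and a larger CMML cohort (19 patients).
Healthy growth rates are drawn per condition from a normal distribution
truncated at 0 (defaults 1.54 +/- 0.09 per day without CXCL8, 1.17 +/- 0.13
with 10 ng/mL CXCL8, daily-fold convention). Each CMML sample draws one
relative fitness uniformly from a band (default [1.08, 1.67]) and its rate
under each condition is that fitness times the condition's healthy mean
rate, so the generating fitness is recoverable exactly from noise-free
data.

Counts follow the exponential growth law from the seed density, with an
independent multiplicative lognormal factor per later timepoint whose
coefficient of variation is ``noise_cv`` (counts are positive and their
error scales with magnitude; the time-0 count is the seed density exactly).
A truth table of generating rates and fitnesses accompanies every cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError
from .growth import CONDITIONS, HOURS_PER_DAY, CountSeries

__all__ = ["CohortConfig", "generate_count_series", "generate_cohort", "write_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator settings (defaults mirror the study design)."""

    n_healthy: int = 3
    n_cmml: int = 19
    healthy_mean_no_cxcl8: float = 1.54
    healthy_sd_no_cxcl8: float = 0.09
    healthy_mean_cxcl8: float = 1.17
    healthy_sd_cxcl8: float = 0.13
    cmml_fitness_low: float = 1.08
    cmml_fitness_high: float = 1.67
    seed_density: float = 0.75e5  # cells/mL
    timepoints: tuple[float, ...] = (0.0, 72.0)  # hours
    noise_cv: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 1:
            raise InvalidParameterError("n_healthy must be >= 1 (fitness needs a denominator)")
        if self.n_cmml < 0:
            raise InvalidParameterError("n_cmml must be >= 0")
        for name in ("healthy_mean_no_cxcl8", "healthy_mean_cxcl8", "seed_density"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        for name in ("healthy_sd_no_cxcl8", "healthy_sd_cxcl8", "noise_cv"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.cmml_fitness_low > self.cmml_fitness_high:
            raise InvalidParameterError("cmml_fitness_low must not exceed cmml_fitness_high")
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise InvalidParameterError("timepoints must be strictly ascending with first = 0")


def _lognormal_factors(cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_count_series(
    growth_rate: float,
    seed_density: float,
    timepoints: tuple[float, ...],
    noise_cv: float,
    rng_seed: int | np.random.Generator,
    *,
    sample_id: str = "synthetic",
    group: str = "healthy",
    condition: str = "control",
) -> CountSeries:
    """Counts for one culture under the exponential daily-fold growth law.

    The noise-free trajectory is ``seed_density * growth_rate**(t/24h)``;
    every timepoint after 0 is multiplied by an independent unit-mean
    lognormal factor with coefficient of variation ``noise_cv``. The time-0
    count equals the seed density exactly.
    """
    if not growth_rate > 0:
        raise InvalidParameterError(f"growth_rate must be positive, got {growth_rate!r}")
    if not seed_density > 0:
        raise InvalidParameterError(f"seed_density must be positive, got {seed_density!r}")
    t = np.asarray(timepoints, dtype=float)
    if t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise InvalidParameterError("timepoints must be strictly ascending with first = 0")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    counts = seed_density * growth_rate ** (t / HOURS_PER_DAY)
    counts[1:] *= _lognormal_factors(noise_cv, t.size - 1, rng)
    counts[0] = seed_density
    return CountSeries(
        sample_id=sample_id,
        group=group,
        condition=condition,
        timepoints=tuple(t.tolist()),
        counts=tuple(counts.tolist()),
    )


def _truncated_normal(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd  # truncate at 0: rates are strictly positive
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort's count table and its hidden-truth table.

    Returns
    -------
    counts
        Long-format table: sample_id, group, condition, time_h,
        count_cells_per_ml — one row per timepoint.
    truth
        Generating values: sample_id, group, condition, true_rate,
        true_fitness (fitness relative to the condition's healthy *mean*
        parameter; NaN-free, healthy samples carry their own rate ratio).
    """
    rng = np.random.default_rng(config.rng_seed)
    cond_params = {
        "control": (config.healthy_mean_no_cxcl8, config.healthy_sd_no_cxcl8),
        "cxcl8": (config.healthy_mean_cxcl8, config.healthy_sd_cxcl8),
    }
    records: list[dict] = []
    truth_rows: list[dict] = []

    healthy_rates = {
        cond: _truncated_normal(mean, sd, config.n_healthy, rng)
        for cond, (mean, sd) in cond_params.items()
    }
    cmml_fitness = rng.uniform(config.cmml_fitness_low, config.cmml_fitness_high, config.n_cmml)

    def emit(sample_id: str, group: str, condition: str, rate: float, fitness: float) -> None:
        series = generate_count_series(
            rate,
            config.seed_density,
            config.timepoints,
            config.noise_cv,
            rng,
            sample_id=sample_id,
            group=group,
            condition=condition,
        )
        for t, c in zip(series.timepoints, series.counts):
            records.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "condition": condition,
                    "time_h": t,
                    "count_cells_per_ml": c,
                }
            )
        truth_rows.append(
            {
                "sample_id": sample_id,
                "group": group,
                "condition": condition,
                "true_rate": rate,
                "true_fitness": fitness,
            }
        )

    for cond in CONDITIONS:
        mean_cond = cond_params[cond][0]
        for i, rate in enumerate(healthy_rates[cond]):
            emit(f"healthy_{i + 1:02d}", "healthy", cond, float(rate), float(rate / mean_cond))
        for j, f in enumerate(cmml_fitness):
            emit(f"cmml_{j + 1:02d}", "cmml", cond, float(f * mean_cond), float(f))

    return pd.DataFrame.from_records(records), pd.DataFrame.from_records(truth_rows)


def write_cohort(
    config: CohortConfig, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write counts CSV, truth CSV and a JSON sidecar manifest; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, truth = generate_cohort(config)
    counts_path = out / "counts.csv"
    truth_path = out / "truth.csv"
    manifest_path = out / "cohort_manifest.json"
    counts.to_csv(counts_path, index=False)
    truth.to_csv(truth_path, index=False)
    manifest = {
        "generator": "clonefix.synthetic.generate_cohort",
        "rng_seed": config.rng_seed,
        "config": dataclasses.asdict(config),
        "outputs": [counts_path.name, truth_path.name],
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=list) + "\n")
    return counts_path, truth_path, manifest_path
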