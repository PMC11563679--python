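"""End-to-end analysis pipeline and its configuration.

Stages: counts (read or synthesised) -> per-sample growth rates ->
healthy-cohort summaries -> relative fitness with the advantageous-subset
report -> per-CMML-sample fixation scenarios (with vs without CXCL8) ->
sensitivity grid -> manifest. Configuration is a nested key/value file
(YAML); unknown keys are rejected to guard against silent typos.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import fixation, io, moran, synthetic
from .errors import ConfigError
from .growth import (
    CONDITIONS,
    GrowthRateEstimate,
    estimate_growth_rate,
    fitness_table,
    summarize_healthy,
)

__all__ = ["GrowthConfig", "MoranConfig", "PipelineConfig", "load_config", "run_pipeline"]

log = logging.getLogger("clonefix")


@dataclass(frozen=True)
class GrowthConfig:
    convention: str = "fold"  # or "log"
    use_regression: bool = False


@dataclass(frozen=True)
class MoranConfig:
    N: int = moran.DEFAULT_N
    division_rate: float = moran.DEFAULT_DIVISION_RATE
    method: str = "auto"  # auto | analytic | exact | mc
    replicates: int = 2_000


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration; ``counts_path`` switches off synthesis."""

    counts_path: str | None = None
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    moran: MoranConfig = field(default_factory=MoranConfig)
    sensitivity_r: tuple[float, ...] = fixation.DEFAULT_R_GRID
    sensitivity_N: tuple[int, ...] = fixation.DEFAULT_N_GRID
    sensitivity_division_rates: tuple[float, ...] = (1.0,)


def _from_mapping(cls, data: dict, context: str):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - field_names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {context}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in ("cohort", "growth", "moran"):
            sub_cls = {"cohort": synthetic.CohortConfig, "growth": GrowthConfig, "moran": MoranConfig}[f.name]
            if not isinstance(value, dict):
                raise ConfigError(f"section {context}.{f.name} must be a mapping")
            value = _from_mapping(sub_cls, value, f"{context}.{f.name}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys raise :class:`ConfigError`.

    ``overrides`` (e.g. a seed from the command line) are applied on top as
    a nested mapping.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = loaded
    for key, value in (overrides or {}).items():
        parts = key.split(".")
        node = data
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    return _from_mapping(PipelineConfig, data, "pipeline")


def run_pipeline(config: PipelineConfig, out_dir: str | Path, seed: int | None = None) -> Path:
    """Run the full analysis; write all output tables and the manifest.

    ``seed`` overrides the cohort's rng_seed when synthesising data (it has
    no effect when ``counts_path`` is given and the fixation method is
    deterministic). Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds: dict[str, int] = {}
    inputs: list[Path] = []
    outputs: list[Path] = []

    if config.counts_path is not None:
        log.info("reading counts from %s", config.counts_path)
        series = io.read_counts_table(config.counts_path)
        inputs.append(Path(config.counts_path))
        truth = None
    else:
        cohort_cfg = config.cohort
        if seed is not None:
            cohort_cfg = dataclasses.replace(cohort_cfg, rng_seed=seed)
        seeds["cohort"] = cohort_cfg.rng_seed
        log.info("synthesising cohort (seed=%d)", cohort_cfg.rng_seed)
        counts_path, truth_path, _ = synthetic.write_cohort(cohort_cfg, out)
        outputs += [counts_path, truth_path]
        series = io.read_counts_table(counts_path)
        truth = pd.read_csv(truth_path)

    log.info("estimating growth rates for %d series", len(series))
    rates = [
        estimate_growth_rate(s, convention=config.growth.convention, use_regression=config.growth.use_regression)
        for s in series
    ]
    groups = {s.sample_id: s.group for s in series}
    rates_df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rates],
            "condition": [r.condition for r in rates],
            "rate": [r.rate for r in rates],
        }
    )
    rates_path = out / "rates.csv"
    rates_df.to_csv(rates_path, index=False)
    outputs.append(rates_path)

    healthy = [r for r in rates if groups[r.sample_id] == "healthy"]
    conditions = [c for c in CONDITIONS if any(r.condition == c for r in rates)]
    summaries = {c: summarize_healthy(healthy, c) for c in conditions}
    summary_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries.values()])
    summary_path = out / "healthy_summary.csv"
    summary_df.to_csv(summary_path, index=False)
    outputs.append(summary_path)

    table, report = fitness_table(rates, summaries, groups)
    fitness_path = out / "fitness.csv"
    table.to_csv(fitness_path, index=False)
    outputs.append(fitness_path)

    mcfg = config.moran
    scenario_rows = []
    cmml_fit = table[table["group"] == "cmml"]
    mc_seed_base = seed if seed is not None else config.cohort.rng_seed
    for i, (sample_id, sub) in enumerate(cmml_fit.groupby("sample_id", sort=True)):
        by_cond = dict(zip(sub["condition"], sub["r"]))
        r_without = by_cond.get("control")
        r_with = by_cond.get("cxcl8", r_without)
        if r_without is None:
            r_without = r_with
        template = moran.MoranParameters(N=mcfg.N, r=1.5, division_rate=mcfg.division_rate)
        result = fixation.scenario_from_fitness(
            sample_id,
            float(r_without),
            float(r_with),
            template,
            method=mcfg.method,
            replicates=mcfg.replicates,
            rng_seed=mc_seed_base * 1_000 % (2**31 - 1) + 2 * i,
        )
        scenario_rows.append(dataclasses.asdict(result))
    scenario_df = pd.DataFrame(scenario_rows)
    scenario_path = out / "scenarios.csv"
    scenario_df.to_csv(scenario_path, index=False)
    outputs.append(scenario_path)

    grid = fixation.sensitivity_grid(
        r_values=config.sensitivity_r,
        N_values=config.sensitivity_N,
        division_rates=config.sensitivity_division_rates,
        method="analytic",
    )
    grid_path = out / "sensitivity_grid.csv"
    grid.to_csv(grid_path, index=False)
    outputs.append(grid_path)

    report_path = out / "advantageous_report.json"
    pd.Series(report, dtype=object).to_json(report_path, indent=2)
    outputs.append(report_path)

    if truth is not None:
        merged = table.merge(truth, on=["sample_id", "condition"], suffixes=("", "_true"))
        recovery = (merged["r"] - merged["true_fitness"]).abs() / merged["true_fitness"]
        log.info("median absolute relative fitness error vs truth: %.4g", recovery.median())

    manifest = io.write_manifest(
        out, command="pipeline", config=config, seeds=seeds, inputs=inputs, outputs=outputs
    )
    log.info("pipeline complete: %s", manifest)
    return manifest
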