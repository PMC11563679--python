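"""Table I/O and run manifests.

All tables are plain CSV: comma-separated, header row, "." decimal, UTF-8,
no thousands separators. Counts tables use the long-format schema
(sample_id, group, condition, time_h, count_cells_per_ml); one
:class:`~clonefix.growth.CountSeries` is formed per (sample_id, condition)
after time-sorting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .growth import CONDITIONS, GROUPS, CountSeries

__all__ = ["COUNTS_COLUMNS", "read_counts_table", "write_counts_table", "write_manifest"]

COUNTS_COLUMNS = ("sample_id", "group", "condition", "time_h", "count_cells_per_ml")


def read_counts_table(path: str | Path) -> list[CountSeries]:
    """Read a counts CSV into one CountSeries per (sample_id, condition).

    Raises :class:`SchemaError` naming the offending column/row for missing
    columns, non-numeric or negative counts, and duplicate
    (sample, condition, time) rows.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col in ("time_h", "count_cells_per_ml"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) or df[col].isna().any():
            row = int(bad[0]) if len(bad) else int(df.index[df[col].isna()][0])
            raise SchemaError(f"{path}: non-numeric or missing {col} at row {row}")
        df[col] = coerced
    if (df["count_cells_per_ml"] < 0).any():
        row = int(df.index[df["count_cells_per_ml"] < 0][0])
        raise SchemaError(f"{path}: negative count at row {row}")
    bad_group = ~df["group"].isin(GROUPS)
    if bad_group.any():
        raise SchemaError(f"{path}: unknown group at row {int(df.index[bad_group][0])}")
    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        raise SchemaError(f"{path}: unknown condition at row {int(df.index[bad_cond][0])}")
    dup = df.duplicated(subset=["sample_id", "condition", "time_h"], keep=False)
    if dup.any():
        raise SchemaError(
            f"{path}: duplicate (sample_id, condition, time_h) at row {int(df.index[dup][0])}"
        )

    series = []
    for (sample_id, condition), grp in df.groupby(["sample_id", "condition"], sort=True):
        grp = grp.sort_values("time_h")
        groups = grp["group"].unique()
        if len(groups) != 1:
            raise SchemaError(f"{path}: sample {sample_id!r} has inconsistent group labels")
        series.append(
            CountSeries(
                sample_id=str(sample_id),
                group=str(groups[0]),
                condition=str(condition),
                timepoints=tuple(grp["time_h"].tolist()),
                counts=tuple(grp["count_cells_per_ml"].tolist()),
            )
        )
    return series


def write_counts_table(series: list[CountSeries], path: str | Path) -> Path:
    """Write CountSeries back to the long-format counts CSV (lossless)."""
    rows = [
        {
            "sample_id": s.sample_id,
            "group": s.group,
            "condition": s.condition,
            "time_h": t,
            "count_cells_per_ml": c,
        }
        for s in series
        for t, c in zip(s.timepoints, s.counts)
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: object,
    seeds: dict[str, int],
    inputs: list[Path] | None = None,
    outputs: list[Path] | None = None,
) -> Path:
    """Write a run manifest JSON recording everything needed to regenerate
    the outputs: command, config echo, seeds, and file digests."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    manifest = {
        "tool": "clonefix",
        "version": __version__,
        "command": command,
        "config": config,
        "rng_seeds": seeds,
        "inputs": {p.name: _sha256(Path(p)) for p in (inputs or [])},
        "outputs": {p.name: _sha256(Path(p)) for p in (outputs or [])},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
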