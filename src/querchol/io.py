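"""CSV and JSON input/output.

One flat long-format CSV schema serves every species and treatment:
columns ``treatment, species, time_min, replicate, value, unit`` (extra
columns such as ``sd`` or ``source`` are preserved on read but unused).
Times are stored in minutes as printed in the source tables and converted
to hours on ingest.  Fit reports are JSON, embedding the seed and a config
hash so every artifact records its provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult
from .model import TimeSeries

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "RunConfig",
    "load_config",
    "config_hash",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "fit_result_to_dict",
    "write_fit_report",
    "read_fit_report",
]

REQUIRED_COLUMNS = ("treatment", "species", "time_min", "replicate", "value", "unit")


class SchemaError(ValueError):
    """The CSV does not match the documented long-format schema."""


@dataclass
class RunConfig:
    """Options governing a fitting run; echoed (hashed) into every report."""

    input_paths: list[str] = field(default_factory=list)
    windows_hours: dict[str, float] = field(
        default_factory=lambda: {"k5_with_quercetin": 1.0, "hydroperoxide": 0.5}
    )
    through_origin: bool = True
    q0_convention: str = "percent"
    n_starts_per_param: int = 5
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Read a YAML config; unknown keys are rejected to catch typos."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig().to_dict())
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def config_hash(config: RunConfig | dict) -> str:
    payload = config.to_dict() if isinstance(config, RunConfig) else config
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Time-series CSV
# ---------------------------------------------------------------------------


def read_timeseries_csv(path) -> list[TimeSeries]:
    """Parse a long-format CSV into one TimeSeries per (treatment, species).

    Validates the schema and reports offending rows by their line number in
    the file (header = line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")

    lines = df.index + 2  # header occupies line 1
    for col in ("time_min", "value"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric {col} at line(s) {list(lines[bad])[:5]}"
            )
        df[col] = numeric
    neg = df.index[df["time_min"] < 0]
    if len(neg):
        raise SchemaError(f"{path}: negative time_min at line(s) {list(lines[neg])[:5]}")

    key_cols = ["treatment", "species", "time_min", "replicate"]
    dup = df.index[df.duplicated(key_cols, keep=False)]
    if len(dup):
        raise SchemaError(
            f"{path}: duplicated (treatment, species, time, replicate) at "
            f"line(s) {list(lines[dup])[:5]}"
        )

    out: list[TimeSeries] = []
    for (treatment, species), grp in df.groupby(["treatment", "species"], sort=True):
        units = grp["unit"].unique()
        if len(units) != 1:
            raise SchemaError(
                f"{path}: series ({treatment}, {species}) mixes units {list(units)}"
            )
        grp = grp.sort_values(["replicate", "time_min"])
        try:
            out.append(
                TimeSeries(
                    species=species,
                    treatment=treatment,
                    times=grp["time_min"].to_numpy(dtype=float) / 60.0,
                    values=grp["value"].to_numpy(dtype=float),
                    replicates=grp["replicate"].to_numpy(),
                    unit=units[0],
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: series ({treatment}, {species}): {exc}") from exc
    return out


def write_timeseries_csv(series: list[TimeSeries], path) -> None:
    """Write series in the same long-format dialect.

    Floats are written with ``repr`` so a write/read round trip reproduces
    every value bit-for-bit.
    """
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS)
        for s in series:
            for t, v, r in zip(s.times, s.values, s.replicates):
                writer.writerow(
                    [s.treatment, s.species, repr(float(t) * 60.0), r, repr(float(v)), s.unit]
                )


# ---------------------------------------------------------------------------
# Fit reports
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def fit_result_to_dict(fit: FitResult) -> dict:
    return _jsonable(
        {
            "params": fit.params,
            "stderr": fit.stderr,
            "r2": fit.r2,
            "residuals": fit.residuals,
            "n_obs": fit.n_obs,
            "method": fit.method,
            "converged": fit.converged,
            "window_hours": fit.window,
            "extras": {
                k: v for k, v in fit.extras.items() if k != "start_diagnostics"
            },
        }
    )


def write_fit_report(
    results: dict[str, FitResult],
    path,
    config: RunConfig | dict | None = None,
    seed: int = 0,
    comparisons: list[dict] | None = None,
) -> dict:
    """Serialize fits (and optional reference comparisons) as a JSON report.

    The report embeds the seed and config hash; no timestamps, so repeated
    runs with the same inputs are byte-identical.  Returns the payload.
    """
    if not results:
        raise ValueError("no fit results to report")
    cfg = config.to_dict() if isinstance(config, RunConfig) else (config or {})
    payload = {
        "seed": int(seed),
        "config": _jsonable(cfg),
        "config_hash": config_hash(cfg),
        "fits": {name: fit_result_to_dict(fit) for name, fit in results.items()},
    }
    if comparisons is not None:
        payload["comparisons"] = _jsonable(comparisons)
        payload["all_passed"] = all(c["passed"] for c in comparisons if "passed" in c)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return payload


def read_fit_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
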