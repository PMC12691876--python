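"""CSV/JSON readers and writers for drying logs, telemetry and assay tables.

CSV conventions: comma-separated, UTF-8, '.' decimal, mandatory header
row; lines starting with '#' before the header may carry metadata as
``# key: value`` pairs (dry mass, geometry, air conditions).  A
``column_map`` translates nonstandard lab column names onto the canonical
schema.  JSON reports are versioned (``schema_version``) and round-trip
all floats losslessly.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, SchemaError, ValidationError
from .types import AssaySample, DryingRun, EnergyLog

SCHEMA_VERSION = "1.0"

__all__ = [
    "read_drying_log",
    "read_energy_log",
    "read_assay_table",
    "mass_to_moisture",
    "write_report",
    "read_report",
]


def mass_to_moisture(mass_kg, dry_mass_kg: float, tol: float = 1e-9) -> np.ndarray:
    """Convert total sample mass to dry-basis moisture X = (m − m_dry)/m_dry."""
    if dry_mass_kg <= 0:
        raise ValidationError("dry_mass_kg must be > 0")
    m = np.asarray(mass_kg, dtype=float)
    deficit = dry_mass_kg - m
    if np.any(deficit > tol):
        idx = int(np.argmax(deficit > tol))
        raise ValidationError(
            f"mass {m[idx]} kg below dry mass {dry_mass_kg} kg at index {idx}: "
            "negative moisture"
        )
    return np.clip((m - dry_mass_kg) / dry_mass_kg, 0.0, None)


def _read_header_metadata(path: Path) -> dict:
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _load_csv(path, context: str) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta = _read_header_metadata(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{context}: {path} contains no data") from None
    if df.empty:
        raise EmptyInputError(f"{context}: {path} has a header but no rows")
    return df, meta


def _require(df: pd.DataFrame, column: str, context: str) -> np.ndarray:
    if column not in df.columns:
        raise SchemaError(f"{context}: required column {column!r} missing "
                          f"(have: {list(df.columns)})")
    return df[column].to_numpy(dtype=float)


def read_drying_log(path, config: dict | None = None) -> DryingRun:
    """Read a drying-log CSV into a validated :class:`DryingRun`.

    Expected columns: ``time_min`` plus either ``moisture_db`` or
    ``mass_kg`` (converted via :func:`mass_to_moisture` using
    ``dry_mass_kg``).  Metadata (dry mass, geometry, air conditions) may
    come from ``config`` or ``# key: value`` header comments; config wins.
    ``config["column_map"]`` maps nonstandard column names onto the schema.
    """
    config = dict(config or {})
    df, meta = _load_csv(path, "drying log")
    column_map = config.pop("column_map", None)
    if column_map:
        df = df.rename(columns=column_map)
    merged = {**meta, **config}

    def get(key, default=None, cast=float):
        if key in merged:
            return cast(merged[key])
        if default is None:
            raise SchemaError(f"drying log: metadata key {key!r} missing "
                              "(supply in config or '# key: value' header)")
        return default

    times = _require(df, "time_min", "drying log")
    if "moisture_db" in df.columns:
        moisture = df["moisture_db"].to_numpy(dtype=float)
        dry_mass = get("dry_mass_kg", 0.01875)
    elif "mass_kg" in df.columns:
        dry_mass = get("dry_mass_kg")
        moisture = mass_to_moisture(df["mass_kg"].to_numpy(dtype=float), dry_mass)
    else:
        raise SchemaError("drying log: need a 'moisture_db' or 'mass_kg' column")

    return DryingRun(
        label=str(merged.get("label", Path(path).stem)),
        air_temp_C=get("air_temp_C", 30.0),
        air_velocity_m_s=get("air_velocity_m_s", 2.0),
        rel_humidity_pct=get("rel_humidity_pct", 83.0),
        times_min=times,
        moisture_db=moisture,
        dry_mass_kg=dry_mass,
        half_thickness_m=get("half_thickness_m", 0.001),
        equilibrium_moisture_db=get("equilibrium_moisture_db", 0.0),
    )


def read_energy_log(path, config: dict | None = None) -> EnergyLog:
    """Read telemetry CSV (time_s, voltage_V, current_A, t_db_C, t_wb_C,
    t_inlet_C, t_process_C, rh_pct) into a validated :class:`EnergyLog`."""
    config = dict(config or {})
    df, meta = _load_csv(path, "energy log")
    column_map = config.pop("column_map", None)
    if column_map:
        df = df.rename(columns=column_map)
    merged = {**meta, **config}

    def get(key, default=None):
        if key in merged:
            return float(merged[key])
        if default is None:
            raise SchemaError(f"energy log: metadata key {key!r} missing")
        return default

    return EnergyLog(
        times_s=_require(df, "time_s", "energy log"),
        voltage_V=_require(df, "voltage_V", "energy log"),
        current_A=_require(df, "current_A", "energy log"),
        t_dry_bulb_C=_require(df, "t_db_C", "energy log"),
        t_wet_bulb_C=_require(df, "t_wb_C", "energy log"),
        t_inlet_C=_require(df, "t_inlet_C", "energy log"),
        t_process_C=_require(df, "t_process_C", "energy log"),
        rel_humidity_pct=_require(df, "rh_pct", "energy log"),
        flow_area_m2=get("flow_area_m2", 0.03),
        air_velocity_m_s=get("air_velocity_m_s", 2.0),
        tray_area_m2=get("tray_area_m2", 0.045),
    )


def read_assay_table(path) -> list[AssaySample]:
    """Read a plate CSV (sample_id, a480, a582, a631, a665, a750,
    abs_control, abs_sample) into a list of :class:`AssaySample`."""
    df, _ = _load_csv(path, "assay table")
    for col in ("a480", "a582", "a631", "a665", "a750"):
        _require(df, col, "assay table")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            AssaySample(
                a480=row["a480"],
                a582=row["a582"],
                a631=row["a631"],
                a665=row["a665"],
                a750=row["a750"],
                abs_control=row.get("abs_control", 0.0) or 0.0,
                abs_sample=row.get("abs_sample", 0.0) or 0.0,
                label=str(row.get("sample_id", "")),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            "_type": type(obj).__name__,
            **{k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()},
        }
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and (obj != obj or obj in (float("inf"), float("-inf"))):
        return repr(obj)  # JSON has no NaN/Inf literals
    return obj


def write_report(results, path, fmt: str = "json") -> Path:
    """Write results (any package dataclasses, dicts, lists) to disk.

    ``json`` round-trips every float bit-identically (Python repr floats);
    ``csv`` flattens a list of records; ``md`` renders a readable table.
    """
    path = Path(path)
    payload = {"schema_version": SCHEMA_VERSION, "results": _jsonable(results)}
    if fmt == "json":
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    elif fmt in ("csv", "md"):
        records = payload["results"]
        if isinstance(records, dict):
            records = [records]
        flat = pd.json_normalize(records)
        if fmt == "csv":
            flat.to_csv(path, index=False)
        else:
            path.write_text(_markdown_table(flat), encoding="utf-8")
    else:
        raise ValidationError(f"unknown report format {fmt!r}")
    return path


def _markdown_table(df: pd.DataFrame) -> str:
    if df.empty:
        return "| (no records) |\n"
    header = "| " + " | ".join(map(str, df.columns)) + " |"
    rule = "|" + "|".join(["---"] * len(df.columns)) + "|"
    rows = [
        "| " + " | ".join("" if pd.isna(v) else str(v) for v in row) + " |"
        for row in df.itertuples(index=False)
    ]
    return "\n".join([header, rule, *rows]) + "\n"


def read_report(path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text(encoding="utf-8"))
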