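"""Core domain containers for convective drying experiments.

All moisture values are stored on a dry basis (kg water / kg dry matter);
wet-basis values appear only at I/O boundaries.  Kinetics time grids are
kept in minutes; diffusion calculations convert to seconds explicitly via
:meth:`MoistureRatioCurve.times_in`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, UnitError, ValidationError

SECONDS_PER_MINUTE = 60.0

_TIME_UNITS = ("min", "s")


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def check_strictly_increasing(times: np.ndarray, name: str = "times") -> None:
    """Raise with the first offending index if `times` is not strictly increasing."""
    diffs = np.diff(times)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        idx = int(bad[0]) + 1
        raise ValidationError(
            f"{name} must be strictly increasing; violation at index {idx} "
            f"(value {times[idx]!r} after {times[idx - 1]!r})"
        )


@dataclass
class DryingRun:
    """One convective drying experiment on a thin slab of material.

    Parameters
    ----------
    label : identifier for reports.
    air_temp_C : drying-air setpoint temperature (°C).
    air_velocity_m_s : superficial air velocity (m/s).
    rel_humidity_pct : relative humidity of the drying air (%).
    times_min : sampling instants in minutes, starting at 0.
    moisture_db : dry-basis moisture X (kg water / kg dry matter) per instant.
    dry_mass_kg : mass of bone-dry solids on the tray (kg).
    half_thickness_m : slab half-thickness L (m) for diffusion calculations.
    initial_moisture_db : X at t=0 (defaults to moisture_db[0]).
    equilibrium_moisture_db : equilibrium moisture X_e (default 0, i.e.
        negligible relative to the drying range).
    """

    label: str
    air_temp_C: float
    air_velocity_m_s: float
    rel_humidity_pct: float
    times_min: np.ndarray
    moisture_db: np.ndarray
    dry_mass_kg: float
    half_thickness_m: float = 0.001
    initial_moisture_db: float | None = None
    equilibrium_moisture_db: float = 0.0

    def __post_init__(self):
        self.times_min = _as_float_array(self.times_min, "times_min")
        self.moisture_db = _as_float_array(self.moisture_db, "moisture_db")
        if self.times_min.size != self.moisture_db.size:
            raise ValidationError("times_min and moisture_db lengths differ")
        if self.times_min.size == 0:
            raise InsufficientDataError("drying run has no observations")
        if self.times_min[0] != 0.0:
            raise ValidationError("times_min must start at 0")
        check_strictly_increasing(self.times_min, "times_min")
        if np.any(self.moisture_db < 0):
            raise ValidationError("moisture_db values must be >= 0")
        if self.dry_mass_kg <= 0:
            raise ValidationError("dry_mass_kg must be > 0")
        if self.half_thickness_m <= 0:
            raise ValidationError("half_thickness_m must be > 0")
        if self.initial_moisture_db is None:
            self.initial_moisture_db = float(self.moisture_db[0])
        elif not np.isclose(self.initial_moisture_db, self.moisture_db[0], rtol=1e-9, atol=1e-12):
            raise ValidationError(
                "initial_moisture_db must equal moisture_db[0]: "
                f"{self.initial_moisture_db} != {self.moisture_db[0]}"
            )
        if self.equilibrium_moisture_db < 0:
            raise ValidationError("equilibrium_moisture_db must be >= 0")
        if self.equilibrium_moisture_db > 0 and self.equilibrium_moisture_db > float(
            np.min(self.moisture_db)
        ):
            raise ValidationError(
                "equilibrium_moisture_db exceeds the minimum observed moisture"
            )

    @property
    def n_obs(self) -> int:
        return int(self.times_min.size)


@dataclass
class MoistureRatioCurve:
    """Dimensionless moisture ratio MR(t) with an explicit time-unit tag."""

    times: np.ndarray
    mr: np.ndarray
    unit: str = "min"

    def __post_init__(self):
        if self.unit not in _TIME_UNITS:
            raise UnitError(f"unit must be one of {_TIME_UNITS}, got {self.unit!r}")
        self.times = _as_float_array(self.times, "times")
        self.mr = _as_float_array(self.mr, "mr")
        if self.times.size != self.mr.size:
            raise ValidationError("times and mr lengths differ")
        check_strictly_increasing(self.times, "times")

    def times_in(self, unit: str) -> np.ndarray:
        """Return the time grid converted to `unit` ('min' or 's')."""
        if unit not in _TIME_UNITS:
            raise UnitError(f"unknown time unit {unit!r}")
        if unit == self.unit:
            return self.times.copy()
        if unit == "s":  # min -> s
            return self.times * SECONDS_PER_MINUTE
        return self.times / SECONDS_PER_MINUTE

    def in_unit(self, unit: str) -> "MoistureRatioCurve":
        return MoistureRatioCurve(self.times_in(unit), self.mr.copy(), unit)

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


@dataclass
class EnergyLog:
    """Dryer telemetry: electrical load, psychrometric temperatures, geometry."""

    times_s: np.ndarray
    voltage_V: np.ndarray
    current_A: np.ndarray
    t_dry_bulb_C: np.ndarray
    t_wet_bulb_C: np.ndarray
    t_inlet_C: np.ndarray
    t_process_C: np.ndarray
    rel_humidity_pct: np.ndarray
    flow_area_m2: float
    air_velocity_m_s: float
    tray_area_m2: float

    def __post_init__(self):
        self.times_s = _as_float_array(self.times_s, "times_s")
        check_strictly_increasing(self.times_s, "times_s")
        n = self.times_s.size
        for name in (
            "voltage_V",
            "current_A",
            "t_dry_bulb_C",
            "t_wet_bulb_C",
            "t_inlet_C",
            "t_process_C",
            "rel_humidity_pct",
        ):
            arr = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (n,)).copy()
            setattr(self, name, _as_float_array(arr, name))
        if np.any(self.voltage_V <= 0) or np.any(self.current_A < 0):
            raise ValidationError("voltage must be > 0 and current >= 0")
        if self.flow_area_m2 <= 0 or self.tray_area_m2 <= 0:
            raise ValidationError("flow and tray areas must be > 0")
        if self.air_velocity_m_s <= 0:
            raise ValidationError("air_velocity_m_s must be > 0")
        if np.any(self.t_wet_bulb_C > self.t_dry_bulb_C + 1e-9):
            raise ValidationError("wet-bulb temperature exceeds dry-bulb temperature")

    @property
    def n_obs(self) -> int:
        return int(self.times_s.size)


@dataclass
class AssaySample:
    """Absorbance readings for one extract.

    a480..a750 feed the pigment formulas; abs_control/abs_sample feed the
    DPPH inhibition calculation.  Values outside [0, 4] are physically
    implausible on a plate reader and trigger a warning (not a rejection).
    """

    a480: float = 0.0
    a582: float = 0.0
    a631: float = 0.0
    a665: float = 0.0
    a750: float = 0.0
    abs_control: float = 0.0
    abs_sample: float = 0.0
    label: str = ""

    def __post_init__(self):
        for name in ("a480", "a582", "a631", "a665", "a750", "abs_control", "abs_sample"):
            value = float(getattr(self, name))
            if not np.isfinite(value):
                raise ValidationError(f"absorbance {name} is not finite")
            setattr(self, name, value)
            if not 0.0 <= value <= 4.0:
                warnings.warn(
                    f"absorbance {name}={value} outside the typical [0, 4] range",
                    stacklevel=2,
                )
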