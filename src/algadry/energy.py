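"""Convective-dryer energy balance, efficiencies, SEC and mass transfer.

The audit splits the electrically supplied energy E_total = Σ V·I·Δt into
the share absorbed by the air stream (sensible heating across the heater
bank) and the share ultimately used to evaporate water from the product.
Stage efficiencies multiply into the overall thermal efficiency (OTE):

    η_air   = E_air / E_total        (air-heating stage)
    η_water = E_water / E_air        (water-removal stage)
    OTE     = η_air · η_water  =  E_water / E_total

Specific energy consumption (SEC) is E_total per kg of water evaporated.
A per-interval overall mass-transfer coefficient K_G links the measured
evaporation rate to the vapor-pressure driving force at the wet-bulb
temperature, with saturation pressure from the Tetens correlation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import NoDryingError, ValidationError
from .types import DryingRun, EnergyLog

__all__ = [
    "EnergyAudit",
    "tetens_psat",
    "dew_point",
    "wet_bulb_temp",
    "latent_heat",
    "air_density",
    "energy_air",
    "energy_water",
    "total_energy",
    "efficiencies",
    "specific_energy_consumption",
    "kg_coefficient",
    "energy_cost",
    "build_energy_audit",
]

CP_AIR_KJ_KG_K = 1.006
ATM_PA = 101325.0
PSYCHROMETER_COEFF = 6.66e-4  # 1/K, standard aspirated-psychrometer constant
KJ_PER_KWH = 3600.0


# ---------------------------------------------------------------------------
# Psychrometrics and physical-property correlations
# ---------------------------------------------------------------------------

def tetens_psat(t_C):
    """Saturation vapor pressure (Pa) from the Tetens correlation.

    P_sat = 610.78 · exp(17.27 · T / (T + 237.3)) for T in °C, valid over
    roughly −20…100 °C.
    """
    t = np.asarray(t_C, dtype=float)
    if np.any(t < -20.0) or np.any(t > 100.0):
        raise ValidationError("tetens_psat valid for -20 <= T <= 100 °C")
    p = 610.78 * np.exp(17.27 * t / (t + 237.3))
    return float(p) if np.ndim(t_C) == 0 else p


def dew_point(pvap_Pa: float) -> float:
    """Invert the Tetens correlation: temperature (°C) with P_sat = pvap."""
    if pvap_Pa <= 0:
        raise ValidationError("vapor pressure must be > 0")
    x = np.log(pvap_Pa / 610.78)
    return float(237.3 * x / (17.27 - x))


def wet_bulb_temp(
    t_db_C: float,
    rh_pct: float,
    pressure_Pa: float = ATM_PA,
    psy_coeff: float = PSYCHROMETER_COEFF,
) -> float:
    """Wet-bulb temperature (°C) from dry-bulb and relative humidity.

    Solves the psychrometer relation
    P_vap = P_sat(T_wb) − A·P·(T_db − T_wb) with Tetens saturation
    pressure, so the triple (T_db, T_wb, RH) is internally consistent.
    """
    if not 0 < rh_pct <= 100:
        raise ValidationError("rh_pct must lie in (0, 100]")
    pvap = rh_pct / 100.0 * tetens_psat(t_db_C)
    if rh_pct >= 100.0:
        return float(t_db_C)
    lo = dew_point(pvap)  # T_wb lies between dew point and dry bulb

    def f(tw):
        return tetens_psat(tw) - psy_coeff * pressure_Pa * (t_db_C - tw) - pvap

    return float(brentq(f, lo, t_db_C, xtol=1e-10))


def latent_heat(t_C, a: float = 2501.0, b: float = 2.361):
    """Latent heat of vaporization of water (kJ/kg), linear in temperature.

    λ(T) = a − b·T with the default coefficients matching steam tables to
    within ~0.1% over 0…100 °C.
    """
    t = np.asarray(t_C, dtype=float)
    if np.any(t < 0.0) or np.any(t > 100.0):
        raise ValidationError("latent_heat valid for 0 <= T <= 100 °C")
    lam = a - b * t
    return float(lam) if np.ndim(t_C) == 0 else lam


def air_density(t_C, pressure_Pa: float = ATM_PA):
    """Dry-air density (kg/m³) from the ideal-gas law at `pressure_Pa`."""
    t = np.asarray(t_C, dtype=float)
    rho = pressure_Pa * 0.0289647 / (8.314462618 * (t + 273.15))
    return float(rho) if np.ndim(t_C) == 0 else rho


# ---------------------------------------------------------------------------
# Energy-balance terms
# ---------------------------------------------------------------------------

def _interval_sum(times_s: np.ndarray, rate_kW: np.ndarray) -> float:
    """Σ rate·Δt over intervals (left-endpoint rate), result in kWh."""
    dt_h = np.diff(times_s) / 3600.0
    if np.any(dt_h < 0):
        raise ValidationError("negative time step in log")
    return float(np.sum(rate_kW[:-1] * dt_h))


def energy_air(log: EnergyLog, rho_air=None, cp_air: float = CP_AIR_KJ_KG_K) -> float:
    """Sensible energy absorbed by the air stream across the heater (kWh).

    E = Σ v̄·A·ρ_air·C̄p·(T_P − T_inlet)·Δt, evaluated piecewise over the
    log so time-varying temperatures are honoured.  ρ_air defaults to the
    ideal-gas density at the process temperature.
    """
    if rho_air is None:
        rho = air_density(log.t_process_C)
    else:
        rho = np.broadcast_to(np.asarray(rho_air, dtype=float), log.times_s.shape)
    dT = log.t_process_C - log.t_inlet_C
    if np.mean(dT) < 0:
        raise ValidationError("process temperature below inlet on average")
    rate_kW = log.air_velocity_m_s * log.flow_area_m2 * rho * cp_air * dT
    return _interval_sum(log.times_s, rate_kW)


def energy_water(run: DryingRun, temp_C=None, lam_coeffs: tuple = (2501.0, 2.361)):
    """Energy absorbed by evaporating water (kWh) and total water mass (kg).

    E = M_dry · Σ (−ΔX)·λ(T) over intervals with net moisture loss; noisy
    intervals with ΔX > 0 contribute zero and are counted in a warning.
    Returns ``(e_kwh, m_water_vap_kg)`` with
    m_water_vap = M_dry·(X_0 − X_final).
    """
    x = run.moisture_db
    if x.size < 2:
        raise NoDryingError("need at least two moisture observations")
    dx = np.diff(x)
    if np.all(dx >= 0) and np.any(dx > 0):
        raise NoDryingError("moisture series is increasing: no drying to audit")
    t = run.air_temp_C if temp_C is None else temp_C
    lam = latent_heat(t, *lam_coeffs)
    lam = np.broadcast_to(np.asarray(lam, dtype=float), dx.shape)
    gain = dx > 0
    if gain.any():
        warnings.warn(
            f"{int(gain.sum())} interval(s) with moisture gain contribute no energy",
            stacklevel=2,
        )
    evap = np.where(dx < 0, -dx, 0.0)
    e_kJ = run.dry_mass_kg * float(np.sum(evap * lam))
    m_water = run.dry_mass_kg * float(x[0] - x[-1])
    return e_kJ / KJ_PER_KWH, m_water


def total_energy(log: EnergyLog) -> float:
    """Total electrical energy drawn by the heaters, Σ V·I·Δt (kWh)."""
    rate_kW = log.voltage_V * log.current_A / 1000.0
    return _interval_sum(log.times_s, rate_kW)


@dataclass
class StageEfficiencies:
    eta_air_heating_pct: float
    eta_water_remotion_pct: float
    ote_pct: float
    q_lost_air_heating_kWh: float
    q_total_lost_kWh: float


def efficiencies(q_available: float, q_air: float, q_water: float) -> StageEfficiencies:
    """Stage efficiencies, OTE and losses from the three energy terms (kWh)."""
    if q_available <= 0 or q_air <= 0:
        raise ValidationError("q_available and q_air must be > 0")
    eta_air = 100.0 * q_air / q_available
    eta_water = 100.0 * q_water / q_air
    ote = eta_air * eta_water / 100.0
    for name, value in (("eta_air", eta_air), ("eta_water", eta_water), ("OTE", ote)):
        if not 0.0 <= value <= 100.0:
            warnings.warn(f"{name} = {value:.2f}% outside [0, 100]", stacklevel=2)
    return StageEfficiencies(
        eta_air_heating_pct=eta_air,
        eta_water_remotion_pct=eta_water,
        ote_pct=ote,
        q_lost_air_heating_kWh=q_available - q_air,
        q_total_lost_kWh=q_available - q_water,
    )


def specific_energy_consumption(e_total_kWh: float, m_water_vap_kg: float) -> float:
    """SEC = E_total / M_water (kWh per kg of evaporated water)."""
    if m_water_vap_kg <= 0:
        raise ValidationError("no water removed: SEC undefined")
    return e_total_kWh / m_water_vap_kg


def energy_cost(e_total_kWh: float, sec_kWh_per_kg: float, tariff_usd_per_kWh: float = 0.4):
    """Energy cost per run (USD) and per kg of evaporated water (USD/kg).

    Both bases are reported because published audits are ambiguous about
    which one a "cost of energy" column uses.
    """
    if tariff_usd_per_kWh < 0:
        raise ValidationError("tariff must be >= 0")
    return tariff_usd_per_kWh * e_total_kWh, tariff_usd_per_kWh * sec_kWh_per_kg


def kg_coefficient(run: DryingRun, log: EnergyLog, pvap_mode: str = "rh_tdb"):
    """Per-interval overall mass-transfer coefficient K_G (kg/m²/s/Pa).

    K_G = [M_dry·(−ΔX/Δt)·λ(T_P)] / [λ(T_wb)·A_tray·(P_sat(T_wb) − P_vap)]

    with P_vap = (RH/100)·P_sat(T_db) (``pvap_mode="rh_tdb"``) or from the
    psychrometer relation at the logged wet bulb (``"wet_bulb"``).  The log
    is resampled onto the run's time grid by linear interpolation.
    Intervals without evaporation give K_G = 0; intervals with a
    non-positive driving force are excluded (NaN) and only raise if no
    interval survives.  Returns ``(kg_series, kg_mean)``.
    """
    t_s = run.times_min * 60.0
    interp = lambda y: np.interp(t_s, log.times_s, y)
    t_p = interp(log.t_process_C)
    t_wb = interp(log.t_wet_bulb_C)
    t_db = interp(log.t_dry_bulb_C)
    rh = interp(log.rel_humidity_pct)

    psat_wb = tetens_psat(t_wb)
    if pvap_mode == "rh_tdb":
        pvap = rh / 100.0 * tetens_psat(t_db)
    elif pvap_mode == "wet_bulb":
        pvap = psat_wb - PSYCHROMETER_COEFF * ATM_PA * (t_db - t_wb)
    else:
        raise ValidationError(f"unknown pvap_mode {pvap_mode!r}")

    dx = np.diff(run.moisture_db)
    dt = np.diff(t_s)
    rate = np.where(dx < 0, -dx, 0.0) / dt  # kg water/kg dm/s
    driving = psat_wb[:-1] - pvap[:-1]

    kg = np.full(dx.shape, np.nan)
    ok = driving > 0
    kg[ok] = (
        run.dry_mass_kg
        * rate[ok]
        * latent_heat(t_p[:-1][ok])
        / (latent_heat(t_wb[:-1][ok]) * log.tray_area_m2 * driving[ok])
    )
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} interval(s) with P_sat <= P_vap excluded from K_G",
            stacklevel=2,
        )
    evaporating = ok & (rate > 0)
    if not evaporating.any():
        raise NoDryingError("no interval with evaporation and positive driving force")
    return kg, float(np.mean(kg[evaporating]))


# ---------------------------------------------------------------------------
# Full audit
# ---------------------------------------------------------------------------

@dataclass
class EnergyAudit:
    """One dryer run's full energy balance (a table-row analogue)."""

    temp_C: float
    q_available_kWh: float
    q_air_kWh: float
    q_lost_air_heating_kWh: float
    eta_air_heating_pct: float
    q_water_kWh: float
    eta_water_remotion_pct: float
    q_total_lost_kWh: float
    sec_kWh_per_kg: float
    cost_usd_per_run: float
    cost_usd_per_kg_water: float
    ote_pct: float
    m_water_vap_kg: float
    kg_mean: float
    kg_series: np.ndarray = field(repr=False, default=None)


def build_energy_audit(
    run: DryingRun,
    log: EnergyLog,
    tariff_usd_per_kWh: float = 0.4,
    rho_air=None,
    cp_air: float = CP_AIR_KJ_KG_K,
) -> EnergyAudit:
    """Assemble the complete audit for one (run, telemetry) pair."""
    q_total = total_energy(log)
    q_air = energy_air(log, rho_air=rho_air, cp_air=cp_air)
    q_water, m_water = energy_water(run)
    eff = efficiencies(q_total, q_air, q_water)
    sec = specific_energy_consumption(q_total, m_water)
    cost_run, cost_kg = energy_cost(q_total, sec, tariff_usd_per_kWh)
    kg_series, kg_mean = kg_coefficient(run, log)
    return EnergyAudit(
        temp_C=run.air_temp_C,
        q_available_kWh=q_total,
        q_air_kWh=q_air,
        q_lost_air_heating_kWh=eff.q_lost_air_heating_kWh,
        eta_air_heating_pct=eff.eta_air_heating_pct,
        q_water_kWh=q_water,
        eta_water_remotion_pct=eff.eta_water_remotion_pct,
        q_total_lost_kWh=eff.q_total_lost_kWh,
        sec_kWh_per_kg=sec,
        cost_usd_per_run=cost_run,
        cost_usd_per_kg_water=cost_kg,
        ote_pct=eff.ote_pct,
        m_water_vap_kg=m_water,
        kg_mean=kg_mean,
        kg_series=kg_series,
    )
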