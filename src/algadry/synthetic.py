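"""Seed-deterministic generators emulating a bench-scale drying study.

Every generator is a pure function of its configuration and seed.  The
defaults reproduce the study conditions this package targets: 150 g of
blanched seaweed pieces (3 cm × 0.5 cm × 0.2 cm slabs, so L = 0.001 m) at
87.5 g water/100 g wet basis (X_0 = 7.0 kg/kg dry basis), dried at 2 m/s
and 83% RH with mass sampled every 7 min, plus constant-setpoint dryer
telemetry with optional Gaussian jitter.  Measurement noise is additive
Gaussian on the moisture ratio (σ default 0.005, giving best-fit R² near
0.999) and truncated at zero by resampling so log-transforms stay defined.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .diffusivity import fick_mr
from .energy import wet_bulb_temp
from .errors import ValidationError
from .kinetics import evaluate_model, get_model
from .types import AssaySample, DryingRun, EnergyLog, MoistureRatioCurve

__all__ = [
    "SimulationConfig",
    "TelemetryConfig",
    "DRYING_PRESETS",
    "simulate_drying_run",
    "simulate_fick_run",
    "simulate_energy_log",
    "simulate_assay_plate",
    "make_pigment_sample",
    "simulate_calibration_standards",
]


@dataclass
class TelemetryConfig:
    """Constant dryer setpoints plus jitter magnitudes for the telemetry log."""

    # 220 V × 10 A ≈ 2.2 kW heater bank, enough to cover the sensible air
    # load at every preset temperature (a bench tray dryer scale)
    voltage_V: float = 220.0
    current_A: float = 10.0
    rh_pct: float = 83.0
    air_velocity_m_s: float = 2.0
    flow_area_m2: float = 0.03
    tray_area_m2: float = 0.045
    inlet_temp_C: float = 20.0
    jitter_temp_C: float = 0.0
    jitter_current_A: float = 0.0


@dataclass
class SimulationConfig:
    """Ground-truth drying model and sampling scheme for one synthetic run."""

    true_model: str = "midilli_kucuk"
    true_params: tuple = (0.993, 0.009, 1.264, 0.0001)
    temp_C: float = 30.0
    dt_min: float = 7.0
    stop_mr: float = 0.01
    max_time_min: float = 300.0
    noise_sigma_mr: float = 0.005
    seed: int = 0
    initial_mass_kg: float = 0.150
    initial_moisture_wb_pct: float = 87.5
    half_thickness_m: float = 0.001
    telemetry: TelemetryConfig = field(default_factory=TelemetryConfig)

    def __post_init__(self):
        if self.dt_min <= 0:
            raise ValidationError("dt_min must be > 0")
        if not 0.0 <= self.stop_mr < 1.0:
            raise ValidationError("stop_mr must lie in [0, 1)")
        if self.noise_sigma_mr < 0:
            raise ValidationError("noise sigma must be >= 0")
        if not 0.0 < self.initial_moisture_wb_pct < 100.0:
            raise ValidationError("initial_moisture_wb_pct must be in (0, 100)")

    @property
    def initial_moisture_db(self) -> float:
        wb = self.initial_moisture_wb_pct / 100.0
        return wb / (1.0 - wb)

    @property
    def dry_mass_kg(self) -> float:
        return self.initial_mass_kg * (1.0 - self.initial_moisture_wb_pct / 100.0)


# Reference Midilli–Kucuk parameter sets (a, k, n, b) per air temperature,
# taken from fitted thin-layer kinetics of convectively dried brown seaweed.
DRYING_PRESETS: dict[str, SimulationConfig] = {
    "30C": SimulationConfig(true_params=(0.993, 0.009, 1.264, 0.0001), temp_C=30.0),
    "40C": SimulationConfig(true_params=(0.989, 0.020, 1.225, 0.0002), temp_C=40.0),
    "50C": SimulationConfig(true_params=(0.996, 0.027, 1.270, 0.00001), temp_C=50.0),
}


def _truncated_noise(rng: np.random.Generator, clean: np.ndarray, sigma: float) -> np.ndarray:
    """Additive Gaussian noise, resampled (not clipped) where MR would go < 0."""
    if sigma == 0:
        return clean.copy()
    noisy = clean + rng.normal(0.0, sigma, clean.size)
    while np.any(noisy < 0):
        bad = noisy < 0
        noisy[bad] = clean[bad] + rng.normal(0.0, sigma, int(bad.sum()))
    return noisy


def simulate_drying_run(cfg: SimulationConfig):
    """Generate one synthetic drying run and its ground-truth record.

    The true model is evaluated on the dt_min grid up to max_time_min and
    truncated at the first point where the clean MR drops below stop_mr.
    Noise is applied to MR, then converted to dry-basis moisture through
    X = MR·X_0.  Identical configs (including seed) give identical runs.
    """
    spec = get_model(cfg.true_model)
    lo, hi = spec.bounds_arrays()
    params = np.asarray(cfg.true_params, dtype=float)
    if params.size != spec.n_params or np.any(params < lo) or np.any(params > hi):
        raise ValidationError(
            f"true_params {cfg.true_params!r} outside the bounds of {cfg.true_model}"
        )
    times = np.arange(0.0, cfg.max_time_min + cfg.dt_min, cfg.dt_min)
    mr_clean = evaluate_model(spec, params, times)
    below = mr_clean < cfg.stop_mr
    if below.any():
        cut = int(np.argmax(below))
        if cut < 2:
            raise ValidationError("stop_mr reached before the second sample")
        times, mr_clean = times[:cut], mr_clean[:cut]

    rng = np.random.default_rng(cfg.seed)
    mr_noisy = _truncated_noise(rng, mr_clean, cfg.noise_sigma_mr)
    x0 = cfg.initial_moisture_db
    run = DryingRun(
        label=f"sim-{cfg.true_model}-{cfg.temp_C:g}C-seed{cfg.seed}",
        air_temp_C=cfg.temp_C,
        air_velocity_m_s=cfg.telemetry.air_velocity_m_s,
        rel_humidity_pct=cfg.telemetry.rh_pct,
        times_min=times,
        moisture_db=mr_noisy * x0,
        dry_mass_kg=cfg.dry_mass_kg,
        half_thickness_m=cfg.half_thickness_m,
    )
    truth = {
        "model": cfg.true_model,
        "params": dict(zip(spec.param_names, params.tolist())),
        "x0_db": x0,
        "mr_clean": mr_clean,
        "noise_sigma_mr": cfg.noise_sigma_mr,
        "seed": cfg.seed,
    }
    return run, truth


def simulate_fick_run(
    d_eff: float,
    half_thickness_m: float = 0.001,
    dt_s: float = 420.0,
    t_max_s: float = 21600.0,
    n_terms: int = 1,
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """Forward-simulate a slab-diffusion MR curve for recovery studies."""
    times = np.arange(0.0, t_max_s + dt_s, dt_s)
    clean = fick_mr(d_eff, half_thickness_m, times, n_terms=n_terms)
    rng = np.random.default_rng(seed)
    noisy = _truncated_noise(rng, clean, noise_sigma)
    curve = MoistureRatioCurve(times, noisy, unit="s")
    truth = {
        "d_eff": d_eff,
        "half_thickness_m": half_thickness_m,
        "n_terms": n_terms,
        "mr_clean": clean,
        "seed": seed,
    }
    return curve, truth


def simulate_energy_log(cfg: SimulationConfig, run: DryingRun) -> EnergyLog:
    """Constant-setpoint telemetry on the run's horizon, with optional jitter.

    The wet-bulb channel is derived from the (possibly jittered) dry-bulb
    temperature and the configured RH through the psychrometer relation, so
    the logged triple (T_db, T_wb, RH) is always self-consistent.
    """
    tel = cfg.telemetry
    times_s = run.times_min * 60.0
    n = times_s.size
    rng = np.random.default_rng(cfg.seed + 1)  # independent of the mass-noise stream

    def jittered(value, sigma):
        if sigma == 0:
            return np.full(n, float(value))
        return value + rng.normal(0.0, sigma, n)

    t_process = jittered(cfg.temp_C, tel.jitter_temp_C)
    t_db = t_process.copy()
    t_inlet = jittered(tel.inlet_temp_C, tel.jitter_temp_C)
    current = np.clip(jittered(tel.current_A, tel.jitter_current_A), 0.0, None)
    t_wb = np.array([wet_bulb_temp(t, tel.rh_pct) for t in t_db])
    return EnergyLog(
        times_s=times_s,
        voltage_V=np.full(n, tel.voltage_V),
        current_A=current,
        t_dry_bulb_C=t_db,
        t_wet_bulb_C=t_wb,
        t_inlet_C=t_inlet,
        t_process_C=t_process,
        rel_humidity_pct=np.full(n, tel.rh_pct),
        flow_area_m2=tel.flow_area_m2,
        air_velocity_m_s=tel.air_velocity_m_s,
        tray_area_m2=tel.tray_area_m2,
    )


def make_pigment_sample(
    ct: float, fc: float, baseline: float = 0.05, label: str = ""
) -> AssaySample:
    """Construct an absorbance quintuple whose pigment formulas recover
    (ct, fc) exactly.

    gamma is pinned to 0 (A665 = A750 = baseline), alpha = ct/4, and beta
    solves the fucoxanthin formula, split evenly between A631 and A582.
    """
    alpha = ct / 4.0
    beta = (7.69 * alpha - fc) / 5.55
    return AssaySample(
        a480=baseline + alpha,
        a582=baseline + beta / 2.0,
        a631=baseline + beta / 2.0,
        a665=baseline,
        a750=baseline,
        label=label,
    )


def simulate_assay_plate(
    targets,
    noise_sigma: float = 0.0,
    seed: int = 0,
    baseline: float = 0.05,
    dpph_control: float = 1.0,
    dpph_inhibition_pct: float = 70.0,
):
    """Synthetic plate: one AssaySample per (ct, fc) target.

    At sigma = 0 the pigment formulas recover each target exactly; noise is
    i.i.d. Gaussian per well.
    """
    rng = np.random.default_rng(seed)
    samples = []
    for i, (ct, fc) in enumerate(targets):
        s = make_pigment_sample(ct, fc, baseline=baseline, label=f"sample-{i}")
        s.abs_control = dpph_control
        s.abs_sample = dpph_control * (1.0 - dpph_inhibition_pct / 100.0)
        if noise_sigma > 0:
            for name in ("a480", "a582", "a631", "a665", "a750", "abs_control", "abs_sample"):
                setattr(s, name, getattr(s, name) + rng.normal(0.0, noise_sigma))
        samples.append(s)
    return samples


def simulate_calibration_standards(
    slope: float,
    intercept: float = 0.0,
    concentrations=(0.0, 25.0, 50.0, 75.0, 100.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """Standard-curve wells: absorbance = slope·conc + intercept + noise."""
    if slope <= 0:
        raise ValidationError("calibration slope must be > 0")
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    absb = slope * conc + intercept + rng.normal(0.0, noise_sigma, conc.size)
    return conc, absb
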