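"""Thin-layer drying kinetics: model registry, fitting, and model selection.

Eight semi-empirical moisture-ratio models are fitted by bounded nonlinear
least squares from a deterministic multi-start grid, scored with the usual
goodness-of-fit suite (R², SSE, RMSE, χ², AIC, AICc) and ranked by AICc.

Time is expressed in minutes throughout this module: the rate constants of
the reference parameter sets (k ≈ 0.01–0.1) are only meaningful on that
scale.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegreesOfFreedomError,
    InsufficientDataError,
    NonConvergenceError,
    ValidationError,
)
from .types import DryingRun, MoistureRatioCurve

__all__ = [
    "MODELS",
    "ModelSpec",
    "FitResult",
    "FitStatistics",
    "moisture_ratio",
    "drying_rate",
    "evaluate_model",
    "fit_model",
    "fit_statistics",
    "select_model",
]


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------

def _page(t, k, n):
    return np.exp(-k * t**n)


def _weibull(t, alpha, beta):
    # beta is the time scale (min), alpha the shape exponent
    return np.exp(-((t / beta) ** alpha))


def _wang_singh(t, a, b):
    return a * t**2 + b * t + 1.0


def _henderson_pabis(t, n, k):
    # single-term exponential with amplitude n
    return n * np.exp(-k * t)


def _midilli_kucuk(t, a, k, n, b):
    return a * np.exp(-k * t**n) + b * t


def _logarithmic(t, a, k, c):
    return a * np.exp(-k * t) + c


def _verma(t, a, k, c):
    return a * np.exp(-k * t) + (1.0 - a) * np.exp(-c * t)


def _verma_modified(t, a, b, c, n):
    return a * np.exp(-b * t**n) + (1.0 - a) * np.exp(-c * t**n)


@dataclass(frozen=True)
class ModelSpec:
    """A thin-layer model form with its fitting configuration."""

    name: str
    param_names: tuple
    func: object
    bounds: dict  # param -> (lo, hi)
    default_grid: dict  # param -> tuple of start values

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def starts(self) -> np.ndarray:
        """Cartesian product of the per-parameter start grids."""
        grids = [self.default_grid[p] for p in self.param_names]
        return np.array(list(itertools.product(*grids)), dtype=float)

    def bounds_arrays(self):
        lo = np.array([self.bounds[p][0] for p in self.param_names])
        hi = np.array([self.bounds[p][1] for p in self.param_names])
        return lo, hi


# Role-based bounds/grids: rate constants (k, c, and the Verma-modified b)
# live on [1e-6, 10]; shape exponents (n, alpha) on [0.05, 5]; amplitudes
# (a, and the Henderson–Pabis n) are allowed the wide range seen in fitted
# parameter tables; the additive linear slopes of Midilli–Kucuk and
# Wang–Singh may take either sign, so they get symmetric bounds.
_RATE = {"bounds": (1e-6, 10.0), "grid": (1e-4, 1e-3, 1e-2, 1e-1)}
_SHAPE = {"bounds": (0.05, 5.0), "grid": (0.5, 1.0, 1.5, 2.5)}
_AMPL = {"bounds": (-10.0, 10.0), "grid": (0.5, 1.0, 2.0, 4.0)}
_SLOPE = {"bounds": (-1.0, 1.0), "grid": (-1e-2, -1e-3, 1e-4, 1e-3)}
_SCALE = {"bounds": (0.1, 1e4), "grid": (5.0, 20.0, 50.0, 200.0)}
_QUAD = {"bounds": (-1.0, 1.0), "grid": (-1e-3, -1e-4, 1e-4, 1e-3)}


def _spec(name, func, roles):
    return ModelSpec(
        name=name,
        param_names=tuple(roles),
        func=func,
        bounds={p: r["bounds"] for p, r in roles.items()},
        default_grid={p: r["grid"] for p, r in roles.items()},
    )


MODELS: dict[str, ModelSpec] = {
    spec.name: spec
    for spec in (
        _spec("page", _page, {"k": _RATE, "n": _SHAPE}),
        _spec("weibull", _weibull, {"alpha": _SHAPE, "beta": _SCALE}),
        _spec("wang_singh", _wang_singh, {"a": _QUAD, "b": _SLOPE}),
        _spec("henderson_pabis", _henderson_pabis, {"n": _SHAPE, "k": _RATE}),
        _spec(
            "midilli_kucuk",
            _midilli_kucuk,
            {"a": _AMPL, "k": _RATE, "n": _SHAPE, "b": _SLOPE},
        ),
        _spec("logarithmic", _logarithmic, {"a": _AMPL, "k": _RATE, "c": _SLOPE}),
        _spec("verma", _verma, {"a": _AMPL, "k": _RATE, "c": _RATE}),
        _spec(
            "verma_modified",
            _verma_modified,
            {"a": _AMPL, "b": _RATE, "c": _RATE, "n": _SHAPE},
        ),
    )
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise ValidationError(
            f"unknown model {name!r}; available: {sorted(MODELS)}"
        ) from None


# ---------------------------------------------------------------------------
# Moisture ratio and drying rate
# ---------------------------------------------------------------------------

def moisture_ratio(run: DryingRun) -> MoistureRatioCurve:
    """Normalize a drying run to the dimensionless moisture ratio.

    MR(t) = (X(t) - X_e) / (X_0 - X_e); with the default X_e = 0 this is
    simply X(t)/X_0, so MR(0) = 1.
    """
    x0 = run.initial_moisture_db
    xe = run.equilibrium_moisture_db
    if x0 <= xe:
        raise ValidationError(
            f"degenerate run: initial moisture {x0} must exceed equilibrium {xe}"
        )
    mr = (run.moisture_db - xe) / (x0 - xe)
    return MoistureRatioCurve(run.times_min.copy(), mr, unit="min")


def drying_rate(run: DryingRun) -> np.ndarray:
    """Finite-difference drying rate per interval (kg/kg dry matter/min).

    Negative values indicate moisture loss and are reported as-is; the
    result has length N-1.
    """
    if run.n_obs < 2:
        raise InsufficientDataError("drying rate needs at least two time points")
    return np.diff(run.moisture_db) / np.diff(run.times_min)


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def evaluate_model(spec: ModelSpec | str, params, times) -> np.ndarray:
    """Evaluate a thin-layer model at the given times (minutes)."""
    if isinstance(spec, str):
        spec = get_model(spec)
    params = np.asarray(params, dtype=float)
    if params.size != spec.n_params:
        raise ValidationError(
            f"{spec.name} expects {spec.n_params} parameters "
            f"({', '.join(spec.param_names)}), got {params.size}"
        )
    if not np.all(np.isfinite(params)):
        raise ValidationError("model parameters must be finite")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValidationError("model evaluation requires times >= 0")
    return np.asarray(spec.func(t, *params), dtype=float)


# ---------------------------------------------------------------------------
# Fit statistics
# ---------------------------------------------------------------------------

@dataclass
class FitStatistics:
    """Goodness-of-fit suite for a fitted moisture-ratio curve.

    `sse_raw` is the plain residual sum of squares Σr²; `sse_paper` is the
    mean-square variant Σr²/N that some drying studies tabulate under the
    name SSE.  χ² divides Σr² by N − z where z is the number of fitted
    model constants (taken equal to the parameter count p).  The
    log-likelihood is the concentrated Gaussian form
    ln L = -(N/2)[ln 2π + 1 - ln N + ln Σr²], from which
    AIC = 2p - 2 ln L and AICc = AIC + 2p(p+1)/(N-p-1).
    """

    n_obs: int
    n_params: int
    n_constants: int
    sse_raw: float
    sse_paper: float
    rmse: float
    chi2: float
    r2: float
    loglik: float
    aic: float
    aicc: float


def fit_statistics(residuals, mr_exp, n_params: int, n_constants: int | None = None) -> FitStatistics:
    """Compute the full statistic suite from residuals r = MR_exp - MR_pred."""
    r = np.asarray(residuals, dtype=float)
    y = np.asarray(mr_exp, dtype=float)
    n = r.size
    p = int(n_params)
    z = p if n_constants is None else int(n_constants)
    if n <= z:
        raise DegreesOfFreedomError(f"chi-square undefined: N={n} <= z={z}")
    if n <= p + 1:
        raise DegreesOfFreedomError(f"AICc undefined: N={n} <= p+1={p + 1}")
    sse_raw = float(np.dot(r, r))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise DegreesOfFreedomError("R² undefined: zero total sum of squares")
    if sse_raw > 0.0:
        loglik = -0.5 * n * (math.log(2 * math.pi) + 1.0 - math.log(n) + math.log(sse_raw))
    else:  # perfect fit: likelihood unbounded above
        loglik = math.inf
    aic = 2.0 * p - 2.0 * loglik
    aicc = aic + 2.0 * p * (p + 1) / (n - p - 1)
    return FitStatistics(
        n_obs=n,
        n_params=p,
        n_constants=z,
        sse_raw=sse_raw,
        sse_paper=sse_raw / n,
        rmse=math.sqrt(sse_raw / n),
        chi2=sse_raw / (n - z),
        r2=1.0 - sse_raw / sst,
        loglik=loglik,
        aic=aic,
        aicc=aicc,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Controls for the multi-start bounded least-squares fit."""

    ftol: float = 1e-12
    xtol: float = 1e-10
    gtol: float = 1e-12
    max_nfev: int = 2000
    grid_override: dict | None = None  # param -> tuple of starts
    bounds_override: dict | None = None  # param -> (lo, hi)
    n_best_starts: int | None = None  # if set, refine only the top-k grid starts


@dataclass
class FitResult:
    """A fitted thin-layer model with its statistic suite."""

    model: str
    param_names: tuple
    params: np.ndarray
    stats: FitStatistics
    residuals: np.ndarray
    converged: bool
    n_starts_tried: int
    delta_aicc: float | None = None

    @property
    def params_dict(self) -> dict:
        return dict(zip(self.param_names, (float(v) for v in self.params)))

    # convenience passthroughs used all over reports and tests
    @property
    def aicc(self) -> float:
        return self.stats.aicc

    @property
    def r2(self) -> float:
        return self.stats.r2


def _model_with_config(spec: ModelSpec, config: FitConfig) -> ModelSpec:
    if not (config.grid_override or config.bounds_override):
        return spec
    grid = dict(spec.default_grid)
    bounds = dict(spec.bounds)
    for p, values in (config.grid_override or {}).items():
        if p in grid:
            grid[p] = tuple(values)
    for p, values in (config.bounds_override or {}).items():
        if p in bounds:
            bounds[p] = tuple(values)
    return ModelSpec(spec.name, spec.param_names, spec.func, bounds, grid)


def fit_model(
    curve: MoistureRatioCurve,
    spec: ModelSpec | str,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit one thin-layer model to an MR curve by multi-start least squares.

    Every point of the deterministic start grid is refined with bounded
    trust-region least squares; the best local optimum (lowest SSE) wins.
    Identical inputs always produce identical results: the grid is fixed
    and no random jitter is applied.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    config = config or FitConfig()
    spec = _model_with_config(spec, config)

    work = curve if curve.unit == "min" else curve.in_unit("min")
    t = work.times
    y = work.mr
    n = t.size
    if n < spec.n_params + 2:
        raise InsufficientDataError(
            f"{spec.name} needs at least {spec.n_params + 2} points, got {n}"
        )

    lo, hi = spec.bounds_arrays()

    def residual(theta):
        return spec.func(t, *theta) - y

    starts = np.clip(spec.starts(), lo + 1e-12, hi - 1e-12)
    if config.n_best_starts is not None and config.n_best_starts < len(starts):
        sses = np.array([float(np.sum(residual(s) ** 2)) for s in starts])
        keep = np.argsort(sses)[: config.n_best_starts]
        starts = starts[keep]

    best = None
    diagnostics = []
    for x0 in starts:
        try:
            sol = least_squares(
                residual,
                x0,
                bounds=(lo, hi),
                method="trf",
                ftol=config.ftol,
                xtol=config.xtol,
                gtol=config.gtol,
                max_nfev=config.max_nfev,
            )
        except Exception as exc:  # singular Jacobian, overflow at a start, ...
            diagnostics.append({"x0": x0.tolist(), "error": str(exc)})
            continue
        diagnostics.append({"x0": x0.tolist(), "cost": float(sol.cost), "status": sol.status})
        if sol.status > 0 and (best is None or sol.cost < best.cost):
            best = sol

    if best is None:
        raise NonConvergenceError(
            f"no start converged for model {spec.name}", diagnostics=diagnostics
        )

    resid = y - spec.func(t, *best.x)
    stats = fit_statistics(resid, y, spec.n_params)
    return FitResult(
        model=spec.name,
        param_names=spec.param_names,
        params=np.asarray(best.x, dtype=float),
        stats=stats,
        residuals=resid,
        converged=True,
        n_starts_tried=len(starts),
    )


def fit_all_models(
    curve: MoistureRatioCurve,
    models=None,
    config: FitConfig | None = None,
) -> list[FitResult]:
    """Fit every requested model (default: all eight) to the same curve."""
    names = list(models) if models else list(MODELS)
    fits = []
    for name in names:
        try:
            fits.append(fit_model(curve, name, config))
        except (InsufficientDataError, NonConvergenceError):
            continue
    if not fits:
        raise NonConvergenceError("no model could be fitted to the curve")
    return fits


def select_model(fits: list[FitResult]) -> list[FitResult]:
    """Rank fits by ascending AICc; return a new list with ΔAICc filled in.

    Ties within 1e-9 are broken by fewer parameters, then model name.
    """
    if not fits:
        raise ValidationError("select_model requires at least one fit")
    def tie_key(value: float) -> float:
        # quantize to the 1e-9 tie tolerance; leave infinities as-is
        return round(value / 1e-9) * 1e-9 if math.isfinite(value) else value

    order = sorted(
        range(len(fits)),
        key=lambda i: (tie_key(fits[i].stats.aicc), fits[i].stats.n_params, fits[i].model),
    )
    ranked = [fits[i] for i in order]
    best = ranked[0].stats.aicc
    for f in ranked:
        f.delta_aicc = f.stats.aicc - best
    return ranked
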