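"""Thin-layer model evaluation, fitting, statistics and selection."""
import math

import numpy as np
import pytest
from scipy.optimize import least_squares

from algadry.errors import (
    DegreesOfFreedomError,
    InsufficientDataError,
    ValidationError,
)
from algadry.kinetics import (
    MODELS,
    FitConfig,
    drying_rate,
    evaluate_model,
    fit_all_models,
    fit_model,
    fit_statistics,
    moisture_ratio,
    select_model,
)
from algadry.types import DryingRun, MoistureRatioCurve

from conftest import MIDILLI_REF


def _make_run(times, x, **kw):
    defaults = dict(
        label="t",
        air_temp_C=30.0,
        air_velocity_m_s=2.0,
        rel_humidity_pct=83.0,
        dry_mass_kg=0.01875,
    )
    defaults.update(kw)
    return DryingRun(times_min=np.asarray(times, float), moisture_db=np.asarray(x, float), **defaults)


class TestMoistureRatio:
    def test_normalizes_by_initial(self):
        run = _make_run([0, 7, 14], [7.0, 3.5, 0.7])
        assert np.allclose(moisture_ratio(run).mr, [1.0, 0.5, 0.1])

    def test_constant_series_gives_unity(self):
        run = _make_run([0, 7, 14], [3.0, 3.0, 3.0])
        assert np.allclose(moisture_ratio(run).mr, 1.0)

    def test_equilibrium_offset(self):
        run = _make_run([0, 7, 14], [8.0, 5.0, 2.0], equilibrium_moisture_db=2.0)
        assert np.allclose(moisture_ratio(run).mr, [1.0, 0.5, 0.0])

    def test_degenerate_run_rejected(self):
        run = _make_run([0, 7], [2.0, 2.0], equilibrium_moisture_db=2.0)
        with pytest.raises(ValidationError, match="degenerate"):
            moisture_ratio(run)


class TestDryingRate:
    def test_uniform_interval(self):
        run = _make_run([0, 7], [7.0, 6.3])
        assert drying_rate(run) == pytest.approx([-0.1])

    def test_nonuniform_intervals(self, simple_run):
        assert drying_rate(simple_run) == pytest.approx([-0.05, -0.0125])

    def test_constant_moisture_zero_rate(self):
        run = _make_run([0, 7, 14], [2.0, 2.0, 2.0])
        assert np.allclose(drying_rate(run), 0.0)

    def test_single_point_rejected(self):
        run = _make_run([0], [7.0])
        with pytest.raises(InsufficientDataError):
            drying_rate(run)


class TestEvaluateModel:
    @pytest.mark.parametrize(
        "model, params, t, expected",
        [
            ("page", (0.007, 1.350), 0.0, 1.0),
            ("midilli_kucuk", MIDILLI_REF[30], 0.0, 0.993),  # MR(0) = a
            ("wang_singh", (0.0001, -0.019), 10.0, 0.82),  # 0.01 - 0.19 + 1
            ("henderson_pabis", (1.0, 0.1), 0.0, 1.0),
            ("weibull", (1.0, 10.0), 10.0, math.exp(-1.0)),
            ("verma", (2.0, 0.1, 0.2), 0.0, 1.0),  # a + (1-a) = 1 at t=0
            ("verma_modified", (0.5, 0.1, 0.2, 1.0), 0.0, 1.0),
            ("logarithmic", (1.0, 0.1, -0.054), 0.0, 0.946),
        ],
    )
    def test_closed_forms(self, model, params, t, expected):
        assert evaluate_model(model, params, [t])[0] == pytest.approx(expected)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_model("page", (0.01, 1.0), [-1.0])

    def test_nonfinite_params_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_model("page", (np.nan, 1.0), [0.0])

    def test_wrong_param_count_rejected(self):
        with pytest.raises(ValidationError, match="expects 4"):
            evaluate_model("midilli_kucuk", (0.9, 0.01), [0.0])

    def test_registry_parameter_counts(self):
        expected = {
            "page": 2, "weibull": 2, "wang_singh": 2, "henderson_pabis": 2,
            "midilli_kucuk": 4, "logarithmic": 3, "verma": 3, "verma_modified": 4,
        }
        assert {name: spec.n_params for name, spec in MODELS.items()} == expected
        for spec in MODELS.values():
            for lo, hi in spec.bounds.values():
                assert np.isfinite(lo) and np.isfinite(hi) and lo < hi


class TestFitStatistics:
    def test_perfect_fit(self):
        y = np.array([1.0, 0.5, 0.25, 0.1, 0.05, 0.01])
        s = fit_statistics(np.zeros(6), y, n_params=2)
        assert s.sse_raw == 0 and s.sse_paper == 0 and s.rmse == 0 and s.chi2 == 0
        assert s.r2 == 1.0

    def test_constant_residual_rmse(self):
        y = np.linspace(1, 0, 10)
        s = fit_statistics(np.full(10, -0.3), y, n_params=2)
        assert s.rmse == pytest.approx(0.3)
        assert s.sse_paper == pytest.approx(0.09)
        assert s.chi2 == pytest.approx(0.9 / 8)  # sum r^2 / (N - z)

    def test_aicc_correction_term(self):
        # N=44, p=4: AICc - AIC = 2*4*5/39
        y = np.linspace(1, 0, 44)
        s = fit_statistics(np.full(44, 0.0047672), y, n_params=4)
        assert s.aicc - s.aic == pytest.approx(2 * 4 * 5 / 39)
        assert s.aicc - s.aic == pytest.approx(1.0256, abs=1e-4)

    def test_loglik_concentrated_gaussian(self):
        # independent check: lnL = -(N/2)(ln 2pi + 1 + ln(sse/N))
        rng = np.random.default_rng(0)
        r = rng.normal(0, 0.1, 20)
        y = np.linspace(1, 0, 20)
        s = fit_statistics(r, y, n_params=2)
        sse = float(np.sum(r**2))
        expected = -10.0 * (math.log(2 * math.pi) + 1 + math.log(sse / 20))
        assert s.loglik == pytest.approx(expected, rel=1e-12)
        assert s.aic == pytest.approx(4 - 2 * expected, rel=1e-12)

    def test_aicc_approaches_aic_for_large_n(self):
        y = np.linspace(1, 0, 10**6)
        s = fit_statistics(np.full(10**6, 0.01), y, n_params=4)
        assert s.aicc > s.aic
        assert s.aicc - s.aic < 1e-3

    def test_degrees_of_freedom_guards(self):
        y = np.linspace(1, 0, 5)
        with pytest.raises(DegreesOfFreedomError):
            fit_statistics(np.zeros(5), y, n_params=4)  # N <= p+1
        with pytest.raises(DegreesOfFreedomError):
            fit_statistics(np.zeros(3), y[:3], n_params=2, n_constants=3)

    def test_zero_sst_rejected(self):
        with pytest.raises(DegreesOfFreedomError, match="R"):
            fit_statistics(np.zeros(6), np.full(6, 0.5), n_params=2)


class TestFitModel:
    def test_noise_free_midilli_round_trip(self, midilli_30C_curve):
        fit = fit_model(midilli_30C_curve, "midilli_kucuk")
        for name, true in zip(("a", "k", "n", "b"), MIDILLI_REF[30]):
            assert fit.params_dict[name] == pytest.approx(true, rel=1e-3)
        assert fit.converged

    def test_page_recovers_plain_exponential(self):
        t = np.arange(0, 200, 7.0)
        curve = MoistureRatioCurve(t, np.exp(-0.02 * t), "min")
        fit = fit_model(curve, "page")
        assert fit.params_dict["k"] == pytest.approx(0.02, rel=1e-6)
        assert fit.params_dict["n"] == pytest.approx(1.0, rel=1e-6)
        assert fit.stats.r2 >= 1 - 1e-10

    def test_insufficient_points_rejected(self):
        t = np.array([0.0, 7.0, 14.0])
        curve = MoistureRatioCurve(t, np.exp(-0.01 * t), "min")
        with pytest.raises(InsufficientDataError):
            fit_model(curve, "midilli_kucuk")  # 4 params need >= 6 points

    def test_seconds_curve_converted_to_minutes(self, midilli_30C_curve):
        fit_min = fit_model(midilli_30C_curve, "page")
        fit_s = fit_model(midilli_30C_curve.in_unit("s"), "page")
        assert fit_s.params_dict["k"] == pytest.approx(fit_min.params_dict["k"], rel=1e-6)

    def test_deterministic_given_config(self, midilli_30C_curve):
        f1 = fit_model(midilli_30C_curve, "midilli_kucuk")
        f2 = fit_model(midilli_30C_curve, "midilli_kucuk")
        assert np.array_equal(f1.params, f2.params)


def _verma_canonical(params_dict):
    """Resolve the (k, c) <-> (c, k), a <-> 1-a reflection symmetry."""
    a, k, c = params_dict["a"], params_dict["k"], params_dict["c"]
    return (a, k, c) if k >= c else (1 - a, c, k)


class TestTableParameterRecovery:
    """Noise-free round trip for all eight models at literature-scale values."""

    CASES = {
        "page": (0.007, 1.350),
        "weibull": (1.350, 37.696),
        "wang_singh": (0.0001, -0.019),
        "henderson_pabis": (1.0572, 0.0257),
        "midilli_kucuk": MIDILLI_REF[30],
        "logarithmic": (1.106, 0.023, -0.054),
        "verma": (2.002, 0.035, 0.055),
        "verma_modified": (4.240, 0.039, 0.046, 1.000),
    }

    @pytest.mark.parametrize("model", sorted(CASES))
    def test_recovery(self, model):
        params = self.CASES[model]
        t = np.arange(44) * 7.0
        if model == "wang_singh":
            # the quadratic only describes drying up to its vertex at
            # t = -b/2a; keep the descending branch
            t = t[t <= -params[1] / (2 * params[0])]
        mr = evaluate_model(model, params, t)
        fit = fit_model(MoistureRatioCurve(t, mr, "min"), model)
        got = fit.params_dict
        want = dict(zip(MODELS[model].param_names, params))
        if model in ("verma", "verma_modified"):
            key = "k" if model == "verma" else "b"
            sym = dict(got)
            if sym[key] < sym["c"]:
                sym[key], sym["c"] = sym["c"], sym[key]
                sym["a"] = 1 - sym["a"]
            got = sym
            if want[key] < want["c"]:
                want[key], want["c"] = want["c"], want[key]
                want["a"] = 1 - want["a"]
        for name, true in want.items():
            assert got[name] == pytest.approx(true, rel=1e-3, abs=1e-9), (
                f"{model}.{name}"
            )


class TestGridSearchOracle:
    def test_multistart_matches_exhaustive_grid(self):
        """2-parameter fit equals a 200x200 grid search refined once."""
        t = np.arange(15) * 7.0
        rng = np.random.default_rng(7)
        mr = np.exp(-0.011 * t**1.2) + rng.normal(0, 0.004, t.size)
        mr[0] = 1.0
        curve = MoistureRatioCurve(t, mr, "min")
        fit = fit_model(curve, "page")

        spec = MODELS["page"]
        (klo, khi), (nlo, nhi) = spec.bounds["k"], spec.bounds["n"]
        ks = np.logspace(np.log10(klo), np.log10(khi), 200)
        ns = np.linspace(nlo, nhi, 200)
        K, N = np.meshgrid(ks, ns, indexing="ij")
        pred = np.exp(-K[..., None] * t**N[..., None])
        sse = ((pred - mr) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        refined = least_squares(
            lambda p: np.exp(-p[0] * t ** p[1]) - mr,
            [ks[i], ns[j]],
            bounds=([klo, nlo], [khi, nhi]),
        )
        assert fit.stats.sse_raw <= 2 * refined.cost + 1e-8


class TestNoiseDegradation:
    def test_median_error_monotone_in_sigma(self, midilli_30C_curve):
        """Median k-error does not decrease as MR noise grows."""
        t = midilli_30C_curve.times
        clean = midilli_30C_curve.mr
        cfg = FitConfig(n_best_starts=12)
        true_k = MIDILLI_REF[30][1]
        medians = []
        for sigma in (0.0, 0.005, 0.02):
            errs = []
            for seed in range(5):
                rng = np.random.default_rng(100 + seed)
                mr = np.clip(clean + rng.normal(0, sigma, clean.size), 1e-6, None)
                fit = fit_model(MoistureRatioCurve(t, mr, "min"), "midilli_kucuk", cfg)
                errs.append(abs(fit.params_dict["k"] - true_k) / true_k)
            medians.append(float(np.median(errs)))
        assert medians[0] <= medians[1] <= medians[2]


class TestSelectModel:
    def test_single_fit_ranks_first(self, midilli_30C_curve):
        fit = fit_model(midilli_30C_curve, "page")
        ranked = select_model([fit])
        assert ranked[0].model == "page" and ranked[0].delta_aicc == 0.0

    def test_orders_by_aicc(self, midilli_30C_curve):
        fits = fit_all_models(midilli_30C_curve, models=["page", "henderson_pabis"])
        ranked = select_model(fits)
        assert ranked[0].stats.aicc <= ranked[1].stats.aicc
        assert ranked[1].delta_aicc >= 0

    def test_generating_model_wins_on_its_own_data(self, midilli_30C_curve):
        t = midilli_30C_curve.times
        rng = np.random.default_rng(3)
        mr = np.clip(midilli_30C_curve.mr + rng.normal(0, 0.005, t.size), 0, None)
        mr /= mr[0]
        curve = MoistureRatioCurve(t, mr, "min")
        fits = fit_all_models(
            curve,
            models=["midilli_kucuk", "page", "henderson_pabis", "logarithmic"],
            config=FitConfig(n_best_starts=12),
        )
        assert select_model(fits)[0].model == "midilli_kucuk"

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            select_model([])
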