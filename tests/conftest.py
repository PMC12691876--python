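import numpy as np
import pytest

from algadry.kinetics import evaluate_model
from algadry.types import DryingRun, MoistureRatioCurve

# Reference Midilli–Kucuk parameter sets (a, k, n, b) per air temperature
MIDILLI_REF = {
    30: (0.993, 0.009, 1.264, 0.0001),
    40: (0.989, 0.020, 1.225, 0.0002),
    50: (0.996, 0.027, 1.270, 0.00001),
}


@pytest.fixture(scope="session")
def midilli_30C_curve():
    """Noise-free 30 °C moisture-ratio curve, 7-min sampling over 300 min."""
    t = np.arange(44) * 7.0  # 0, 7, ..., 301
    mr = evaluate_model("midilli_kucuk", MIDILLI_REF[30], t)
    return MoistureRatioCurve(t, mr, unit="min")


@pytest.fixture
def simple_run():
    """Small hand-checkable drying run: X halves then quarters."""
    return DryingRun(
        label="simple",
        air_temp_C=40.0,
        air_velocity_m_s=2.0,
        rel_humidity_pct=83.0,
        times_min=np.array([0.0, 10.0, 30.0]),
        moisture_db=np.array([1.0, 0.5, 0.25]),
        dry_mass_kg=0.1,
    )


try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass
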