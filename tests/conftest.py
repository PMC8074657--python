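import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wheezekit as wk
from wheezekit.fluid_law import RigConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bench_tube() -> wk.TubeGeometry:
    """The l = 23 mm, l0 = 20.4 mm, h = 0.35 mm, d = 6 mm rubber tube."""
    return wk.EXAMPLE_TUBE


@pytest.fixture(scope="session")
def rubber() -> wk.Material:
    return wk.EXAMPLE_MATERIAL


@pytest.fixture(scope="session")
def rig(bench_tube) -> RigConfig:
    return RigConfig.for_tube(bench_tube)


@pytest.fixture(scope="session")
def bench_sweep(bench_tube, rubber, rig):
    """50-point quasi-steady suction sweep of the bench tube."""
    from wheezekit.equilibrium import sweep_suction

    return sweep_suction(bench_tube, rubber, rig, np.linspace(-50.0, -1500.0, 50))


@pytest.fixture(scope="session")
def prescribed_run(bench_tube):
    """Short synthetic run with a prescribed 164 Hz tone from t = 3 s."""
    from wheezekit.synthetic_data import RunScenario, generate_run

    scenario = RunScenario(
        geom=bench_tube,
        t1=1.0, t2=4.0, t3=6.0, t4=9.0, duration=10.0,
        onset_time=3.0, onset_freq=164.0, seed=11,
    )
    return scenario, generate_run(scenario)
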