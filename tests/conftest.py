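import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from fluctlight.gasex_io import (GasExchangeTrace, LightResponseTable,
                                 TraceMeta)
from fluctlight.light_response import SteadyStateReference, nrh_curve


def trace_frame(n=6, dt=0.5, **overrides):
    """Minimal well-formed trace frame with canonical columns."""
    t = np.arange(n) * dt
    base = {
        "t_s": t,
        "pfd_in": np.full(n, 800.0),
        "co2_s": np.full(n, 400.0),
        "h2o_s": np.full(n, 20.0),
        "a_raw": np.full(n, 10.0),
        "e_raw": np.full(n, 2e-3),
        "ci": np.full(n, 280.0),
        "gsw": np.full(n, 0.2),
        "p_air": np.full(n, 101325.0),
        "t_air": np.full(n, 298.15),
        "flow": np.full(n, 600.0),
        "s_leaf": np.full(n, 6e-4),
    }
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture
def simple_trace():
    return GasExchangeTrace(trace_frame(), TraceMeta(species="demo"))


def make_light_response(phi=0.06, a_max=25.0, theta=0.7, rd=1.0,
                        levels=(2000, 1700, 1500, 1200, 1000, 800, 600, 400,
                                300, 200, 100, 75, 30, 0),
                        noise_sd=0.0, seed=0):
    levels = np.asarray(levels, dtype=float)
    a = nrh_curve(levels, phi, a_max, theta, rd)
    if noise_sd:
        a = a + np.random.default_rng(seed).normal(0, noise_sd, len(levels))
    return LightResponseTable(pd.DataFrame({
        "pfd_in": levels, "a": a,
        "ci": np.full(len(levels), 300.0),
        "gsw": np.full(len(levels), 0.2),
    }))


@pytest.fixture
def reference():
    return SteadyStateReference(a_800=12.0, a_100=4.0, ci_800=250.0,
                                ci_100=340.0, rd=1.0, phi_800=0.016,
                                phi_100=0.05)
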