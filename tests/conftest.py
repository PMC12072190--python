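import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import leedna as L

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def film():
    """Reference film: 20 nm, λ = 12 nm, mild charging."""
    return L.FilmParameters(h=20.0, lambda_att=12.0, tau=10.0, J=1e11, P0=100.0)


@pytest.fixture(scope="session")
def table1():
    return L.load_table1()


@pytest.fixture(scope="session")
def bare_table(table1):
    return table1[0]


@pytest.fixture(scope="session")
def arg_table(table1):
    return table1[1]


def linear_curve(slope_per_band=None, n=8, fmax=1e13, energy=10.0, **kwargs):
    """Exactly linear noiseless curve builder shared by several tests."""
    slope_per_band = slope_per_band or {}
    fluence = np.linspace(0.0, fmax, n)
    bands = {}
    gains = {b: slope_per_band.get(b, 0.0) for b in ("circular", "linear", "crosslink")}
    for b, s in gains.items():
        bands[b] = s * fluence
    bands["supercoiled"] = 100.0 - sum(bands[b] for b in gains)
    return L.FluenceResponseCurve(
        energy=energy, thickness=20.0, treatment=L.Treatment.NONE,
        fluence=fluence, bands=bands, **kwargs)
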