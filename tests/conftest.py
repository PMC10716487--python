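import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from spffs import (
    DetectorGeometry,
    EmitterSpecies,
    LaserConfig,
    PhotonStream,
    SimulationConfig,
    simulate_fcs,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_stream(channels, t_abs_ns, microtimes_ns=None, duration_s=0.0, **kw):
    return PhotonStream(
        channels=np.asarray(channels, dtype=np.uint8),
        t_abs_ns=np.asarray(t_abs_ns, dtype=np.uint64),
        microtimes_ns=None if microtimes_ns is None else np.asarray(microtimes_ns, float),
        duration_s=duration_s,
        **kw,
    )


@pytest.fixture
def tiny_stream():
    """Three photons on channels 12, 0, 25 with microtimes."""
    return make_stream([12, 0, 25], [100, 250, 900], [3.2, 11.0, 0.7], duration_s=1e-6)


@pytest.fixture(scope="session")
def poisson_stream():
    """Homogeneous 100 kHz Poisson stream, 1 s, single channel."""
    r = np.random.default_rng(7)
    n = r.poisson(100_000)
    t = np.sort(r.uniform(0, 1e9, n)).astype(np.uint64)
    return make_stream(np.full(n, 12), t, duration_s=1.0)


@pytest.fixture(scope="session")
def free_fcs_stream():
    """Short free-diffusion acquisition shared by the pipeline tests.

    20 s, D = 10 µm²/s, the calibrated nested volumes; bright enough for
    stable correlation curves at this duration.
    """
    cfg = SimulationConfig(
        duration_s=20.0,
        dt_us=20.0,
        seed=42,
        species=[EmitterSpecies(D_um2_s=10.0, brightness_cps=5e5, n_emitters=500)],
    )
    return cfg, simulate_fcs(cfg)
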