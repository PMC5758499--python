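import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from calyxkit.protocol import make_stimulus_protocol
from calyxkit.synth import (EventGroundTruth, synthesize_juxtacellular_trace,
                            wt_like_ground_truth)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    return make_stimulus_protocol()


@pytest.fixture(scope="session")
def wt_truth():
    return wt_like_ground_truth()


def make_trace(times, slopes, dvdts, prespikes, failures, kernel=None,
               noise_sd=0.0, seed=0, duration=None):
    """Render a juxtacellular trace from explicit per-event truth."""
    k = kernel or wt_like_ground_truth().kernel
    times = np.asarray(times, dtype=float)
    n = times.size
    gt = EventGroundTruth(
        times,
        np.broadcast_to(np.asarray(slopes, dtype=float), (n,)).copy(),
        np.broadcast_to(np.asarray(dvdts, dtype=float), (n,)).copy(),
        np.broadcast_to(np.asarray(prespikes, dtype=float), (n,)).copy(),
        np.broadcast_to(np.asarray(failures, dtype=bool), (n,)).copy(),
    )
    return synthesize_juxtacellular_trace(
        gt, k, noise_sd, 50_000.0, seed=seed,
        duration=duration if duration is not None else float(times.max() + 20.0 if n else 50.0),
    )
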