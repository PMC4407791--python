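import numpy as np
import pytest

import pocketmotion as pm


@pytest.fixture(scope="session")
def default_dataset():
    """Balanced 5-class feature table from the default generator (250 rows)."""
    return pm.gen_dataset(n_per_class=50, seed=0)


@pytest.fixture(scope="session")
def walking_recording():
    """A 30 s single-activity walking recording (default placement)."""
    return pm.gen_recording(
        [pm.ActivityAnnotation(0.0, 30.0, "walking")], seed=3
    )


@pytest.fixture()
def uniform_recording():
    """Small deterministic 3-sensor recording on a uniform 25 Hz grid."""
    rng = np.random.default_rng(42)
    t = np.arange(0, 20.0, 1 / 25.0)
    traces = {}
    for kind in ("accelerometer", "gyroscope", "magnetometer"):
        xyz = rng.normal(size=(len(t), 3))
        if kind == "accelerometer":
            xyz[:, 2] += 9.81
        traces[kind] = pm.SensorTrace(kind, 25.0, t, xyz)
    return pm.Recording(
        traces=traces,
        annotations=[pm.ActivityAnnotation(0.0, 20.0, "static")],
    )
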