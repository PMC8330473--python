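import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A 4-habitat 128x128 scene with well-separated colours and a target."""
    from patchcamo import synth

    mhs = tuple(
        synth.MicrohabitatSpec(name, mean, (2.0, 1.0, 1.0), 0.25, 8.0)
        for name, mean in [
            ("h0", (30.0, 0.0, 0.0)),
            ("h1", (50.0, 20.0, 10.0)),
            ("h2", (60.0, -20.0, 10.0)),
            ("h3", (75.0, 0.0, -20.0)),
        ]
    )
    spec = synth.SceneSpec(128, 128, 0.08, mhs, seed=11)
    return synth.place_target(synth.generate_scene(spec), height_mm=400.0)
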