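import numpy as np
import pytest

from sfdibruise import synth


@pytest.fixture(scope="session")
def apple_map_64():
    spec = synth.FruitSceneSpec(fruit_kind="apple", size=64, seed=3)
    return synth.make_fruit_map(spec)


@pytest.fixture(scope="session")
def reference_64():
    return synth.render_reference_stack(
        shape=(64, 64), pixel_size=synth.FIELD_WIDTH_MM / 64
    )


@pytest.fixture(scope="session")
def smoke_dataset(tmp_path_factory):
    """Small paired dataset (40 scenes, 64x64) shared by training tests."""
    out = tmp_path_factory.mktemp("smoke_ds")
    sweep = {
        "mu_a": np.linspace(0.02, 0.4, 5).tolist(),
        "mu_s_prime": np.linspace(0.6, 3.4, 4).tolist(),
        "severity": [0.0, 1.0],
    }
    manifest = synth.build_dataset(out, seed=7, sweep=sweep, size=64)
    return manifest, out
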