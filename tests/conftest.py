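import numpy as np
import pandas as pd
import pytest

from jagaze.io import DEFAULT_GEOMETRY, load_default_design


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def design():
    return load_default_design()


@pytest.fixture(scope="session")
def presets():
    # calibrating the packaged presets solves a least-squares problem once
    from jagaze.simulate import calibrated_presets

    return calibrated_presets()


def make_samples(t_ms, x_px, y_px, valid=None):
    """Canonical sample frame from plain arrays (both eyes share validity)."""
    t_ms = np.asarray(t_ms, dtype=float)
    if valid is None:
        valid = np.ones(len(t_ms), dtype=int)
    return pd.DataFrame(
        {
            "t_ms": t_ms,
            "x_px": np.asarray(x_px, dtype=float),
            "y_px": np.asarray(y_px, dtype=float),
            "valid_l": np.asarray(valid, dtype=int),
            "valid_r": np.asarray(valid, dtype=int),
        }
    )


@pytest.fixture
def samples_factory():
    return make_samples
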