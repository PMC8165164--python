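import warnings

import numpy as np
import pytest

from aviforage import SimConfig, write_fixture_set
from aviforage.config import ArenaGeometry

warnings.filterwarnings("ignore", category=FutureWarning)


def small_config(**overrides) -> SimConfig:
    """A fast two-condition design (short sessions, low frame rate)."""
    kwargs = dict(
        n_birds=2,
        conditions=("Wall", "Stranger"),
        n_sessions=2,
        session_length=60.0,
        fps=10.0,
        latency_mean={"Wall": (8.0, 6.0), "Stranger": (10.0, 8.0)},
        seed=11,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def fast_cfg() -> SimConfig:
    return small_config()


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory, fast_cfg):
    """A written fixture set shared by the I/O and pipeline tests."""
    out = tmp_path_factory.mktemp("fixtures")
    manifest = write_fixture_set(fast_cfg, out)
    return out, manifest


@pytest.fixture
def arena() -> ArenaGeometry:
    return ArenaGeometry()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
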