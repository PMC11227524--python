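import numpy as np
import pytest

from hjdpose import CohortSpec, KeypointSchema, MocapRecording, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def schema():
    return KeypointSchema()


def random_recording(rng, n_frames=20, with_nans=False, schema=None):
    """Small random recording helper used across test modules."""
    schema = schema or KeypointSchema()
    pos = rng.normal(0.0, 100.0, size=(n_frames, 12, 3))
    if with_nans:
        mask = rng.random(pos.shape[:2]) < 0.1
        pos[mask] = np.nan
    return MocapRecording("T1", pos, 100.0, 0.0, schema)


@pytest.fixture
def make_recording(rng):
    return lambda **kw: random_recording(rng, **kw)


@pytest.fixture(scope="session")
def short_subject():
    """One delta = 1 subject with 20 s stages, reused by feature tests."""
    spec = CohortSpec(
        seed=3,
        stage_durations={"B1": 20, "B2": 20, "CR1": 20, "CR2": 20, "DC": 20},
    )
    return generate_subject(spec, 0)
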