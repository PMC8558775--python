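import numpy as np
import pytest

from pupvox.calibration import CalibrationConvention
from pupvox.synth import SynthCallParams

FS = 16000.0


@pytest.fixture(scope="session")
def cal():
    return CalibrationConvention()


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def default_params():
    return SynthCallParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_260_927)


@pytest.fixture(scope="session")
def small_session(cal, default_params):
    """One assembled 9x8s-block session with ~20 calls, reused read-only."""
    from pupvox.synth import assemble_session, make_session_design, schedule_calls

    design = make_session_design(8.0, seed=5)
    schedule = schedule_calls(design, default_params, ["a", "b"], 1.2, 77)
    session, annots, noise = assemble_session(
        design, default_params, schedule, cal, 99, sample_rate=FS
    )
    return design, schedule, session, annots, noise
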