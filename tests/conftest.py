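import numpy as np
import pytest

from pedfem import FootParams, generate_foot


@pytest.fixture(scope="session")
def foot_model():
    """A single mid-severity synthetic right foot (default study mesh)."""
    return generate_foot(FootParams(seed=1, severity=0.7))


@pytest.fixture(scope="session")
def severe_foot():
    return generate_foot(FootParams(seed=3, severity=0.9))
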