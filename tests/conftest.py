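import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session", autouse=True)
def warm_train_kernel():
    """Trigger the one-off jit compilation outside of timed assertions."""
    from zoomnn import NEWFM

    X = np.array([[0.0], [1.0]])
    NEWFM(max_epochs=1).fit(X, np.array([0, 1]))


@pytest.fixture
def separable_1d():
    """The canonical linearly separable 1-D dataset."""
    X = np.array([[0.1], [0.2], [0.8], [0.9]])
    y = np.array([0, 0, 1, 1])
    return X, y
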