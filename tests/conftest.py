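import numpy as np
import pytest

from fedbids.model_zoo import DenseNetSpec
from fedbids.synthetic import PhantomConfig, generate_dataset


@pytest.fixture(scope="session")
def small_spec():
    return DenseNetSpec.small()


@pytest.fixture(scope="session")
def phantom_dataset(tmp_path_factory):
    """A 10-subject phantom BIDS dataset shared across read-only tests."""
    root = tmp_path_factory.mktemp("bids") / "dataset"
    config = PhantomConfig(n_subjects=10, seed=42)
    generate_dataset(config, root)
    return root, config


def finite_difference_grad(f, x, eps=1e-3):
    """Central finite differences of scalar f at every element of x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g
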