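import numpy as np
import pytest

from tdfe import AnnotatedTensor, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_tensor(values, roles=None, time_values=None, class_labels=None):
    """Wrap a raw array in an AnnotatedTensor with generated labels."""
    values = np.asarray(values, dtype=float)
    if roles is None:
        roles = ["sample"] * (values.ndim - 1) + ["gene"]
    labels = [
        [f"m{k}_{j}" for j in range(n)] if roles[k] != "gene"
        else [f"G{j:04d}" for j in range(n)]
        for k, n in enumerate(values.shape)
    ]
    return AnnotatedTensor(values, roles, labels,
                           class_labels=class_labels or {},
                           time_values=time_values or {})


@pytest.fixture
def random_345(rng):
    return make_tensor(rng.normal(size=(3, 4, 5)))


@pytest.fixture
def tiny_config():
    """Reduced-size study conditions for fast pipeline tests."""
    return SyntheticConfig(
        n_compounds=12,
        n_times=4,
        n_samples_per_class=8,
        n_genes=200,
        n_signal_genes=12,
        n_active_compounds=3,
        seed=11,
    )
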