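import numpy as np
import pytest

from pkqspr.simulate import GeneratorConfig, generate_qspr_dataset, generate_structures


@pytest.fixture(scope="session")
def default_dataset():
    """Synthetic compound set at the generator's default study conditions."""
    return generate_qspr_dataset(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def scaled_xy(default_dataset):
    """Autoscaled descriptor matrix and (logVss, fu) responses, complete rows only."""
    cset, truth = default_dataset
    mask = ~cset.fu_missing_mask
    X = cset.descriptors[mask]
    Y = np.column_stack([cset.log_vss[mask], cset.fu[mask]])
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    return Xs, Ys, truth, mask


@pytest.fixture(scope="session")
def separable_3class():
    """Three well-separated Gaussian classes with imbalanced sizes."""
    rng = np.random.default_rng(42)
    sizes = (40, 25, 60)
    X = []
    y = []
    for cls, (size, shift) in enumerate(zip(sizes, (0.0, 8.0, 16.0)), start=1):
        block = rng.normal(size=(size, 6))
        block[:, 0] += shift
        X.append(block)
        y.extend([cls] * size)
    return np.vstack(X), np.asarray(y)


@pytest.fixture(scope="session")
def toy_mols():
    return generate_structures(12, seed=0)
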