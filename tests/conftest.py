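import numpy as np
import pytest

import mvda


@pytest.fixture(scope="session")
def small_dataset():
    """2 views x 120 patients, 2 classes x 2 subclasses, moderate signal."""
    spec = mvda.SyntheticSpec(
        n_patients=120,
        n_classes=2,
        subclasses_per_class=(2, 2),
        views=(
            mvda.SyntheticViewSpec(
                n_features=60, n_informative_blocks=4, block_size=10,
                within_block_correlation=0.3, effect_size=2.0,
            ),
            mvda.SyntheticViewSpec(
                n_features=60, n_informative_blocks=4, block_size=10,
                within_block_correlation=0.3, effect_size=2.0,
            ),
        ),
        seed=7,
    )
    return mvda.generate(spec)


@pytest.fixture()
def block_view():
    """One view with 4 planted correlated feature blocks and no class signal."""
    spec = mvda.SyntheticSpec(
        n_patients=120,
        n_classes=1,
        subclasses_per_class=(1,),
        views=(
            mvda.SyntheticViewSpec(
                n_features=40, n_informative_blocks=4, block_size=10,
                within_block_correlation=0.8, effect_size=0.0,
            ),
        ),
        seed=11,
    )
    dataset, truth = mvda.generate(spec)
    return dataset.views[0], truth


def planted_partition(n: int, k: int) -> np.ndarray:
    """Balanced hard partition of n items into k groups."""
    return np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
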