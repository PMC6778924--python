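import numpy as np
import pytest

from bioselect.synthetic import SyntheticSpec, generate_dataset


def surrogate_fitness(mask):
    """Cardinality surrogate: fraction of selected features (optimum: all ones)."""
    mask = np.asarray(mask)
    return mask.sum() / mask.size


@pytest.fixture
def surrogate():
    return surrogate_fitness


@pytest.fixture
def small_dataset():
    """60-row separable table: 2 informative, 1 duplicate, 2 noise features."""
    dataset, truth = generate_dataset(
        SyntheticSpec(n_instances=60, n_informative=2, n_redundant=1,
                      n_noise=2, effect_size=3.0, noise_sd=0.1, seed=7)
    )
    return dataset, truth


@pytest.fixture
def csv_file(tmp_path):
    """Tiny clinical-style CSV with one missing cell."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "age,sex,bili,outcome\n"
        "30,male,0.7,live\n"
        "41,female,?,die\n"
        "52,female,1.9,live\n"
    )
    return path
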