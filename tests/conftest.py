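import numpy as np
import pytest

from pifminer.synthetic import SyntheticSpec, generate_dataset
from pifminer.templates import default_templates


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture()
def rng():
    return np.random.default_rng(11)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact planted-truth dataset shared by classifier/pipeline tests."""
    spec = SyntheticSpec(
        genome_length=600_000,
        seed=5,
        class_counts={
            "AUTONOMOUS": 4,
            "DEF_NO_ORF1": 3,
            "DEF_NO_TPASE": 3,
            "DEF_NO_CODING": 3,
            "DEF_ONE_TIR": 3,
            "DEF_NO_TIR_FRAGMENT": 2,
            "MITE_LIKE": 6,
        },
        n_genes=20,
        variant_extra_insertions=1,
    )
    return generate_dataset(spec)
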