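import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from fsbrr import BinningSpec, DiscreteVector, FSBRRConfig, SynthSpec, generate
from fsbrr.infotheory import DiscretizedTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_config():
    return FSBRRConfig()


@pytest.fixture
def eight_feature_table():
    """3 informative + 2 exact duplicates + 3 irrelevant, n=500, fixed seed."""
    spec = SynthSpec(
        n_instances=500,
        n_informative=3,
        n_exact_duplicates=2,
        n_noisy_duplicates=0,
        n_irrelevant=3,
        seed=42,
    )
    return generate(spec)


def random_coded_table(rng, n_features, n_instances, max_card=5):
    """A DiscretizedTable of random integer-coded columns + binary class."""
    features = []
    ids = []
    for k in range(n_features):
        card = int(rng.integers(2, max_card + 1))
        features.append(DiscreteVector.from_codes(rng.integers(0, card, n_instances)))
        ids.append(f"f{k}")
    class_codes = DiscreteVector.from_codes(rng.integers(0, 2, n_instances))
    if class_codes.cardinality < 2:  # pragma: no cover - vanishingly unlikely
        class_codes = DiscreteVector.from_codes(
            np.arange(n_instances) % 2
        )
    return DiscretizedTable(feature_ids=ids, features=features, class_codes=class_codes)
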