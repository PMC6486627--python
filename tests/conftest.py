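import numpy as np
import pytest

from helicore.synthetic import (gen_stacked_rna, gen_two_lobe_structure,
                                random_rigid_transform, transform_structure)


@pytest.fixture
def two_lobe():
    """Two-lobe pseudo-structure with an exactly known 30 A separation."""
    return gen_two_lobe_structure(com_separation=30.0, seed=11)


@pytest.fixture
def reoriented_two_lobe(two_lobe):
    """The same structure under an arbitrary global rigid motion."""
    return transform_structure(two_lobe.structure, random_rigid_transform(23))


@pytest.fixture
def stacked_seven():
    return gen_stacked_rna(7)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
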