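import numpy as np
import pytest

from plish import synthetic_data as sd


@pytest.fixture(scope="session")
def default_tissue():
    """One default-spec synthetic tissue field, shared across tests."""
    return sd.gen_tissue_images(sd.TissueSpec(seed=7))


@pytest.fixture(scope="session")
def small_tissue():
    """A reduced field (faster) for segmentation/measurement tests."""
    spec = sd.TissueSpec(
        shape=(256, 256), n_cells=60,
        class_proportions=tuple([0.25] * 4),
        class_rates=sd.default_class_rates(n_classes=4),
        seed=11,
    )
    return sd.gen_tissue_images(spec)


@pytest.fixture(scope="session")
def collision_transcriptome():
    """Targets/background with five planted off-target 10-mer collisions."""
    return sd.gen_transcriptome(
        n_targets=5, n_background=20, planted_collisions=5, seed=21
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
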