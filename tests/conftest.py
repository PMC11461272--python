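import numpy as np
import pytest

from reoxquant.phantoms import (
    FociCountDistribution,
    FociPhantomParams,
    SectionPhantomParams,
    generate_foci_phantom,
    generate_section_phantom,
)


@pytest.fixture(scope="session")
def section_phantom():
    """Noiseless dual-marker phantom: 30% baseline hypoxia, half reoxygenated."""
    params = SectionPhantomParams(
        image_height_px=192,
        image_width_px=192,
        baseline_hypoxic_fraction=0.30,
        reoxygenated_fraction=0.5,
        new_hypoxia_fraction=0.05,
        seed=7,
    )
    image, truth = generate_section_phantom(params)
    return params, image, truth


@pytest.fixture(scope="session")
def foci_phantom_fixed4():
    """Noiseless phantom: 12 well-separated nuclei, exactly 4 foci each."""
    params = FociPhantomParams(
        n_nuclei=12,
        image_height_px=180,
        image_width_px=180,
        foci_count_distribution=FociCountDistribution(name="fixed", mean=4),
        seed=21,
    )
    image, truth = generate_foci_phantom(params)
    return params, image, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
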