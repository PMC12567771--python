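import numpy as np
import pytest

from mirfluor.phantom import (
    PhantomConfig,
    TissueClassSpec,
    default_class_table,
    generate_brain_phantom,
)


@pytest.fixture(scope="session")
def class_table():
    return default_class_table()


@pytest.fixture(scope="session")
def phantom256():
    """Default-composition phantom on a 256×256 ground-truth grid (512 µm field)."""
    return generate_brain_phantom(PhantomConfig(width=256, height=256, seed=5))


def zero_cv_classes():
    return [
        TissueClassSpec(
            c.class_id,
            c.name,
            c.chem_mean,
            {k: 0.0 for k in c.chem_cv},
            c.fluor_mean,
            {k: 0.0 for k in c.fluor_cv},
            c.scatter_mean,
        )
        for c in default_class_table()
    ]


@pytest.fixture(scope="session")
def cv0_phantom():
    """Noise-free composition: piecewise-constant fields at the class means."""
    return generate_brain_phantom(
        PhantomConfig(width=192, height=192, seed=2), zero_cv_classes()
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
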