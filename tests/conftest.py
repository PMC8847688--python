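import warnings

import numpy as np
import pytest

from graphfuse.synthetic import (
    LayerSpec,
    SynthConfig,
    generate_dataset,
    standard_benchmark_config,
)

# the narrow layers used in fixtures make latent_dim warnings expected noise
warnings.filterwarnings("ignore", message="latent_dim")


@pytest.fixture()
def four_points():
    """Two tight pairs of 2-D points, far apart: the hand-computed example."""
    return np.array([[0.0, 0.0], [0.0, 1.0], [5.0, 5.0], [5.0, 6.0]])


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down planted-subtype cohort for fast pipeline tests."""
    cfg = SynthConfig(
        n_samples=120,
        class_proportions=(0.25, 0.25, 0.25, 0.25),
        layer_specs=[
            LayerSpec(120, 10, 4.0, 1.0, name="wide"),
            LayerSpec(80, 10, 4.0, 1.0, name="mid"),
            LayerSpec(30, 6, 4.0, 1.0, name="narrow"),
        ],
        latent_dim_true=6,
        seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def standard_benchmark():
    """The standard benchmark cohort: n=300, layers 500/400/60, seed 7."""
    return generate_dataset(standard_benchmark_config(seed=7))
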