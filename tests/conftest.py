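"""Shared fixtures: all inputs are generated programmatically.

The trained network fixture runs one smoke training of the FP-net-23 on the
synthetic shape dataset and is shared (session scope) by every test that
needs trained weights, so the suite trains exactly once.
"""

import numpy as np
import pytest

from fpnets import (SyntheticDatasetSpec, build_pyrblocknet, fp_transform,
                    make_synthetic_dataset, neuron_census, smoke_train)

TRAIN_STEPS = 300
TRAIN_SEED = 1


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def shape_dataset():
    """512 synthetic 32x32x3 images over 4 shape classes, balanced."""
    return make_synthetic_dataset(SyntheticDatasetSpec(n_images=512, seed=0))


@pytest.fixture(scope="session")
def trained_fpnet23(shape_dataset):
    """(loss trace, network) of one smoke training of the FP-net-23."""
    spec = fp_transform(build_pyrblocknet(3), q=1.0)
    return smoke_train(spec, shape_dataset, steps=TRAIN_STEPS, seed=TRAIN_SEED,
                       lr=0.05, batch_size=32)


@pytest.fixture(scope="session")
def trained_census(trained_fpnet23, shape_dataset):
    """Neuron census of the trained FP-net-23 over 256 images."""
    _, net = trained_fpnet23
    return neuron_census(net, shape_dataset[0][:256])
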