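import numpy as np
import pytest

from pqlung import injury_classifier, phantom, pipeline
from pqlung.volume_io import CTVolume


@pytest.fixture(scope="session")
def training_phantom():
    """Default phantom with truth masks (seeded, noise sd 30 HU)."""
    spec = phantom.PhantomSpec(seed=42)
    volume, truth = phantom.render_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def trained_model(training_phantom):
    """Classifier trained on pipeline-consistent phantom features."""
    _, volume, truth = training_phantom
    dataset = pipeline.build_training_dataset(volume, truth, max_per_class=1000, seed=3)
    model, report = injury_classifier.train(dataset, seed=1)
    return model, report, dataset


@pytest.fixture()
def flat_volume():
    """Uniform aerated-parenchyma volume (zero gradients everywhere)."""
    return CTVolume(np.full((5, 16, 16), -850.0), (1.25, 0.7, 0.7))


def make_ellipsoid_volume(shape=(16, 32, 32), center=(8, 16, 16), radii=(6, 12, 12),
                          inside=-850.0, outside=0.0):
    """Simple two-compartment test volume with its exact inside mask."""
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    mask = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii)) <= 1.0
    hu = np.full(shape, outside)
    hu[mask] = inside
    return CTVolume(hu, (1.0, 1.0, 1.0)), mask
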