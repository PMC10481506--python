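import numpy as np
import pytest
from hypothesis import settings

import archlabel as al

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def upper_template():
    return al.default_template("upper")


@pytest.fixture(scope="session")
def lower_template():
    return al.default_template("lower")


@pytest.fixture(scope="session")
def full_prior(upper_template, lower_template):
    return al.template_prior(upper_template, lower_template)


def make_random_scene(rng, n_upper, n_lower):
    """Bimaxillary scene with random COMs, jaws separated along z."""
    detections = []
    for _ in range(n_upper):
        com = np.array(
            [rng.uniform(0, 60), rng.uniform(0, 50), rng.uniform(20, 25)]
        )
        detections.append(
            al.ToothDetection(len(detections), com, al.Box3(com - 1, com + 1))
        )
    for _ in range(n_lower):
        com = np.array(
            [rng.uniform(0, 60), rng.uniform(0, 50), rng.uniform(-25, -20)]
        )
        detections.append(
            al.ToothDetection(len(detections), com, al.Box3(com - 1, com + 1))
        )
    return al.build_scene(detections)
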