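import math

import numpy as np
import pytest

from barrettometry.phantom import (
    CameraModel,
    PaintRegion,
    Pose,
    build_phantom,
    render_frame,
)

TWO_PI = 2.0 * math.pi


@pytest.fixture(scope="session")
def camera():
    return CameraModel()  # f=128, 256x256


@pytest.fixture(scope="session")
def band_phantom():
    """Constant-radius tube, full circumferential band z in [15, 85) mm."""
    band = PaintRegion("band", (0.0, TWO_PI), (15.0, 85.0), name="band")
    return build_phantom(100.0, 20.0, [band])


@pytest.fixture(scope="session")
def band_frame(band_phantom, camera):
    # proximal enough that the whole band lies inside the field of view
    pose = Pose(np.eye(3), np.array([0.0, 0.0, 2.0]))
    return render_frame(band_phantom, pose, camera)


@pytest.fixture(scope="session")
def length_experiment():
    from barrettometry.experiments import run_length_experiment

    return run_length_experiment(seed=1)


@pytest.fixture(scope="session")
def area_experiment():
    from barrettometry.experiments import run_area_experiment

    return run_area_experiment(seed=1)
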