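import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vitroscan as vs
from vitroscan.calibration import PixelMetric

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def laser_cal():
    """Exact-line calibration: 0.01 mm per raw unit, zero plane at 19430."""
    return vs.fit_laser_calibration([(19430 + i * 100, float(i)) for i in range(6)])


@pytest.fixture(scope="session")
def pm_synthetic():
    """Pixel pitch used for synthetic vessel renders (2 px/mm -> 200 px images)."""
    return PixelMetric(2.0, reference_height_mm=20.0)


@pytest.fixture(scope="session")
def trained_classifier(pm_synthetic):
    """Random forest trained on four synthetic day scenes (truth-labeled)."""
    labeled = []
    for s in range(4):
        scene = vs.random_scene(s)
        img, mask = vs.render_rgb(scene, pm_synthetic, "day")
        labeled.append((img, mask.astype(np.int8)))
    return vs.train_pixel_classifier(labeled, seed=0)
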