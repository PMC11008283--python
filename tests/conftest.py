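import numpy as np
import pytest

from pvceval.phantom import (
    GeometryConfig,
    PSFModel,
    apply_psf,
    make_brain_phantom,
    paint_activity,
)
from pvceval.phantom import DEFAULT_ACTIVITIES


@pytest.fixture(scope="session")
def default_truth():
    return make_brain_phantom((64, 64, 64), 2.0)


@pytest.fixture(scope="session")
def default_labels(default_truth):
    return default_truth.label_volume


@pytest.fixture(scope="session")
def psf8():
    return PSFModel(fwhm_mm=8.0)


@pytest.fixture(scope="session")
def blurred_pet(default_truth, psf8):
    return apply_psf(paint_activity(default_truth), psf8)


@pytest.fixture(scope="session")
def shell_truth():
    """GM shell 2.0, WM core 1.0, CSF 0 — the 3-compartment recovery case."""
    activities = {
        **DEFAULT_ACTIVITIES,
        "csf": 0.0,
        "white_matter": 1.0,
        "cerebellum_reference": 0.0,
        "meninges": 0.0,
        "skull": 0.0,
        **{n: 2.0 for n in GeometryConfig().cortical_names},
    }
    geometry = GeometryConfig(activities=activities)
    return make_brain_phantom((64, 64, 64), 2.0, geometry)


def composite_mean(regional_values, labels, names):
    """Voxel-count-weighted composite of per-label regional values."""
    counts = labels.counts()
    present = [n for n in names if n in regional_values]
    weights = np.array([counts[n] for n in present], dtype=float)
    values = np.array([regional_values[n] for n in present], dtype=float)
    return float(np.average(values, weights=weights))
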