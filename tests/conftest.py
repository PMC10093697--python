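import numpy as np
import pytest

from vsimri import (
    VesselSizeModel,
    default_bolus,
    default_classes,
    simulate_dsc,
)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Five-class block phantom, no noise: exact recovery reference."""
    return simulate_dsc(
        default_classes(),
        default_bolus(),
        grid_shape=(25, 20, 4),
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noisy_phantom():
    """Same phantom at SNR 50 (baseline 1000, noise SD 20)."""
    return simulate_dsc(
        default_classes(),
        default_bolus(),
        grid_shape=(40, 40, 6),
        noise_sd=20.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_results(noiseless_phantom):
    return VesselSizeModel.from_phantom(noiseless_phantom).fit()


@pytest.fixture(scope="session")
def noisy_results(noisy_phantom):
    return VesselSizeModel.from_phantom(noisy_phantom).fit()


def class_means(value_map, phantom):
    """Mean of a 3D map within each tissue class, keyed by label."""
    out = {}
    for i, spec in enumerate(phantom.classes):
        vals = value_map[phantom.class_map == i]
        out[spec.label] = float(np.nanmean(vals))
    return out
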