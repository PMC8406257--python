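import dataclasses

import numpy as np
import pytest

from trenchph import (CalibrationModel, OpticsConfig, load_preset,
                      make_cohort)


@pytest.fixture(scope="session")
def parental():
    return load_preset("parental")


@pytest.fixture(scope="session")
def default_optics():
    return OpticsConfig()


@pytest.fixture(scope="session")
def noiseless_optics():
    return OpticsConfig().replace(shot_noise=False, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def exact_model():
    """Calibration model equal to the generator's ground-truth map."""
    return CalibrationModel(slope=5.0, intercept=4.0, n_points=4,
                            residual_sd=0.0, r_squared=1.0)


def pure_fate_preset(preset, fate: str):
    """Copy of a preset whose lineages all take one fate."""
    probs = {"persister": (1.0, 0.0, 0.0), "vbnc": (0.0, 1.0, 0.0),
             "susceptible": (0.0, 0.0, 1.0)}[fate]
    return dataclasses.replace(preset, name=f"{preset.name}_{fate}",
                               fate_probs=probs)


@pytest.fixture(scope="session")
def small_parental_cohort(parental):
    return make_cohort(parental, 30, seed=42)
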