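"""Shared fixtures.

The end-to-end acceptance tests share one dataset bundle and one trained
model (both session-scoped) so the expensive work happens once.
"""

import warnings

import numpy as np
import pytest

from cspd.forward import make_gaussian_psf
from cspd.pipeline import ExperimentConfig, assemble_dataset, fit_cspd
from cspd.ulm import TrainingPairConfig

# the study pixel pitch (25 um) deliberately undersamples the axial PSF;
# the synthesis module warns about it once per PSF construction
warnings.filterwarnings("ignore", message=".*PSF is undersampled.*",
                        category=RuntimeWarning)


@pytest.fixture(scope="session")
def experiment_config():
    return ExperimentConfig(master_seed=1)


@pytest.fixture(scope="session")
def bundle(experiment_config):
    return assemble_dataset(experiment_config)


@pytest.fixture(scope="session")
def trained(bundle):
    return fit_cspd(bundle)


@pytest.fixture(scope="session")
def pcfg():
    return TrainingPairConfig()


@pytest.fixture(scope="session")
def psf(pcfg):
    return pcfg.make_psf()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
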