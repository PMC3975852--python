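import warnings

import numpy as np
import pytest

from mtgblup.pipeline import ScenarioConfig, run_study

# Desk-scale study conditions for the end-to-end checks: the genome is
# scaled down together with the population so that the reference set still
# carries information relative to the number of independent chromosome
# segments (2 x 100 cM, 400 markers, 30 QTLs; 75 sires x 1,500 dams,
# 225 reference / 75 validation bulls; 90% masking as in the full study).
STUDY_CONFIG = ScenarioConfig(
    chromosome_lengths=(100.0, 100.0),
    marker_spacing=0.5,
    n_qtl=30,
    hist_sires=25,
    hist_dams=25,
    hist_generations=30,
    n_sires=75,
    n_dams=1500,
    replicates=3,
    seed=11,
)

# Minimal configuration for structural / plumbing tests.
TINY_CONFIG = ScenarioConfig(
    chromosome_lengths=(50.0,),
    marker_spacing=1.0,
    n_qtl=10,
    hist_sires=10,
    hist_dams=10,
    hist_generations=5,
    n_sires=10,
    n_dams=50,
    replicates=1,
    seed=7,
)


@pytest.fixture(scope="session")
def study_report():
    """Aggregated three-replicate, three-scenario study at desk scale."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_study(STUDY_CONFIG)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
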