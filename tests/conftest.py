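import numpy as np
import pytest

from cav3ephys.protocols import activation_protocol, inactivation_protocol
from cav3ephys.synthetic_data import (
    generate_recording,
    mutant_group_spec,
    wt_group_spec,
)

# 2 kHz sampling keeps fixtures light; idealized-mode peaks are placed
# analytically, so peak-based results do not depend on the sampling rate.
FAST_RATE_HZ = 2000.0


@pytest.fixture(scope="session")
def wt_params():
    return wt_group_spec().mean_params()


@pytest.fixture(scope="session")
def mut_params():
    return mutant_group_spec().mean_params()


@pytest.fixture(scope="session")
def fast_protocols():
    return (
        activation_protocol(sampling_rate_hz=FAST_RATE_HZ),
        inactivation_protocol(sampling_rate_hz=FAST_RATE_HZ),
    )


@pytest.fixture(scope="session")
def ideal_wt_recording(wt_params, fast_protocols):
    act, inact = fast_protocols
    return generate_recording(
        wt_params, act, inact, noise_sd=0.0, mode="idealized", rng_seed=0,
        cell_id="WT-mean", group="WT",
    )


@pytest.fixture(scope="session")
def ideal_mut_recording(mut_params, fast_protocols):
    act, inact = fast_protocols
    return generate_recording(
        mut_params, act, inact, noise_sd=0.0, mode="idealized", rng_seed=0,
        cell_id="mutant-mean", group="mutant",
    )
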