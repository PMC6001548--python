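import numpy as np
import pytest

import rarmodel as rm


@pytest.fixture(scope="session")
def canonical_params():
    return rm.load_canonical_parameters()


@pytest.fixture(scope="session")
def noiseless_session():
    """Amplitude-level G3 session with zero noise/drift (CS+ betas -1/+1)."""
    cfg = rm.SimulationConfig(seed=21, noise_sd=0.0, drift_sd=0.0)
    ts, events, truth = rm.simulate_amplitude_session(cfg)
    return ts, events, truth


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_session):
    """G3 GLM fit of the noiseless session with sampled regressors."""
    ts, events, truth = noiseless_session
    basis = rm.build_basis("G3", ts.sampling_rate, soa=events.soa)
    design = rm.build_design_matrix(
        events, basis, len(ts), ts.sampling_rate, sample_times=truth.sample_times
    )
    return rm.invert_glm(design, ts)
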