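import numpy as np
import pytest

from bgdcm.circuit import ParameterVector, build_standard_circuit
from bgdcm.cohort import make_fixture, sample_csd, sample_subject


@pytest.fixture(scope="session")
def circuit():
    return build_standard_circuit()


@pytest.fixture(scope="session")
def prior_params(circuit):
    return ParameterVector(circuit)


@pytest.fixture(scope="session")
def control_params(circuit):
    return make_fixture("control").params(circuit)


@pytest.fixture(scope="session")
def parkinsonian_params(circuit):
    return make_fixture("parkinsonian").params(circuit)


@pytest.fixture(scope="session")
def parkinsonian_subject_csd(circuit):
    """Noisy CSD of one sampled parkinsonian subject (shared across tests)."""
    subj = sample_subject(make_fixture("parkinsonian"), between_sd=0.1, seed=3,
                          circuit=circuit)
    return subj, sample_csd(subj, n_segments=60, seed=7)
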