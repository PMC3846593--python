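import numpy as np
import pytest

from seminoquant.cohort_qc import SemenSample
from seminoquant.fixtures import reference_evidence as load_reference_evidence


def make_sample(subject_id="S001", cohort="patient", ros=10.0, endtz=0.0,
                **overrides):
    kwargs = dict(
        subject_id=subject_id, cohort=cohort, concentration=40.0,
        motility=50.0, round_cells=2.0, endtz=endtz, morphology=4.0,
        ros=ros,
    )
    kwargs.update(overrides)
    return SemenSample(**kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20130903)


@pytest.fixture(scope="session")
def reference_evidence():
    """Packaged per-pool identification evidence for the 14 study proteins."""
    return load_reference_evidence()
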