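import numpy as np
import pytest

from ecochg import ANNParams, CMParams, ModelParams, TimeGrid


@pytest.fixture
def grid():
    """The standard recording configuration: 500 Hz tone at 16 kHz."""
    return TimeGrid(stimulus_frequency=500.0, sampling_rate=16000.0)


def make_params(
    a_cm=1.0,
    phi_cm=0.0,
    peak_saturation=0.0,
    trough_saturation=0.0,
    a_ann=0.3,
    phi_ann=0.0,
    soe=0.65,
):
    """Model parameters with saturation given as a fraction of A_CM."""
    return ModelParams(
        cm=CMParams(
            a_cm=a_cm,
            phi_cm=phi_cm,
            upper_cutoff=(1.0 - peak_saturation) * a_cm if a_cm > 0 else 1.0,
            lower_cutoff=-(1.0 - trough_saturation) * a_cm if a_cm > 0 else -1.0,
        ),
        ann=ANNParams(a_ann=a_ann, phi_ann=phi_ann, soe=soe),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
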