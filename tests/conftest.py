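"""Shared phantom fixtures.

Session-scoped because rendering a 512x512 study is the expensive part
of the suite; tests must not mutate fixture arrays in place.
"""

import pytest

from l3comp.phantom import PhantomParams, generate_phantom_study


@pytest.fixture(scope="session")
def noiseless():
    """(params, study, truth) of a default phantom with zero noise."""
    params = PhantomParams(patient_id="P000", seed=11).noiseless()
    study, gt = generate_phantom_study(params)
    return params, study, gt


@pytest.fixture(scope="session")
def noisy_sd5():
    """(params, study, truth) with 5 HU Gaussian pixel noise everywhere."""
    params = PhantomParams(patient_id="P005", seed=12).with_noise(5.0)
    study, gt = generate_phantom_study(params)
    return params, study, gt
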