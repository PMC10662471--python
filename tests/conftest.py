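import numpy as np
import pytest

from sescom.body_models import build_preset
from sescom.synthetic import sample_postures, sample_subject


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def subject():
    return sample_subject(11, subject_id="fix")


@pytest.fixture
def model_d(subject):
    return subject.model("d")


@pytest.fixture
def postures_d(model_d):
    return sample_postures(model_d, 40, 101)
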