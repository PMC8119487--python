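import numpy as np
import pytest

from artakit.audiogram import EarAudiogram


def make_ear(ear="left", thresholds=None, subject="S1", age=30.0, **kw):
    if thresholds is None:
        thresholds = {0.25: 20, 0.5: 20, 1.0: 25, 2.0: 30, 4.0: 40, 8.0: 45}
    return EarAudiogram(
        subject_id=subject, family_id="F", ear=ear, age_years=age,
        thresholds=dict(thresholds), **kw,
    )


@pytest.fixture
def ear_pair():
    left = make_ear("left")
    right = make_ear("right", {0.25: 30, 0.5: 20, 1.0: 35, 2.0: 30, 4.0: 50, 8.0: 45})
    return left, right


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
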