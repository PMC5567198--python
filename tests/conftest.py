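import numpy as np
import pytest

from milksession.core import MilkingSchedule
from milksession.params import MeanParams, VarParams, reference_params, reference_var_params


@pytest.fixture(scope="session")
def ref_params():
    return reference_params()


@pytest.fixture(scope="session")
def ref_var_params():
    return reference_var_params()


@pytest.fixture(scope="session")
def nominal_schedule(ref_params):
    """610-session schedule alternating 10 h / 14 h (morning first)."""
    intervals = np.tile([10.0, 14.0], 305)[:609]
    times = ref_params.delta + np.concatenate([[0.0], np.cumsum(intervals)])
    labels = np.array(["M", "E"] * 305)[:610]
    return MilkingSchedule(times, labels, ref_params.delta)


@pytest.fixture
def short_schedule():
    """20-session chain starting at delta = 70.98 h."""
    delta = 70.98
    intervals = np.tile([10.0, 14.0], 10)[:19]
    times = delta + np.concatenate([[0.0], np.cumsum(intervals)])
    labels = np.array(["M", "E"] * 10)[:20]
    return MilkingSchedule(times, labels, delta)


@pytest.fixture
def simple_params():
    return MeanParams(
        delta=70.98, lambda_a=64e-4, lambda_r=45e-6, pi=0.04,
        pl_segments=(1.41,), segment_starts=(1,),
    )


@pytest.fixture
def simple_var_params():
    return VarParams(phi=0.54)
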