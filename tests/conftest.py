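import numpy as np
import pytest

from lowpet.framing import make_full_schedule
from lowpet.simulate import (
    InputFunctionParams,
    KineticParams,
    ReferenceKinetics,
    TimeActivityCurve,
    exp_conv,
    fine_grid_s,
    plasma_input,
    srtm_forward,
)


@pytest.fixture(scope="session")
def fine_time_min():
    return fine_grid_s() / 60.0


@pytest.fixture(scope="session")
def default_reference_fine(fine_time_min):
    """Noise-free reference curve on the fine grid (default input/kinetics)."""
    p = InputFunctionParams()
    rk = ReferenceKinetics()
    dt = fine_time_min[1] - fine_time_min[0]
    return rk.K1p * exp_conv(plasma_input(fine_time_min, p), rk.k2p, dt)


@pytest.fixture(scope="session")
def full_schedule():
    return make_full_schedule()


def sample_tac(region, fine_t_min, fine_vals, schedule):
    """Noise-free TAC: the continuous curve sampled at full-frame mid-times."""
    mid = np.asarray(schedule.midtimes_s, float)
    dur = np.asarray(schedule.durations_s, float)
    return TimeActivityCurve(region, mid, dur, np.interp(mid / 60.0, fine_t_min, fine_vals))


@pytest.fixture(scope="session")
def noiseless_pair(fine_time_min, default_reference_fine, full_schedule):
    """(target, reference, truth) noiseless TAC pair on the full schedule."""
    truth = KineticParams(r1=1.0, k2=0.3, bp_nd=2.0)
    ct = srtm_forward(default_reference_fine, truth, fine_time_min)
    tac_r = sample_tac("reference", fine_time_min, default_reference_fine, full_schedule)
    tac_t = sample_tac("target", fine_time_min, ct, full_schedule)
    return tac_t, tac_r, truth
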