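import math

import pytest

from cqscreen import BindingSystem, QpcrCalibration, ScreenDesign


def quadratic_bound(t_tot: float, l_tot: float, kd: float) -> float:
    """Independent two-species closed-form oracle (plain quadratic root)."""
    s = t_tot + l_tot + kd
    return (s - math.sqrt(s * s - 4.0 * t_tot * l_tot)) / 2.0


def closed_form_delta_cq(kd_compound, i_tot, p_tot=0.2, kd_probe=1.32):
    """Oracle: cycle shift implied by inverting the single-well kd relation."""
    return math.log2(1.0 + i_tot / (kd_compound * (1.0 + p_tot / kd_probe)))


@pytest.fixture
def default_system():
    return BindingSystem(t_tot=0.01, p_tot=0.2, i_tot=0.0, kd_probe=1.32)


@pytest.fixture
def unit_cal():
    return QpcrCalibration(cq_ref=10.0, bound_ref=1.0, efficiency=1.0)


@pytest.fixture
def noise_free_design():
    return ScreenDesign(noise_sd=0.0, seed=7)
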