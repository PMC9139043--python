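"""Shared fixtures: the canonical simulation-study device.

The canonical parameter set is a p-type Si / 35 nm SiO2 EISCAP with 0.5 cm^2
contact area, a ~5 Ohm*cm wafer doping, a bare-surface interfacial potential
of -10 mV and a particle-covered interfacial potential of +30 mV
(delta_phi = +40 mV); the ConCap working point is 30 nF (~50 mV).
"""

import pytest

from eiscap import DeviceParams

CANONICAL_IO = {
    "eps_ir": 3.9,
    "d_i_nm": 35.0,
    "eps_sr": 11.7,
    "N_a_per_cm3": 2.76e15,
    "n_i_per_cm3": 1.5e10,
    "T_K": 300.0,
    "A_cm2": 0.5,
    "V_ip_mV": 0.0,
    "phi_0_mV": -10.0,
}

DELTA_PHI = 0.040  # V, phi_NP - phi_0 for the positively charged particles
C_WORK = 30e-9  # F, depletion working capacitance of the bare device


@pytest.fixture(scope="session")
def device() -> DeviceParams:
    return DeviceParams.from_io_units(**CANONICAL_IO)
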