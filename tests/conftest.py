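import numpy as np
import pytest

import firesweep as fs
from firesweep.cable_solver import CompiledModel


@pytest.fixture(scope="session")
def oc_model():
    return fs.build_oc()


@pytest.fixture(scope="session")
def bas_model():
    return fs.build_bas()


@pytest.fixture(scope="session")
def small_fixture():
    """Small synthetic perisomatic model (fast: ~15 segments)."""
    model, swc, bundle = fs.generate_synthetic_cell(1, n_dendrites=2, depth=1)
    return model, swc, bundle


@pytest.fixture(scope="session")
def oc_compiled(oc_model):
    return CompiledModel.from_model(oc_model)


@pytest.fixture(scope="session")
def oc_thresholds(oc_model):
    """Thresholds for OC at c_m x1.0 / x1.5 (shared across acceptance tests)."""
    from firesweep.perturbations import PerturbationSpec, apply

    t10 = fs.find_threshold(oc_model)
    t15 = fs.find_threshold(apply(oc_model, PerturbationSpec(cm_factor=1.5)))
    return t10, t15


@pytest.fixture(scope="session")
def bas_thresholds(bas_model):
    from firesweep.perturbations import PerturbationSpec, apply

    t10 = fs.find_threshold(bas_model)
    t15 = fs.find_threshold(apply(bas_model, PerturbationSpec(cm_factor=1.5)))
    return t10, t15


def hh_rates(v):
    """Independent textbook squid-kinetics rates (oracle; no package code)."""
    am = 0.1 * (v + 40) / (1 - np.exp(-(v + 40) / 10)) if abs(v + 40) > 1e-9 else 1.0
    bm = 4 * np.exp(-(v + 65) / 18)
    ah = 0.07 * np.exp(-(v + 65) / 20)
    bh = 1 / (1 + np.exp(-(v + 35) / 10))
    an = 0.01 * (v + 55) / (1 - np.exp(-(v + 55) / 10)) if abs(v + 55) > 1e-9 else 0.1
    bn = 0.125 * np.exp(-(v + 65) / 80)
    return am, bm, ah, bh, an, bn


@pytest.fixture(scope="session")
def hh_oracle_trace():
    """High-accuracy LSODA integration of the OC equations (oracle).

    Returns (t_grid_ms_from_stim_onset, V_mV) at the default dt for a 0.1 nA,
    200 ms step after the 600 ms settle.
    """
    from scipy.integrate import solve_ivp

    area = np.pi * 10 * 10 * 1e-8  # cm^2
    settle, dur, amp = 600.0, 200.0, 0.1

    def rhs(t, y):
        v, m, h, n = y
        am, bm, ah, bh, an, bn = hh_rates(v)
        istim = amp * 1e-3 / area if t >= settle else 0.0
        dv = -120 * m**3 * h * (v - 50) - 36 * n**4 * (v + 77) - 0.3 * (v + 54.3) + istim
        return [dv, am * (1 - m) - bm * m, ah * (1 - h) - bh * h, an * (1 - n) - bn * n]

    v0 = -65.0
    am, bm, ah, bh, an, bn = hh_rates(v0)
    y0 = [v0, am / (am + bm), ah / (ah + bh), an / (an + bn)]
    sol = solve_ivp(rhs, (0, settle + dur), y0, method="LSODA", rtol=1e-10, atol=1e-10,
                    dense_output=True, max_step=0.5)
    t = (np.arange(int(round(dur / fs.DEFAULT_DT))) + 1) * fs.DEFAULT_DT
    return t, sol.sol(settle + t)[0]
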