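import numpy as np
import pytest

from achmap.ionic import IonicParams, steady_state_init
from achmap.solver import (PacingProtocol, VmField, conduction_velocity,
                           initialize_states, simulate)
from achmap.tissue import TissueModel, Patch


@pytest.fixture(scope="session")
def baseline_steady_state():
    """Myocyte state after 10 s of pacing at CL 1000 ms (session-cached)."""
    return steady_state_init(IonicParams(), duration_s=10.0)


@pytest.fixture(scope="session")
def fibroblast_steady_state():
    pf = IonicParams(model_variant="fibroblast")
    return steady_state_init(pf, duration_s=5.0)


def make_translating_wave(ny=30, nx=30, dx=0.02, sample_dt=1.0, nt=80,
                          cv_cm_s=50.0, amp=100.0, width_cm=0.1, rest=-80.0):
    """Synthetic planar upstroke translating along +y at a known speed."""
    y = np.arange(ny) * dx
    t = np.arange(nt) * sample_dt
    front = cv_cm_s / 1000.0 * t          # cm
    vm = rest + amp / (1.0 + np.exp((y[None, :, None] - front[:, None, None])
                                    / width_cm)) * np.ones((1, 1, nx))
    return VmField(vm=vm, sample_dt=sample_dt, dx=dx)


@pytest.fixture
def translating_wave():
    return make_translating_wave()


def run_strip(dx, d_long=0.003, fiber_axis="y", wx=0.6, wy=1.6, dt=0.005,
              init_s=10.0, cl=60.0):
    """Planar-wave strip run used by CV measurements (fiber along y)."""
    nx = int(round(wx / dx)) + 1
    ny = int(round(wy / dx)) + 1
    tis = TissueModel(nx=nx, ny=ny, dx=dx, d_long=d_long,
                      fiber_axis=fiber_axis)
    states = initialize_states(tis, IonicParams(), duration_s=init_s)
    return simulate(tis, PacingProtocol(cl=cl, n_beats=1), states,
                    IonicParams(), dt_range=(dt, dt), sample_dt=1.0,
                    record_activation=True)


@pytest.fixture(scope="session")
def cv_refinement_pair():
    """Longitudinal CV at dx = 0.04 and 0.02 cm, everything else fixed."""
    cv = {dx: conduction_velocity(run_strip(dx), axis="y")
          for dx in (0.04, 0.02)}
    return cv


@pytest.fixture(scope="session")
def cv_anisotropy_pair():
    """Longitudinal vs transverse CV at dx = 0.02 cm."""
    cv_l = conduction_velocity(run_strip(0.02, fiber_axis="y"), axis="y")
    cv_t = conduction_velocity(run_strip(0.02, fiber_axis="x"), axis="y")
    return cv_l, cv_t


@pytest.fixture
def small_tissue():
    """2 x 2 cm myocyte-only sheet with one central ACh circle."""
    n = 51
    dx = 0.04
    ach = np.zeros((n, n))
    xg, yg = np.meshgrid(np.arange(n) * dx, np.arange(n) * dx)
    ach[(xg - 1.0) ** 2 + (yg - 1.0) ** 2 <= 0.4 ** 2] = 0.1
    return TissueModel(nx=n, ny=n, dx=dx, ach_map=ach,
                       patch_registry=[Patch(1.0, 1.0, 0.4, "ACh")])
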