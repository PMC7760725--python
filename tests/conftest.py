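import numpy as np
import pytest
from hypothesis import settings
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

import pibquant as pq

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schedule():
    return pq.pib_frame_schedule()


@pytest.fixture(scope="session")
def clean_study():
    """Noise-free 20-cube phantom with default (control-like) kinetics."""
    spec = pq.PhantomSpec(shape=(20, 20, 20), noise_scale=0.0, seed=7)
    return pq.build_phantom(spec)


def ode_tissue_tac(kp: pq.KineticParams, cp: np.ndarray, t_min: np.ndarray) -> np.ndarray:
    """Independent fine-step ODE solution of the 2TC system (oracle)."""
    cp_f = interp1d(t_min, cp, bounds_error=False, fill_value=0.0)

    def rhs(t, y):
        cf, cb = y
        return [kp.K1 * cp_f(t) - (kp.k2 + kp.k3) * cf + kp.k4 * cb,
                kp.k3 * cf - kp.k4 * cb]

    sol = solve_ivp(rhs, (t_min[0], t_min[-1]), [0.0, 0.0], t_eval=t_min,
                    max_step=0.05, rtol=1e-8, atol=1e-10)
    return sol.y[0] + sol.y[1]


@pytest.fixture(scope="session")
def fine_grid():
    """Fine time grid (minutes) covering the 70 min scan."""
    return np.arange(0.0, 70.0 + 1e-9, 0.5 / 60.0)


@pytest.fixture(scope="session")
def plasma_curve(fine_grid):
    """Ground-truth metabolite-corrected plasma input on the fine grid."""
    wb = pq.blood_input_curve(pq.BloodCurveParams(), fine_grid)
    return pq.hill_fraction(pq.PIB_HILL, fine_grid) * wb
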