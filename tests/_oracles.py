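"""Independent numerical oracles used by the tests."""

import numpy as np
from scipy.integrate import solve_ivp

from cefazopk.model import DoseEvent, IndividualParams


def ode_concentration(p: IndividualParams, dose: DoseEvent, times_min):
    """Stiff numerical integration of the linear two-compartment system
    (amounts in mg, rates per hour); independent of the closed form."""
    k10, k12, k21 = p.cl / p.v1, p.q / p.v1, p.q / p.v2

    def rhs(_t, y):
        a1, a2 = y
        return [-(k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    t_h = np.asarray(times_min, dtype=float) / 60.0
    sol = solve_ivp(rhs, (0.0, max(t_h.max(), 1e-9)), [dose.amount, 0.0],
                    method="LSODA", t_eval=t_h, rtol=1e-10, atol=1e-12)
    assert sol.success
    return sol.y[0] / p.v1
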