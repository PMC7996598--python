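"""Independent brute-force oracles shared by the test modules."""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize


def direct_transcription_control(
    z_fine: np.ndarray,
    tgrid: np.ndarray,
    nodes: np.ndarray,
    r_weight: float,
    D: float = 0.24,
    s_in: float = 1.25,
    x0: float = 0.1,
    mu_max: float = 0.77,
    K: float = 0.7,
    inv_y: float = 3.98,
) -> np.ndarray:
    """Optimal single-AOB tracking control by generic constrained
    minimization: parametrize u at the nodes (piecewise linear), simulate
    the cascade accurately, and minimize the trapezoid objective
    int (x - z)^2 + r (u - 1)^2 dt with a derivative-free optimizer.
    Entirely independent of the Riccati machinery it cross-checks.
    """

    def cost(un: np.ndarray) -> float:
        def rhs_(t, v):
            x, s1 = v[0], max(v[1], 0.0)
            mu = mu_max * s1 / (K + s1) * np.interp(t, nodes, un)
            return [
                (mu - D) * x,
                (s_in - v[1]) * D - inv_y * mu * x,
                -v[2] * D + inv_y * mu * x,
                -v[3] * D,
            ]

        sol = solve_ivp(
            rhs_, (tgrid[0], tgrid[-1]), [x0, s_in, 0.0, 0.0], t_eval=tgrid,
            rtol=1e-8, atol=1e-11, method="LSODA",
        )
        uf = np.interp(tgrid, nodes, un)
        return float(np.trapezoid((sol.y[0] - z_fine) ** 2 + r_weight * (uf - 1) ** 2, tgrid))

    res = minimize(
        cost, np.ones(nodes.size), method="Powell",
        options={"maxiter": 4000, "xtol": 1e-10, "ftol": 1e-12},
    )
    return res.x
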