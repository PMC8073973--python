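"""Independent reference computations used to cross-check the simulator.

These deliberately avoid the package's radial solver: the well-mixed oracle
integrates its own three-ODE batch formulation, and the Langmuir
equilibrium is the closed form.
"""

import math

import numpy as np
from scipy.integrate import solve_ivp


def langmuir_theta(k_ads: float, k_des: float, c_free: float) -> float:
    """Closed-form equilibrium fractional coverage for a fixed free
    concentration: theta* = K c / (1 + K c), K = k_ads / k_des."""
    k = k_ads / k_des
    return k * c_free / (1.0 + k * c_free)


def well_mixed_yield(spec, params, derived, conditions, t_eval):
    """Zero-dimensional (well-mixed) batch oracle.

    Ignores all spatial structure: one bulk/pore free-enzyme pool in
    instantaneous equilibrium across the particle, one bound-enzyme pool,
    one porosity.  Valid in the limit of fast diffusion (small particle,
    large diffusivity).  Returns the glucose yield (total-cellulose basis)
    at t_eval.
    """
    v_p = math.pi * spec.radius_cm**2
    span = derived.eps_f - derived.eps_0

    def capacity(eps):
        if span <= 0:
            return derived.c_s_max0 if eps <= derived.eps_0 else 0.0
        return float(np.clip(derived.c_s_max0 * (derived.eps_f - eps) / span,
                             0.0, derived.c_s_max0))

    def rhs(t, y):
        c_free, c_s, eps = y
        dcs = params.k_ads * c_free * (capacity(eps) - c_s) - params.k_des * c_s
        deps = (
            params.k_des * c_s * params.m_p * params.mm_glu * params.h_glu / spec.rho_c_iv
            if eps < derived.eps_f
            else 0.0
        )
        # free enzyme is shared between bulk and pore fluid; bound removal
        # and pore-volume growth both act on the combined pool
        dcf = (-v_p * dcs - c_free * v_p * deps) / (conditions.v_b + eps * v_p)
        return [dcf, dcs, deps]

    sol = solve_ivp(
        rhs,
        (float(t_eval[0]), float(t_eval[-1])),
        [conditions.c_e0, 0.0, derived.eps_0],
        t_eval=np.asarray(t_eval, dtype=float),
        method="BDF",
        rtol=1e-10,
        atol=[1e-22, 1e-22, 1e-14],
    )
    assert sol.success
    eps = sol.y[2]
    total_cellulose = spec.f_cell * spec.rho_p
    return (eps - derived.eps_0) * spec.rho_c_iv / total_cellulose
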