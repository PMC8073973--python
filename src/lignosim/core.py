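"""Coupled balances for free enzyme, bound enzyme and porosity on a radial
grid, with the finite-bath bulk node.

State layout: ``y = [C_E^F(0..n), C_E^S(0..n), eps(0..n)]`` where indices
0..n-1 are cell-centred interior nodes and index n is the bulk node, giving
3(n+1) coupled ODEs.  Free enzyme C_E^F is a concentration per pore-fluid
volume; bound enzyme C_E^S is per total cylinder volume (so the adsorption
sink enters the free-enzyme balance divided by the porosity); porosity eps
is dimensionless.  The bulk node carries the bulk concentration with
eps == 1 as bookkeeping.

The spatial operator is a conservative finite-volume discretisation of
(1/eps) d/dr (r eps D_E dC/dr) / r with centred, second-order face fluxes;
the same outer-face flux drives both the outermost cell and the bulk
depletion ODE, so the semi-discrete system conserves enzyme moles exactly
(up to integrator tolerance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import KineticTransportParams, OperatingConditions
from .substrate import SubstrateDerived, SubstrateSpec

_EPS_FLOOR = 1e-9


def effective_diffusivity(eps, d_pore: float, tau: float):
    """Effective cellulase diffusivity eps * D_pore / tau, cm^2/min."""
    if tau < 1.0:
        import warnings

        warnings.warn("tortuosity < 1 is unphysical", stacklevel=2)
    eps = np.asarray(eps, dtype=float)
    if np.any(eps < 0) or np.any(eps > 1):
        raise ValueError("porosity must lie in [0, 1]")
    out = eps * d_pore / tau
    return float(out) if out.ndim == 0 else out


def site_capacity(eps, derived: SubstrateDerived):
    """Maximum bound-enzyme concentration at porosity eps, mol/cm^3 total
    volume.

    Binding sites decline linearly with porosity as cellulose is consumed:
    C_max = C_S_max0 * (eps_f - eps)/(eps_f - eps_0), clamped to
    [0, C_S_max0] against transient integrator overshoot.
    """
    eps = np.asarray(eps, dtype=float)
    span = derived.eps_f - derived.eps_0
    if span <= 0.0:
        # No hydrolyzable cellulose: capacity is flat until eps passes eps_0.
        cap = np.where(eps <= derived.eps_0, derived.c_s_max0, 0.0)
    else:
        cap = derived.c_s_max0 * (derived.eps_f - eps) / span
    cap = np.clip(cap, 0.0, derived.c_s_max0)
    return float(cap) if cap.ndim == 0 else cap


def langmuir_rate(c_f, c_s, c_max, k_ads: float, k_des: float):
    """Time-dependent Langmuir isotherm: dC_E^S/dt, mol/(cm^3*min).

    k_ads*C_F*(C_max - C_S) - k_des*C_S.  When C_max has shrunk below C_S the
    first term turns negative (net displacement), which is accepted.
    """
    c_f = np.asarray(c_f, dtype=float)
    out = k_ads * c_f * (np.asarray(c_max) - np.asarray(c_s)) - k_des * np.asarray(c_s)
    return float(out) if out.ndim == 0 else out


def porosity_rate(c_s, params: KineticTransportParams, rho_c_iv: float, eps=None, eps_f=None):
    """Porosity growth rate, 1/min: each desorption event removes M_p moles
    of glucose worth of cellulose from the pore walls.

    dEps/dt = k_des * C_S * M_p * MM_glu * H_glu / rho_C^IV, forced to zero
    once eps >= eps_f (hydrolyzable cellulose exhausted).
    """
    c_s = np.asarray(c_s, dtype=float)
    rate = params.k_des * c_s * params.m_p * params.mm_glu * params.h_glu / rho_c_iv
    rate = np.maximum(rate, 0.0)
    if eps is not None and eps_f is not None:
        rate = np.where(np.asarray(eps) >= eps_f, 0.0, rate)
    return float(rate) if rate.ndim == 0 else rate


def _surface_gradient(c_f: np.ndarray, dr: float) -> float:
    """Second-order one-sided dC/dr at r = R from the bulk value (at R) and
    the two outermost cell centres (R - dr/2, R - 3dr/2)."""
    return (8.0 * c_f[-1] - 9.0 * c_f[-2] + c_f[-3]) / (3.0 * dr)


def free_enzyme_rhs(grid, c_f, eps, dcs_dt, deps_dt, d_e: float):
    """dC_E^F/dt on the interior nodes.

    Diffusion enters as the conservative divergence of the face fluxes
    eps_face * D_E * dC/dr divided by the cell porosity (equivalent to the
    cylindrical Laplacian plus the porosity-gradient advection term);
    adsorption as -(1/eps) dC_S/dt (bound enzyme is per total volume);
    dilution as -(C_F/eps) dEps/dt.  The r = 0 singularity never arises: the
    innermost face sits at r = 0 with zero area (no-flux by symmetry).
    """
    n = grid.n
    eps_i = np.clip(np.asarray(eps[:n], dtype=float), _EPS_FLOOR, 1.0)
    flux = np.empty(n + 1)
    flux[0] = 0.0
    eps_face = 0.5 * (eps_i[:-1] + eps_i[1:])
    flux[1:n] = eps_face * d_e * np.diff(c_f[:n]) / grid.dr
    flux[n] = eps_i[-1] * d_e * _surface_gradient(c_f, grid.dr)
    div = (grid.face_radii[1:] * flux[1:] - grid.face_radii[:-1] * flux[:-1]) / (
        grid.radii * grid.dr
    )
    return (div - dcs_dt - c_f[:n] * deps_dt) / eps_i


def bulk_boundary_rhs(grid, c_f, eps, d_e: float, v_b: float) -> float:
    """dC_bulk/dt from the enzyme flux through the particle's outer surface
    (per unit length S_cyl = 2 pi R): -(S_cyl/V_B) * eps_s * D_E * dC/dr|_R.

    The surface porosity eps_s is the outermost interior value (the bulk
    node's eps == 1 is bookkeeping, not a physical surface layer)."""
    n = grid.n
    eps_s = float(np.clip(eps[n - 1], _EPS_FLOOR, 1.0))
    flux = eps_s * d_e * _surface_gradient(c_f, grid.dr)
    return -(2.0 * math.pi * grid.r_particle / v_b) * flux


def initial_state(derived: SubstrateDerived, conditions: OperatingConditions, grid) -> np.ndarray:
    """All enzyme starts in the bulk: interior C_F = C_S = 0, eps = eps_0;
    bulk node C_F = C_E0, eps = 1."""
    n = grid.n
    y0 = np.zeros(3 * (n + 1))
    y0[n] = conditions.c_e0
    y0[2 * (n + 1) : 3 * (n + 1) - 1] = derived.eps_0
    y0[-1] = 1.0
    return y0


@dataclass
class RadialState:
    """Unpacked state at one instant: free enzyme (mol/cm^3 pore fluid),
    bound enzyme (mol/cm^3 total volume) and porosity on n interior nodes
    plus the bulk node (last index)."""

    c_f: np.ndarray
    c_s: np.ndarray
    eps: np.ndarray

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "RadialState":
        m = y.size // 3
        return cls(c_f=y[:m].copy(), c_s=y[m : 2 * m].copy(), eps=y[2 * m :].copy())

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.c_f, self.c_s, self.eps])


class HydrolysisRHS:
    """Right-hand side of the 3(n+1) ODE system, callable as f(t, y)."""

    def __init__(
        self,
        grid,
        params: KineticTransportParams,
        derived: SubstrateDerived,
        conditions: OperatingConditions,
        rho_c_iv: float,
    ):
        self.grid = grid
        self.params = params
        self.derived = derived
        self.conditions = conditions
        self.rho_c_iv = rho_c_iv
        self.d_e = params.d_e
        self.clamp_events = 0  # transient overshoot clamps seen during integration

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        n = self.grid.n
        m = n + 1
        c_f = y[:m]
        c_s = y[m : 2 * m]
        eps = y[2 * m :]
        p, d = self.params, self.derived

        cap = site_capacity(eps[:n], d)
        if np.any(eps[:n] > d.eps_f + 1e-12):
            self.clamp_events += 1
        dcs = langmuir_rate(c_f[:n], c_s[:n], cap, p.k_ads, p.k_des)
        deps = porosity_rate(c_s[:n], p, self.rho_c_iv, eps=eps[:n], eps_f=d.eps_f)

        dy = np.zeros_like(y)
        dy[:n] = free_enzyme_rhs(self.grid, c_f, eps, dcs, deps, self.d_e)
        dy[n] = bulk_boundary_rhs(self.grid, c_f, eps, self.d_e, self.conditions.v_b)
        dy[m : m + n] = dcs
        dy[2 * m : 2 * m + n] = deps
        # bulk node: no adsorption, eps pinned at 1
        return dy

    def jac_sparsity(self):
        """Sparsity pattern for the BDF Jacobian: nearest-neighbour coupling
        in the free-enzyme block plus local kinetic coupling."""
        from scipy.sparse import lil_matrix

        n = self.grid.n
        m = n + 1
        size = 3 * m
        s = lil_matrix((size, size), dtype=np.int8)
        for i in range(n):
            for j in (i - 2, i - 1, i, i + 1, i + 2):
                if 0 <= j <= n:
                    s[i, j] = 1  # c_f on neighbouring c_f (incl. boundary stencil)
                    s[i, 2 * m + j] = 1  # and on neighbouring eps
            s[i, m + i] = 1  # adsorption sink
            s[m + i, i] = 1
            s[m + i, m + i] = 1
            s[m + i, 2 * m + i] = 1
            s[2 * m + i, m + i] = 1
            s[2 * m + i, 2 * m + i] = 1
        for j in (n, n - 1, n - 2):
            s[n, j] = 1  # bulk ODE sees the one-sided surface stencil
            s[j, n] = 1
        s[n, 2 * m + n - 1] = 1
        s[n, n] = 1
        return s.tocsr()
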