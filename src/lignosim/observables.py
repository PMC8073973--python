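"""Reported quantities derived from trajectories: glucose yield, surface
coverage, bulk enzyme depletion."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import site_capacity
from .solver import RadialTrajectory


@dataclass
class HydrolysisResult:
    """Time series of the headline observables.

    yield_fraction is on the total-cellulose basis (fraction of theoretical
    glucose from all cellulose, so it saturates at the digestibility d);
    yield_hydrolyzable rescales to the hydrolyzable fraction only.
    """

    times: np.ndarray
    yield_fraction: np.ndarray
    yield_hydrolyzable: np.ndarray
    titer_g_per_l: np.ndarray
    mean_coverage: np.ndarray
    coverage: np.ndarray  # (n_times, n) per-node theta
    bulk_fraction: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.times,
                "yield_fraction": self.yield_fraction,
                "titer_g_per_L": self.titer_g_per_l,
                "mean_coverage": self.mean_coverage,
                "bulk_fraction": self.bulk_fraction,
            }
        )


def glucose_yield(traj: RadialTrajectory, basis: str = "total") -> np.ndarray:
    """Glucose yield vs time from the porosity gain.

    Dissolved cellulose mass per unit length is sum over shells of
    (eps - eps_0) * rho_C^IV * dV; the glucose mass is that divided by the
    hydrolysis factor H_glu.  Basis 'total' divides by the glucose
    equivalent of all cellulose (f_cell * rho_p * pi R^2 / H_glu);
    'hydrolyzable' divides by the digestible part only.
    """
    spec = traj.spec
    if spec is None:
        raise ValueError("trajectory carries no substrate spec")
    n = traj.grid.n
    v = traj.grid.shell_volumes
    dissolved = np.sum(
        (traj.eps[:, :n] - traj.derived.eps_0) * v, axis=1
    ) * spec.rho_c_iv
    dissolved = np.clip(dissolved, 0.0, None)
    total_cellulose = spec.f_cell * spec.rho_p * traj.grid.particle_volume
    if total_cellulose <= 0:
        return np.zeros_like(dissolved)
    y = dissolved / total_cellulose
    if basis == "hydrolyzable":
        if spec.digestibility <= 0:
            return np.zeros_like(y)
        y = y / spec.digestibility
    elif basis != "total":
        raise ValueError("basis must be 'total' or 'hydrolyzable'")
    return y


def glucose_titer(traj: RadialTrajectory) -> np.ndarray:
    """Glucose concentration in the bulk liquid, g/L."""
    spec = traj.spec
    n = traj.grid.n
    v = traj.grid.shell_volumes
    dissolved = np.sum((traj.eps[:, :n] - traj.derived.eps_0) * v, axis=1) * spec.rho_c_iv
    glucose_mass = np.clip(dissolved, 0.0, None) / traj.params.h_glu
    return glucose_mass / traj.conditions.v_b * 1000.0  # g/cm^3 -> g/L


def surface_coverage(traj: RadialTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Fractional coverage theta(r, t) = C_E^S / C_E,max^S(eps) and its
    site-weighted radial mean.  Where the capacity has vanished theta is 0.
    """
    n = traj.grid.n
    v = traj.grid.shell_volumes
    cap = site_capacity(traj.eps[:, :n], traj.derived)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(cap > 0, traj.c_s[:, :n] / np.where(cap > 0, cap, 1.0), 0.0)
    weights = cap * v
    wsum = weights.sum(axis=1)
    mean = np.where(wsum > 0, (theta * weights).sum(axis=1) / np.where(wsum > 0, wsum, 1.0), 0.0)
    return theta, mean


def bulk_depletion(traj: RadialTrajectory) -> np.ndarray:
    """Fraction of the initial bulk enzyme remaining, starting at 1.  With
    no enzyme loaded the fraction is reported as 1 by convention."""
    c0 = traj.conditions.c_e0
    if c0 <= 0:
        return np.ones_like(traj.times)
    return traj.c_bulk / c0


def compute_result(traj: RadialTrajectory) -> HydrolysisResult:
    theta, mean_theta = surface_coverage(traj)
    return HydrolysisResult(
        times=traj.times,
        yield_fraction=glucose_yield(traj, basis="total"),
        yield_hydrolyzable=glucose_yield(traj, basis="hydrolyzable"),
        titer_g_per_l=glucose_titer(traj),
        mean_coverage=mean_theta,
        coverage=theta,
        bulk_fraction=bulk_depletion(traj),
    )
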