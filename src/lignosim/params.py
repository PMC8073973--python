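"""Kinetic/transport parameter sets and operating conditions.

Unit system: cm, min, mol, g throughout.  Pore widths are accepted in
Angstrom at the I/O boundary and converted internally (1 A = 1e-8 cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

ANGSTROM_TO_CM = 1e-8
BOLTZMANN_J_PER_K = 1.380649e-23

#: Diameter of the spherical cellulase footprint on the cellulose surface, in
#: Angstrom.  Sets both the pore-accessibility cutoff and the default
#: Stokes-Einstein diffusivity.
CELLULASE_DIAMETER_ANGSTROM = 51.0

#: Dynamic viscosity of water at 50 degC (typical hydrolysis temperature), Pa*s.
WATER_VISCOSITY_50C_PA_S = 5.47e-4


class InfeasibleLoadingError(ValueError):
    """Raised when the bulk liquid volume implied by a biomass loading is
    smaller than the particle's own pore volume."""


def stokes_einstein_diffusivity(
    diameter_angstrom: float = CELLULASE_DIAMETER_ANGSTROM,
    temperature_k: float = 323.15,
    viscosity_pa_s: float = WATER_VISCOSITY_50C_PA_S,
) -> float:
    """Free-solution diffusivity of a sphere, in cm^2/min.

    D = k_B T / (3 pi mu d).  For a 51 A cellulase at 50 degC in water this
    gives ~1.0e-4 cm^2/min, the package default for the average pore
    diffusivity when none is supplied.
    """
    if diameter_angstrom <= 0:
        raise ValueError("diameter must be positive")
    d_m = diameter_angstrom * 1e-10
    d_m2_per_s = BOLTZMANN_J_PER_K * temperature_k / (3.0 * math.pi * viscosity_pa_s * d_m)
    return d_m2_per_s * 1e4 * 60.0  # m^2/s -> cm^2/min


@dataclass(frozen=True)
class KineticTransportParams:
    """Rate constants, transport properties and the two fitted parameters.

    Attributes
    ----------
    k_ads : float
        Cellulase surface adsorption rate constant, cm^3/(mol*min).
    k_des : float
        Cellulase surface desorption rate constant, 1/min.
    sigma : float
        Enzyme binding-site density on accessible cellulose surface, mol/cm^2
        (geometric footprint of a 51 A sphere).
    m_p : float
        Moles of glucose liberated per mole of enzyme during one
        adsorption-reaction-desorption cycle (lumped hydrolytic capacity;
        equivalent to an average intrinsic processivity).
    d_pore : float
        Average cellulase diffusivity inside pores, cm^2/min.
    tau : float
        Pore-network tortuosity, dimensionless (>= 1).
    h_glu : float
        Anhydroglucose/glucose mass ratio (162/180 = 0.9) converting
        dissolved cellulose mass to glucose mass.
    mm_glu : float
        Molar mass of glucose, g/mol.
    """

    k_ads: float = 3.0e10
    k_des: float = 0.068
    sigma: float = 2.1e-12
    m_p: float = 755.0
    d_pore: float = field(default_factory=stokes_einstein_diffusivity)
    tau: float = 2.0
    h_glu: float = 0.9
    mm_glu: float = 180.0

    def __post_init__(self) -> None:
        for name in ("k_ads", "k_des", "sigma", "d_pore", "tau", "h_glu", "mm_glu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.m_p < 0:
            raise ValueError("m_p must be non-negative (0 switches hydrolysis off)")
        if self.tau < 1.0:
            import warnings

            warnings.warn("tortuosity < 1 is unphysical for a pore network", stacklevel=2)

    @property
    def d_e(self) -> float:
        """Time-independent part of the effective diffusivity, D_pore/tau."""
        return self.d_pore / self.tau

    @property
    def langmuir_k(self) -> float:
        """Langmuir affinity K = k_ads/k_des, cm^3/mol."""
        return self.k_ads / self.k_des

    def with_fit(self, m_p: float, tau: float) -> "KineticTransportParams":
        return replace(self, m_p=m_p, tau=tau)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class OperatingConditions:
    """Batch operating point, bookkept per representative particle of unit
    length.

    Attributes
    ----------
    e_l : float
        Enzyme loading, mol enzyme per mol of initially accessible binding
        sites (e_l = 1 is exact full-coverage stoichiometry).
    b_l : float
        Biomass loading, g dry substrate per cm^3 bulk liquid.
    v_b : float
        Bulk liquid volume assigned to one representative particle of unit
        length, cm^3.
    c_e0 : float
        Initial bulk enzyme concentration, mol/cm^3.
    n_e0 : float
        Total enzyme moles in the system (per unit particle length), mol.
    """

    e_l: float
    b_l: float
    v_b: float
    c_e0: float
    n_e0: float

    def __post_init__(self) -> None:
        if self.e_l < 0:
            raise ValueError("enzyme loading must be non-negative")
        if self.b_l <= 0 or self.v_b <= 0:
            raise ValueError("biomass loading and bulk volume must be positive")
        if not math.isclose(self.c_e0 * self.v_b, self.n_e0, rel_tol=1e-9, abs_tol=1e-30):
            raise ValueError("inconsistent conditions: c_e0 * v_b != n_e0")

    def to_dict(self) -> dict:
        return asdict(self)


def bulk_concentration_from_loadings(e_l, b_l, derived, spec) -> OperatingConditions:
    """Convert (enzyme loading, biomass loading) into an initial bulk enzyme
    concentration by mole balance.

    Per representative particle of unit length: particle mass
    m_p = rho_p * pi * R^2, bulk volume V_B = m_p / b_l, total enzyme moles
    n_E0 = e_l * site_density * m_p, hence C_E0 = e_l * site_density * b_l.
    """
    if e_l < 0:
        raise ValueError("e_l must be >= 0")
    if b_l <= 0:
        raise ValueError("b_l must be > 0")
    m_particle = spec.rho_p * math.pi * spec.radius_cm**2
    v_b = m_particle / b_l
    pore_volume = derived.eps_0 * math.pi * spec.radius_cm**2
    if v_b <= pore_volume:
        raise InfeasibleLoadingError(
            f"biomass loading {b_l} g/cm^3 leaves bulk volume {v_b:.3g} cm^3 "
            f"below the particle pore volume {pore_volume:.3g} cm^3"
        )
    n_e0 = e_l * derived.site_density * m_particle
    c_e0 = n_e0 / v_b
    return OperatingConditions(e_l=e_l, b_l=b_l, v_b=v_b, c_e0=c_e0, n_e0=n_e0)


def e_l_from_mass_loading(
    mg_protein_per_g: float,
    site_density: float,
    enzyme_molar_mass: float = 65_000.0,
) -> float:
    """Convert a mass-based enzyme loading (mg protein per g substrate) to a
    molar site ratio e_l.

    The enzyme molar mass default of 65 kg/mol is an assumption for a lumped
    cellulase cocktail; override it when the cocktail composition is known.
    """
    if mg_protein_per_g < 0:
        raise ValueError("mass loading must be non-negative")
    if site_density <= 0:
        raise ValueError("site density must be positive")
    mol_per_g = mg_protein_per_g * 1e-3 / enzyme_molar_mass
    return mol_per_g / site_density
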