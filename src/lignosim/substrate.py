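"""Substrate characterisation: pore-size distributions and derived
cellulose-accessibility quantities.

The particle is a non-shrinking porous cylinder whose pores are treated as
parallel-wall slits.  A pore of width w contributes wall area per unit pore
volume according to how many flat walls a cellulase of diameter d_E can
reach:

* w >  2 d_E : both walls, area 2 v / w
* d_E <= w <= 2 d_E : one wall, area v / w
* w <  d_E : inaccessible, no area and no accessible volume

Exact boundary widths are assigned to the higher-accessibility class
(w = d_E counts one wall, w = 2 d_E counts two); the slit rule itself does
not fix the boundaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .params import ANGSTROM_TO_CM, CELLULASE_DIAMETER_ANGSTROM


class InfeasibleSubstrateError(ValueError):
    """Raised when derived porosities leave the physical range [0, 1]."""


@dataclass(frozen=True)
class PoreSizeDistribution:
    """Incremental pore-size distribution from wet-state porosimetry
    (solute exclusion): specific pore volume per width bin.

    Attributes
    ----------
    widths_angstrom : array
        Representative slit widths, A; strictly positive and increasing.
    volumes_cm3_per_g : array
        Incremental specific pore volume in each bin, cm^3 per g dry
        substrate; non-negative.
    """

    widths_angstrom: np.ndarray
    volumes_cm3_per_g: np.ndarray

    def __init__(self, widths_angstrom, volumes_cm3_per_g, cumulative: bool = False):
        w = np.asarray(widths_angstrom, dtype=float)
        v = np.asarray(volumes_cm3_per_g, dtype=float)
        if w.ndim != 1 or w.size == 0 or w.shape != v.shape:
            raise ValueError("PSD needs matching, non-empty width and volume arrays")
        if np.any(w <= 0):
            raise ValueError("pore widths must be strictly positive")
        if np.any(np.diff(w) <= 0):
            raise ValueError("pore widths must be strictly increasing")
        if cumulative:
            v = np.diff(v, prepend=0.0)
        if np.any(v < 0):
            raise ValueError("specific pore volumes must be non-negative")
        object.__setattr__(self, "widths_angstrom", w)
        object.__setattr__(self, "volumes_cm3_per_g", v)

    @property
    def total_volume(self) -> float:
        """Total specific pore volume, cm^3/g."""
        return float(self.volumes_cm3_per_g.sum())

    @classmethod
    def from_csv(cls, path: Union[str, Path], cumulative: bool = False) -> "PoreSizeDistribution":
        """Read a PSD table with header ``width_angstrom,volume_cm3_per_g``."""
        import pandas as pd

        df = pd.read_csv(path)
        missing = {"width_angstrom", "volume_cm3_per_g"} - set(df.columns)
        if missing:
            raise ValueError(f"PSD CSV missing columns: {sorted(missing)}")
        return cls(df["width_angstrom"].to_numpy(), df["volume_cm3_per_g"].to_numpy(),
                   cumulative=cumulative)

    def to_records(self) -> list:
        return [
            {"width_angstrom": float(w), "volume_cm3_per_g": float(v)}
            for w, v in zip(self.widths_angstrom, self.volumes_cm3_per_g)
        ]


@dataclass(frozen=True)
class SubstrateSpec:
    """Static physical description of one particle type.

    Attributes
    ----------
    radius_cm : float
        Particle radius R, cm.
    rho_p : float
        Apparent particle density (voids included), g/cm^3.
    f_cell : float
        Cellulose mass fraction of the dry substrate.
    digestibility : float
        Fraction of cellulose hydrolyzable at completion, inferred from the
        final experimental glucose yield.
    rho_c_iv : float
        Density of cellulose including inaccessible void volume, g/cm^3.
    psd : PoreSizeDistribution
    label : str
    """

    radius_cm: float
    rho_p: float
    f_cell: float
    digestibility: float
    rho_c_iv: float
    psd: PoreSizeDistribution
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius_cm <= 0:
            raise ValueError("particle radius must be positive")
        if self.rho_p <= 0:
            raise ValueError("apparent density must be positive")
        if not 0.0 <= self.f_cell <= 1.0:
            raise ValueError("cellulose fraction must lie in [0, 1]")
        if not 0.0 <= self.digestibility <= 1.0:
            raise ValueError("digestibility must lie in [0, 1]")
        if self.rho_c_iv <= 0:
            raise ValueError("cellulose density must be positive")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "radius_cm": self.radius_cm,
            "apparent_density_g_cm3": self.rho_p,
            "cellulose_fraction": self.f_cell,
            "digestibility": self.digestibility,
            "cellulose_density_g_cm3": self.rho_c_iv,
            "psd": self.psd.to_records(),
        }


@dataclass(frozen=True)
class SubstrateDerived:
    """Accessibility quantities derived from a SubstrateSpec.

    eps_0 : initial accessible porosity, cm^3 pore / cm^3 particle
    eps_f : porosity at exhaustion of hydrolyzable cellulose
    s_spec : accessible cellulose surface, cm^2/g substrate
    accessible_volume : accessible specific pore volume, cm^3/g
    site_density : mol binding sites per g substrate
    c_s_max0 : initial maximum bound-enzyme concentration per total particle
        volume, mol/cm^3
    """

    eps_0: float
    eps_f: float
    s_spec: float
    accessible_volume: float
    site_density: float
    c_s_max0: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.eps_0 <= self.eps_f <= 1.0):
            raise InfeasibleSubstrateError(
                f"porosities out of range: eps_0={self.eps_0}, eps_f={self.eps_f}"
            )
        if self.s_spec < 0 or self.site_density < 0 or self.c_s_max0 < 0:
            raise ValueError("surface and site quantities must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def accessible_surface_from_psd(
    psd: PoreSizeDistribution,
    enzyme_diameter_angstrom: float = CELLULASE_DIAMETER_ANGSTROM,
) -> tuple[float, float]:
    """Accessible cellulose wall area and accessible pore volume from a PSD.

    Applies the slit-pore wall-counting rule bin by bin (see module
    docstring) and returns ``(surface_cm2_per_g, volume_cm3_per_g)``.
    """
    if enzyme_diameter_angstrom <= 0:
        raise ValueError("enzyme diameter must be positive")
    w_ang = psd.widths_angstrom
    v = psd.volumes_cm3_per_g
    w_cm = w_ang * ANGSTROM_TO_CM
    # boundary widths go to the higher-accessibility class (compared in
    # Angstrom so unit conversion cannot blur the breakpoints)
    walls = np.where(
        w_ang >= 2.0 * enzyme_diameter_angstrom, 2.0,
        np.where(w_ang >= enzyme_diameter_angstrom, 1.0, 0.0),
    )
    surface = float(np.sum(walls * v / w_cm))
    accessible_volume = float(np.sum(v[w_ang >= enzyme_diameter_angstrom]))
    return surface, accessible_volume


def binding_site_density(s_spec: float, sigma: float = 2.1e-12) -> float:
    """Moles of enzyme binding sites per g substrate: accessible surface
    times the footprint site density sigma (mol/cm^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if s_spec < 0:
        raise ValueError("surface must be non-negative")
    return s_spec * sigma


def derive_substrate(
    spec: SubstrateSpec,
    sigma: float = 2.1e-12,
    enzyme_diameter_angstrom: float = CELLULASE_DIAMETER_ANGSTROM,
    cellulose_fraction_scaling: bool = False,
) -> SubstrateDerived:
    """Derive porosities, accessible surface and binding-site capacity.

    eps_0 = accessible specific pore volume * rho_p.  Complete hydrolysis of
    the digestible cellulose converts its solid volume into pore volume:
    eps_f = eps_0 + d * f_cell * rho_p / rho_C^IV.  The initial bound-enzyme
    capacity per total particle volume is site_density * rho_p.

    ``cellulose_fraction_scaling`` optionally attributes only the cellulose
    fraction of the accessible wall area to binding (default off: the whole
    accessible wall is treated as cellulose surface).
    """
    s_spec, acc_vol = accessible_surface_from_psd(spec.psd, enzyme_diameter_angstrom)
    if cellulose_fraction_scaling:
        s_spec *= spec.f_cell
    eps_0 = acc_vol * spec.rho_p
    if eps_0 >= 1.0:
        raise InfeasibleSubstrateError(
            f"accessible pore volume implies initial porosity {eps_0:.3f} >= 1"
        )
    eps_f = eps_0 + spec.digestibility * spec.f_cell * spec.rho_p / spec.rho_c_iv
    if eps_f > 1.0 + 1e-12:
        raise InfeasibleSubstrateError(
            f"porosity at exhaustion {eps_f:.3f} exceeds 1; "
            "composition, density and digestibility are inconsistent"
        )
    eps_f = min(eps_f, 1.0)
    sites = binding_site_density(s_spec, sigma)
    return SubstrateDerived(
        eps_0=eps_0,
        eps_f=eps_f,
        s_spec=s_spec,
        accessible_volume=acc_vol,
        site_density=sites,
        c_s_max0=sites * spec.rho_p,
    )


# ---------------------------------------------------------------------------
# I/O


def _spec_from_mapping(data: dict) -> SubstrateSpec:
    psd_raw = data["psd"]
    if isinstance(psd_raw, (str, Path)):
        psd = PoreSizeDistribution.from_csv(psd_raw, cumulative=data.get("psd_cumulative", False))
    else:
        psd = PoreSizeDistribution(
            [row["width_angstrom"] for row in psd_raw],
            [row["volume_cm3_per_g"] for row in psd_raw],
            cumulative=data.get("psd_cumulative", False),
        )
    return SubstrateSpec(
        radius_cm=float(data["radius_cm"]),
        rho_p=float(data["apparent_density_g_cm3"]),
        f_cell=float(data["cellulose_fraction"]),
        digestibility=float(data["digestibility"]),
        rho_c_iv=float(data["cellulose_density_g_cm3"]),
        psd=psd,
        label=str(data.get("label", "")),
    )


def load_substrate_spec(path: Union[str, Path]) -> SubstrateSpec:
    """Load a substrate spec from YAML or JSON.

    Expected keys: radius_cm, apparent_density_g_cm3, cellulose_fraction,
    digestibility, cellulose_density_g_cm3, psd (list of
    {width_angstrom, volume_cm3_per_g} or a path to a PSD CSV), optional
    psd_cumulative flag and label.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    return _spec_from_mapping(data)


def save_substrate_spec(spec: SubstrateSpec, path: Union[str, Path]) -> None:
    path = Path(path)
    data = spec.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        import yaml

        path.write_text(yaml.safe_dump(data, sort_keys=False))
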