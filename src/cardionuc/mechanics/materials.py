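"""Material parameter sets for the chemo-mechanical cardiomyocyte model.

Units throughout: lengths in µm, stresses and moduli in kPa (so the
chemical-feedback parameters beta and alpha_v are in kPa^-1).

The cytoplasm (myofibril) constitutive law is a linear-elastic medium with
an isotropic rest contractility rho0 whose magnitude feeds back on the
mechanical state through a chemical stiffness beta and a volumetric
feedback parameter alpha_v.  Eliminating the contractility from the
stress-strain relation renormalises the elastic moduli: the solver works
with the "barred" effective bulk/shear moduli and effective contractility
computed by :func:`effective_moduli`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple


class SingularParametersError(ValueError):
    """Raised when beta <= alpha_v makes the effective moduli singular."""


class EffectiveModuli(NamedTuple):
    Kbar: float        # effective bulk modulus, kPa
    mubar: float       # effective shear modulus, kPa
    rhobar0: float     # effective rest contractility, kPa
    Kbar_rho: float    # bulk feedback modulus of the contractility tensor, kPa
    mubar_rho: float   # shear feedback modulus of the contractility tensor, kPa


def bulk_shear(E: float, nu: float) -> tuple[float, float]:
    """Bulk and shear moduli K = E/(3(1-2nu)), mu = E/(2(1+nu))."""
    return E / (3.0 * (1.0 - 2.0 * nu)), E / (2.0 * (1.0 + nu))


def effective_moduli(E: float, nu: float, beta: float, alpha_v: float,
                     rho0: float) -> EffectiveModuli:
    """Renormalised moduli of the chemo-mechanical myofibril law.

    3*Kbar     = (3*K*beta - 1) / (beta - alpha_v)
    2*mubar    = (2*mu*beta - 1) / (beta - alpha_v)
    rhobar0    = beta*rho0 / (beta - alpha_v)
    3*Kbar_rho = (3*K*alpha_v - 1) / (beta - alpha_v)
    2*mubar_rho= (2*mu*alpha_v - 1) / (beta - alpha_v)

    Raises
    ------
    SingularParametersError
        If ``beta <= alpha_v`` (the chemo-mechanical feedback denominator
        changes sign and the effective medium is ill-defined).
    """
    if not (E > 0 and beta > 0):
        raise ValueError("E and beta must be positive")
    if beta <= alpha_v:
        raise SingularParametersError(
            f"beta ({beta}) must exceed alpha_v ({alpha_v})")
    K, mu = bulk_shear(E, nu)
    den = beta - alpha_v
    Kbar = (3.0 * K * beta - 1.0) / (3.0 * den)
    mubar = (2.0 * mu * beta - 1.0) / (2.0 * den)
    rhobar0 = beta * rho0 / den
    Kbar_rho = (3.0 * K * alpha_v - 1.0) / (3.0 * den)
    mubar_rho = (2.0 * mu * alpha_v - 1.0) / (2.0 * den)
    return EffectiveModuli(Kbar, mubar, rhobar0, Kbar_rho, mubar_rho)


@dataclass
class Geometry:
    """Axisymmetric quarter-cell geometry (µm).

    The quarter domain is r in [0, cell_radius], z in [0, cell_length/2];
    the nucleus is a sphere of ``nuclear_radius`` centred at the origin
    whose outer ``ne_thickness`` is the nuclear-envelope (NE) + lamina
    shell; the perinuclear microtubule cage fills the space between the
    nucleus and the ellipse with semi-axes ``cage_semi_axis_z`` (axial)
    x ``cage_semi_axis_r`` (radial).
    """
    cell_radius: float = 35.0
    cell_length: float = 100.0
    nuclear_radius: float = 4.0
    ne_thickness: float = 0.2
    cage_semi_axis_z: float = 8.0
    cage_semi_axis_r: float = 4.4

    def validate(self) -> None:
        if self.nuclear_radius <= 0:
            raise ValueError("nuclear_radius must be positive")
        if not 0 < self.ne_thickness < self.nuclear_radius:
            raise ValueError("ne_thickness must lie inside the nucleus")
        if self.nuclear_radius >= self.cell_radius:
            raise ValueError("nucleus must fit inside the cell radius")
        if self.cage_semi_axis_r <= self.nuclear_radius:
            raise ValueError("cage radial semi-axis must clear the nucleus")
        if self.cage_semi_axis_z >= self.cell_length / 2:
            raise ValueError("cage axial semi-axis exceeds the half cell")


@dataclass
class CytoplasmParams:
    """Myofibril (cytoplasm) chemo-mechanical parameters."""
    E: float = 1.2          # kPa
    nu: float = 0.3
    beta: float = 2.77      # kPa^-1, chemical stiffness
    alpha_v: float = 2.3    # kPa^-1, volumetric feedback
    rho0: float = 1.2       # kPa, rest contractility at full load

    def effective(self, rho0_fraction: float = 1.0) -> EffectiveModuli:
        return effective_moduli(self.E, self.nu, self.beta, self.alpha_v,
                                self.rho0 * rho0_fraction)


@dataclass
class NucleusParams:
    """Nucleoplasm (chromatin) and nuclear envelope + lamina moduli.

    Chromatin is soft and linear (150 Pa = 0.15 kPa, nearly incompressible
    at nu = 0.49); the NE + lamina layer is a stiff, volume-preserving
    membrane (15 kPa; nu -> 0.5 handled as 0.4999 in the displacement
    formulation, with conservation checked a posteriori).
    """
    E_chromatin: float = 0.15   # kPa
    nu_chromatin: float = 0.49
    E_ne: float = 15.0          # kPa
    nu_ne: float = 0.4999


@dataclass
class CageParams:
    """Perinuclear microtubule cage: passive elasticity + active compression.

    The cage shares the cytoplasm's elastic constants by default; sigma_MT
    is the isotropic active compressive stress it exerts (0.5 kPa at the
    physiological working point).
    """
    E: float = 1.2
    nu: float = 0.3
    sigma_MT: float = 0.5   # kPa, >= 0

    def __post_init__(self) -> None:
        if self.sigma_MT < 0:
            raise ValueError("sigma_MT must be non-negative")

    @property
    def K_MT(self) -> float:
        return bulk_shear(self.E, self.nu)[0]

    @property
    def mu_MT(self) -> float:
        return bulk_shear(self.E, self.nu)[1]


@dataclass
class ConditionSpec:
    """Named experimental condition mapped onto model parameters.

    ``cage_scale`` multiplies the cage's active compressive stress
    sigma_MT (reduced MT forces model LINC disruption); ``E_ne`` is the
    NE + lamina modulus (softened by lamin A/C deficiency).
    """
    name: str
    E_ne: float = 15.0
    cage_scale: float = 1.0


#: Default condition presets: lamin A/C mutation softens the NE to 10 kPa;
#: LINC disruption removes most of the MT cage's compressive force (x0.1).
CONDITIONS: dict[str, ConditionSpec] = {
    "WT": ConditionSpec("WT", E_ne=15.0, cage_scale=1.0),
    "LMNA": ConditionSpec("LMNA", E_ne=10.0, cage_scale=1.0),
    "LINC": ConditionSpec("LINC", E_ne=15.0, cage_scale=0.1),
    "LMNA_LINC": ConditionSpec("LMNA_LINC", E_ne=10.0, cage_scale=0.1),
}


@dataclass
class LoadRamp:
    """Proportional load ramp from the stress-free state to full load.

    ``steps`` is an ordered list of (rho0 fraction, sigma_MT fraction)
    pairs, monotone non-decreasing, ending at (1, 1).
    """
    steps: list[tuple[float, float]] = field(
        default_factory=lambda: [((k + 1) / 10, (k + 1) / 10)
                                 for k in range(10)])

    def validate(self) -> None:
        prev = (0.0, 0.0)
        for s in self.steps:
            if s[0] < prev[0] or s[1] < prev[1]:
                raise ValueError("ramp fractions must be non-decreasing")
            prev = s
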