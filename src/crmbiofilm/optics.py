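"""Closed-form confocal / index-matching optics.

Confocal reflection microscopy (CRM) images backscattered incident light;
contrast at a solid-liquid interface is set by the Fresnel reflectance of the
refractive-index (RI) step, and the optical-slice thickness by the axial FWHM
of the confocal point spread function.  An index-matching material (IMM)
overlaid on the glass suppresses the interface reflection, at the cost of
clipping the numerical aperture of an oil-immersion objective to the layer RI
(rays steeper than the critical angle are totally internally reflected at the
glass-IMM boundary).

All lengths are micrometres internally; wavelengths are accepted in
nanometres at the public boundary and converted once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "OpticalConfig",
    "ImmLayer",
    "Interface",
    "airy_unit_diameter",
    "axial_fwhm",
    "fresnel_reflectance",
    "effective_na",
    "min_imm_thickness",
]

NM_PER_UM = 1000.0


class InvalidParameterError(ValueError):
    """An optics parameter is outside its physical domain."""


@dataclass(frozen=True)
class OpticalConfig:
    """Confocal imaging configuration.

    Parameters
    ----------
    wavelength_nm:
        Illumination wavelength in nanometres (> 0).
    numerical_aperture:
        Objective NA, n*sin(theta_max); must satisfy 0 < NA <= immersion_ri.
    immersion_ri:
        Refractive index of the immersion medium (oil ~1.515, water ~1.333,
        air 1.0).
    pinhole_au:
        Confocal pinhole diameter as a multiple of the Airy unit (> 0).
    """

    wavelength_nm: float
    numerical_aperture: float
    immersion_ri: float
    pinhole_au: float = 1.2

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise InvalidParameterError("wavelength_nm must be > 0")
        if self.numerical_aperture <= 0:
            raise InvalidParameterError("numerical_aperture must be > 0")
        if self.immersion_ri <= 0:
            raise InvalidParameterError("immersion_ri must be > 0")
        if self.numerical_aperture > self.immersion_ri:
            raise InvalidParameterError(
                f"NA {self.numerical_aperture} exceeds immersion RI "
                f"{self.immersion_ri} (evanescent regime)"
            )
        if self.pinhole_au <= 0:
            raise InvalidParameterError("pinhole_au must be > 0")

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm / NM_PER_UM


@dataclass(frozen=True)
class ImmLayer:
    """Index-matching layer: refractive index and thickness in micrometres."""

    refractive_index: float
    thickness_um: float

    def __post_init__(self) -> None:
        if self.refractive_index < 1.0:
            raise InvalidParameterError("layer refractive_index must be >= 1")
        if self.thickness_um < 0:
            raise InvalidParameterError("layer thickness_um must be >= 0")


@dataclass(frozen=True)
class Interface:
    """A planar interface between two media of refractive index n1, n2."""

    ri_incident: float
    ri_transmitted: float

    def __post_init__(self) -> None:
        if self.ri_incident <= 0 or self.ri_transmitted <= 0:
            raise InvalidParameterError("refractive indices must be > 0")


def airy_unit_diameter(wavelength_nm: float, numerical_aperture: float) -> float:
    """Airy-disk diameter 1.22*lambda/NA in object space, micrometres.

    This is the unit in which confocal pinholes are sized ("1.2 AU").
    """
    if wavelength_nm <= 0 or numerical_aperture <= 0:
        raise InvalidParameterError("wavelength and NA must be > 0")
    return 1.22 * (wavelength_nm / NM_PER_UM) / numerical_aperture


def axial_fwhm(config: OpticalConfig, *, diffraction_only: bool = False) -> float:
    """Axial FWHM of the confocal PSF (the optical-slice thickness), in um.

    Combines in quadrature a diffraction term

        0.88 * lambda / (n - sqrt(n^2 - NA^2))

    and a finite-pinhole term

        sqrt(2) * n * PH / NA

    where PH is the backprojected pinhole diameter (pinhole_au x Airy unit) in
    object space.  ``diffraction_only=True`` returns the pinhole->0 limit.

    The result strictly decreases with NA (fixed lambda, n, AU) and strictly
    increases with the pinhole diameter.
    """
    lam = config.wavelength_um
    na = config.numerical_aperture
    n = config.immersion_ri
    diffraction = 0.88 * lam / (n - math.sqrt(n * n - na * na))
    if diffraction_only:
        return diffraction
    ph = config.pinhole_au * airy_unit_diameter(config.wavelength_nm, na)
    pinhole = math.sqrt(2.0) * n * ph / na
    return math.hypot(diffraction, pinhole)


def fresnel_reflectance(interface: Interface) -> float:
    """Normal-incidence Fresnel power reflectance ((n1-n2)/(n1+n2))^2.

    Symmetric in its arguments, zero iff the indices match, and < 1 for any
    positive pair — the quantity that sets the interface background in CRM.
    """
    n1, n2 = interface.ri_incident, interface.ri_transmitted
    r = (n1 - n2) / (n1 + n2)
    return r * r


def effective_na(numerical_aperture: float, layer: ImmLayer) -> float:
    """NA of an objective imaging through an IMM layer.

    With any layer of finite thickness present, rays steeper than the layer's
    critical angle undergo total internal reflection at the glass-layer
    boundary, clipping the aperture: the effective NA is
    min(NA, layer RI).  A zero-thickness layer leaves the NA unchanged.
    """
    if numerical_aperture <= 0:
        raise InvalidParameterError("numerical_aperture must be > 0")
    if layer.thickness_um > 0:
        return min(numerical_aperture, layer.refractive_index)
    return numerical_aperture


def min_imm_thickness(axial_fwhm_um: float) -> float:
    """Minimum IMM layer thickness for reflection-free optical slices, in um.

    The layer must be at least one axial FWHM thick so that an optical slice
    at the IMM-liquid interface excludes the glass-IMM interface below it;
    the rule is the identity on the axial FWHM.
    """
    if axial_fwhm_um <= 0:
        raise InvalidParameterError("axial_fwhm_um must be > 0")
    return axial_fwhm_um
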