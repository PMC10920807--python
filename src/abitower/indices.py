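"""Radiometric conversions and vegetation indices.

Covers the chain from at-sensor radiance to the photosynthesis proxies:

* kappa = pi d^2 / E_sun, the Lambertian-equivalent factor that converts a
  reflective-band radiance to a TOA reflectance factor;
* the direct ("R3") atmospheric-correction closed form
  r_s = (r - r0) / (gamma + (r - r0) rho);
* BRF = pi * BRDF;
* NDVI = (NIR - Red)/(NIR + Red), NIRv = (NDVI - soil_offset) * NIR,
  NIRvP = NIRv * PAR with PAR approximated as 0.45 * DSR;
* PPFD = 4.56 umol J^-1 * PAR.

All functions accept scalars or numpy arrays and propagate NaN as missing.
Reflectance factors are nominally in [0, 1.3]; out-of-range values are
flagged, never clipped, so the product's envelope semantics survive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BandSolarConstants",
    "AtmosphericParams",
    "ReflectanceSet",
    "RetrievalFailure",
    "kappa_factor",
    "toa_reflectance",
    "surface_reflectance_r3",
    "brf_from_brdf",
    "ndvi",
    "nirv",
    "par_from_dsr",
    "nirvp",
    "ppfd_from_par",
    "PAR_FRACTION_OF_DSR",
    "PPFD_PER_PAR_W",
    "REFLECTANCE_MAX",
]

#: PAR approximated as this fraction of total downward shortwave radiation.
PAR_FRACTION_OF_DSR = 0.45
#: PAR energy (W m^-2 = J s^-1 m^-2) to photon flux (umol m^-2 s^-1).
PPFD_PER_PAR_W = 4.56
#: Upper end of the reflectance-factor envelope delivered by the imagery.
REFLECTANCE_MAX = 1.3


class RetrievalFailure(ValueError):
    """The atmospheric-correction denominator is not positive."""


@dataclass(frozen=True)
class BandSolarConstants:
    """Band solar irradiance (W m^-2 um^-1) and Earth-Sun distance (AU)."""

    esun_w_m2_um: float
    earth_sun_distance_au: float = 1.0

    def __post_init__(self) -> None:
        if self.esun_w_m2_um <= 0:
            raise ValueError("band solar irradiance must be positive")
        if self.earth_sun_distance_au <= 0:
            raise ValueError("Earth-Sun distance must be positive")


@dataclass(frozen=True)
class AtmosphericParams:
    """Transmittance, path reflectance and spherical albedo of one view."""

    transmittance: float
    path_reflectance: float = 0.0
    spherical_albedo: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.transmittance <= 1.0:
            raise ValueError("transmittance must be in (0, 1]")
        if not 0.0 <= self.path_reflectance < 1.0:
            raise ValueError("path reflectance must be in [0, 1)")
        if not 0.0 <= self.spherical_albedo < 1.0:
            raise ValueError("spherical albedo must be in [0, 1)")


@dataclass(frozen=True)
class ReflectanceSet:
    """Red (band 2) and NIR (band 3) surface reflectance factors."""

    red: float
    nir: float


def kappa_factor(consts: BandSolarConstants) -> float:
    """kappa = pi d^2 / E_sun; multiplies radiance to give reflectance."""
    d = consts.earth_sun_distance_au
    return math.pi * d * d / consts.esun_w_m2_um


def toa_reflectance(radiance, kappa: float, warn_out_of_range: bool = True):
    """Scale radiance (W m^-2 sr^-1 um^-1) to a TOA reflectance factor.

    Values outside the nominal [0, 1.3] envelope are kept but produce a
    warning; the caller decides whether to discard them.
    """
    refl = np.multiply(radiance, kappa)
    if warn_out_of_range:
        bad = (np.asarray(refl) < 0.0) | (np.asarray(refl) > REFLECTANCE_MAX)
        if np.any(bad):
            warnings.warn(
                f"{int(np.sum(bad))} reflectance value(s) outside [0, "
                f"{REFLECTANCE_MAX}]",
                stacklevel=2,
            )
    return refl


def surface_reflectance_r3(r_toa, atm: AtmosphericParams):
    """Direct surface reflectance: r_s = (r - r0) / (gamma + (r - r0) rho)."""
    delta = np.subtract(r_toa, atm.path_reflectance)
    denom = atm.transmittance + delta * atm.spherical_albedo
    if np.any(np.asarray(denom) <= 0.0):
        raise RetrievalFailure("nonpositive denominator in surface retrieval")
    return delta / denom


def brf_from_brdf(brdf):
    """Reflectance factor from a BRDF value: BRF = pi * BRDF."""
    return np.multiply(brdf, math.pi)


def _as_red_nir(refl) -> tuple:
    if isinstance(refl, ReflectanceSet):
        return refl.red, refl.nir
    red, nir = refl
    return red, nir


def ndvi(refl):
    """(NIR - Red)/(NIR + Red); NaN where the denominator is zero."""
    red, nir = _as_red_nir(refl)
    denom = np.add(nir, red)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.asarray(denom) != 0.0, np.subtract(nir, red) / denom, np.nan)
    return float(out) if np.ndim(out) == 0 else out


def nirv(refl, soil_offset: float = 0.0):
    """NIRv = (NDVI - soil_offset) * NIR.

    The soil offset (commonly 0.08) defaults to 0: the unadjusted form is
    what the distributed record carries, and a regional offset can be
    applied downstream.
    """
    red, nir = _as_red_nir(refl)
    return np.multiply(np.subtract(ndvi(refl), soil_offset), nir)


def par_from_dsr(dsr_w_m2, fraction: float = PAR_FRACTION_OF_DSR):
    """PAR (W m^-2) approximated as a fixed fraction of DSR."""
    return np.multiply(dsr_w_m2, fraction)


def nirvp(nirv_value, par_w_m2):
    """NIRvP = NIRv * PAR (W m^-2)."""
    return np.multiply(nirv_value, par_w_m2)


def ppfd_from_par(par_w_m2, factor: float = PPFD_PER_PAR_W):
    """Photon flux density (umol m^-2 s^-1) from PAR in W m^-2."""
    return np.multiply(par_w_m2, factor)
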