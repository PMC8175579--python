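"""Local new-nitrogen sources: Trichodesmium N2-fixation and the
nitrification potential of the ammonium pool.

Fixation follows a chlorophyll-specific photo-fixation model: the
per-chlorophyll rate saturates exponentially with irradiance,

    F(E) = fmax * (1 - exp(-alpha * E / fmax)),

and volumetric rates scale with trichome abundance and per-trichome
chlorophyll over a fixed photoperiod.  Nitrification potential is the
product of the ambient ammonium stock and a literature
ammonium-specific oxidation rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrichomeProfile",
    "PhotoFixationParams",
    "PARProfile",
    "fixation_rate_profile",
    "integrate_fixation",
    "nitrification_potential",
]


@dataclass
class TrichomeProfile:
    """Trichome abundance (trichomes L^-1) and per-trichome chlorophyll
    (ng chl a trichome^-1) vs depth (m)."""

    depth: np.ndarray
    abundance: np.ndarray
    chl_per_trichome: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.chl_per_trichome = np.broadcast_to(
            np.asarray(self.chl_per_trichome, dtype=float), self.depth.shape).copy()
        if np.any(self.abundance < 0):
            raise ValueError("abundance must be non-negative")
        if np.any(self.chl_per_trichome <= 0):
            raise ValueError("chl_per_trichome must be positive")


@dataclass
class PhotoFixationParams:
    """Photo-fixation curve parameters.

    fmax : light-saturated chl-specific fixation, umol N (ug chl)^-1 h^-1.
    alpha : initial slope vs irradiance,
        umol N (ug chl)^-1 h^-1 per (umol photons m^-2 s^-1).
    photoperiod : h of daylight fixation per day (dark fixation zero).
    temperature : deg C, informational (defaults match the 26 degC /
        12 h culture conditions behind the coefficient set).
    """

    fmax: float
    alpha: float
    photoperiod: float = 12.0
    temperature: float = 26.0

    def __post_init__(self) -> None:
        if self.fmax <= 0 or self.alpha <= 0:
            raise ValueError("fmax and alpha must be positive")
        if not 0 < self.photoperiod <= 24:
            raise ValueError("photoperiod must be in (0, 24] h")


@dataclass
class PARProfile:
    """Photosynthetically active radiation (umol photons m^-2 s^-1) vs depth."""

    depth: np.ndarray
    irradiance: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        if np.any(self.irradiance < 0):
            raise ValueError("irradiance must be non-negative")
        if np.any(np.diff(self.irradiance) > 1e-12):
            raise ValueError("irradiance must be non-increasing with depth")


def fixation_rate_profile(tp: TrichomeProfile, par: PARProfile,
                          params: PhotoFixationParams) -> np.ndarray:
    """Volumetric N2-fixation (umol N m^-3 d^-1) at the trichome depths.

    PAR is linearly interpolated onto the trichome depths; the profiles
    must overlap in depth.
    """
    if tp.depth.min() > par.depth.max() or tp.depth.max() < par.depth.min():
        raise ValueError("trichome and PAR profiles do not overlap in depth")
    E = np.interp(tp.depth, par.depth, par.irradiance)
    # trichomes L^-1 -> m^-3 (x1000); ng chl -> ug chl (x1e-3)
    chl_density = tp.abundance * 1000.0 * tp.chl_per_trichome * 1e-3  # ug chl m^-3
    per_chl = params.fmax * (1.0 - np.exp(-params.alpha * E / params.fmax))
    return chl_density * per_chl * params.photoperiod


def integrate_fixation(depth: np.ndarray, rate: np.ndarray,
                       z_top: float, z_bottom: float) -> float:
    """Trapezoidal depth integral (umol N m^-2 d^-1) over [z_top, z_bottom]."""
    depth = np.asarray(depth, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if z_top >= z_bottom:
        raise ValueError("z_top must be shallower than z_bottom")
    if z_top < depth.min() - 1e-9 or z_bottom > depth.max() + 1e-9:
        raise ValueError("integration bounds must lie inside the profile span")
    zs = np.unique(np.concatenate([[z_top, z_bottom],
                                   depth[(depth > z_top) & (depth < z_bottom)]]))
    rs = np.interp(zs, depth, rate)
    return float(np.trapezoid(rs, zs))


def nitrification_potential(nh4: float, specific_rate: float) -> float:
    """Potential nitrate source (umol N m^-3 d^-1) from ammonium oxidation:
    ambient NH4+ stock (umol m^-3) times an ammonium-specific rate (d^-1)."""
    if nh4 < 0 or specific_rate < 0:
        raise ValueError("ammonium and specific rate must be non-negative")
    return nh4 * specific_rate
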