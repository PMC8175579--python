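"""Turbulent diffusive nutrient fluxes across euphotic-zone boundaries.

The diffusive flux of nitrate across a horizontal surface is
``F = -K_z d[NO3]/dz`` with z positive upward; with the package's
depth-positive-downward convention a nitrate concentration that
increases downward (positive gradient) and a positive diffusivity give
a positive, upward flux into the overlying layer:

    flux [umol N m^-2 d^-1] = K_z [m^2 s^-1] * gradient [umol m^-4] * 86400
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NutrientProfile", "VerticalFluxEstimate", "layer_gradient", "diffusive_flux"]

SECONDS_PER_DAY = 86400.0


@dataclass
class NutrientProfile:
    """Nutrient concentration vs depth.

    conc is in umol m^-3 (1 nM == 1 umol m^-3); depth in metres,
    positive downward, strictly increasing.
    """

    species: str
    depth: np.ndarray
    conc: np.ndarray
    cast_id: str = ""
    time: str = ""

    def __post_init__(self) -> None:
        if self.species not in ("nitrate", "ammonium"):
            raise ValueError(f"unknown nutrient species {self.species!r}")
        self.depth = np.asarray(self.depth, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if not np.all(np.diff(self.depth) > 0):
            raise ValueError("depth must be strictly increasing")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")

    @classmethod
    def from_nM(cls, species: str, depth, conc_nM, **kw) -> "NutrientProfile":
        # 1 nM = 1 umol m^-3: numerically identical, kept for intent
        return cls(species, depth, np.asarray(conc_nM, dtype=float), **kw)


@dataclass
class VerticalFluxEstimate:
    """Diffusive flux across a depth layer, positive upward (into the
    euphotic zone)."""

    layer: tuple[float, float]
    kz: float
    gradient: float
    flux: float  # umol N m^-2 d^-1


def layer_gradient(p: NutrientProfile, layer: tuple[float, float]) -> float:
    """d[conc]/dz (umol m^-4) over a depth layer by OLS.

    Uses the samples inside the layer; if fewer than two fall inside,
    the nearest bracketing samples above and below are added.  With
    exactly two samples the OLS slope reduces to the finite difference.
    """
    lo, hi = layer
    inside = (p.depth >= lo) & (p.depth <= hi)
    idx = np.flatnonzero(inside)
    if idx.size < 2:
        above = np.flatnonzero(p.depth < lo)
        below = np.flatnonzero(p.depth > hi)
        extra = []
        if above.size:
            extra.append(above[-1])
        if below.size:
            extra.append(below[0])
        idx = np.unique(np.concatenate([idx, np.array(extra, dtype=int)]))
    if idx.size < 2:
        raise ValueError(f"need at least 2 samples within or bracketing layer {layer}")
    z, c = p.depth[idx], p.conc[idx]
    return float(np.polyfit(z, c, 1)[0])


def diffusive_flux(kz: float, gradient: float,
                   layer: tuple[float, float] = (0.0, 0.0)) -> VerticalFluxEstimate:
    """Upward diffusive flux (umol N m^-2 d^-1) from K_z and the
    downward-positive concentration gradient."""
    if kz < 0:
        raise ValueError("K_z must be non-negative")
    flux = kz * gradient * SECONDS_PER_DAY
    return VerticalFluxEstimate(layer=tuple(layer), kz=float(kz),
                                gradient=float(gradient), flux=float(flux))
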