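"""Thorpe-scale analysis of CTD density profiles.

Turbulent overturns appear in a CTD cast as gravitationally unstable
density inversions.  Sorting the potential-density profile into a
monotonically stable state defines, for every sample, a Thorpe
displacement (the vertical distance the sample must move); the rms
displacement over an overturning patch is the Thorpe length ``L_T``,
an observable proxy for the Ozmidov overturning scale.  Assuming a
fixed Ozmidov/Thorpe ratio ``a`` and mixing efficiency ``gamma``,

    epsilon = (a * L_T)**2 * N**3
    K_z     = gamma * epsilon / N**2  =  gamma * a**2 * L_T**2 * N

with ``N`` the buoyancy frequency of the sorted (stable) profile over
the patch.  Per-cast diffusivity profiles are averaged across the casts
of a Lagrangian experiment with the geometric mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import InitVar, dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DensityProfile",
    "DisplacementProfile",
    "OverturnSegment",
    "MixingParams",
    "DiffusivityProfile",
    "DegenerateProfileError",
    "preprocess_profile",
    "thorpe_displacements",
    "detect_overturns",
    "cast_kz_profile",
    "average_kz",
    "layer_geomean",
]


class DegenerateProfileError(ValueError):
    """Raised when a profile has too few valid samples to analyse."""


@dataclass
class DensityProfile:
    """A single cast: potential density anomaly vs depth.

    depth is in metres, positive downward and strictly increasing;
    sigma is potential density anomaly (sigma_theta) in kg m^-3.
    ``validate=False`` admits raw (unprocessed) casts that still contain
    pressure reversals, for feeding to :func:`preprocess_profile`.
    """

    cast_id: str
    time: str
    depth: np.ndarray
    sigma: np.ndarray
    temperature: np.ndarray | None = None
    salinity: np.ndarray | None = None
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool = True) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.depth.size < 3:
            raise DegenerateProfileError(
                f"cast {self.cast_id}: need at least 3 samples, got {self.depth.size}"
            )
        if self.depth.shape != self.sigma.shape:
            raise ValueError("depth and sigma must have the same length")
        if not validate:
            return
        if not np.all(np.isfinite(self.sigma)):
            raise ValueError(f"cast {self.cast_id}: non-finite sigma values")
        if not np.all(np.diff(self.depth) > 0):
            raise ValueError(f"cast {self.cast_id}: depth must be strictly increasing")


@dataclass
class DisplacementProfile:
    """Thorpe displacements: sorted-position depth minus original depth."""

    depth: np.ndarray
    displacement: np.ndarray


@dataclass
class OverturnSegment:
    start_depth: float
    end_depth: float
    L_T: float
    N: float
    epsilon: float
    K_z: float
    n_samples: int = 0
    sum_abs_displacement: float = 0.0


@dataclass
class MixingParams:
    """Constants of the Thorpe method.

    gamma : mixing efficiency (flux Richardson number correction), 0.2.
    ozmidov_ratio : assumed Ozmidov/Thorpe length ratio ``a``, 0.8.
    noise_threshold : minimum density range (kg m^-3) an overturning
        patch must span to be distinguished from sensor noise.
    min_patch_samples : minimum samples per accepted patch.
    background_kz : diffusivity floor (m^2 s^-1) assigned to bins with
        no detected overturn, so geometric averaging stays defined.
    despike_window / despike_factor : a sample further than
        despike_factor * noise_threshold from the running window median
        is treated as a spike and dropped.
    n2_method : 'endpoint' (sorted-profile endpoint difference) or
        'fit' (least-squares slope of the sorted profile).
    """

    gamma: float = 0.2
    ozmidov_ratio: float = 0.8
    noise_threshold: float = 0.002
    min_patch_samples: int = 3
    background_kz: float = 1e-6
    g: float = 9.81
    rho0: float = 1025.0
    despike_window: int = 5
    despike_factor: float = 10.0
    n2_method: str = "endpoint"

    def __post_init__(self) -> None:
        for name in ("gamma", "ozmidov_ratio", "noise_threshold", "background_kz",
                     "g", "rho0", "despike_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MixingParams.{name} must be strictly positive")
        if self.min_patch_samples < 1:
            raise ValueError("min_patch_samples must be >= 1")
        if self.n2_method not in ("endpoint", "fit"):
            raise ValueError("n2_method must be 'endpoint' or 'fit'")


@dataclass
class DiffusivityProfile:
    """Geometric-mean K_z on uniform depth bins, with cast counts."""

    depth_bins: np.ndarray  # bin centres, m
    kz_geomean: np.ndarray  # m^2 s^-1
    n_casts: np.ndarray


def preprocess_profile(raw: DensityProfile, params: MixingParams,
                       bin_size: float | None = None) -> DensityProfile:
    """Clean a raw cast: drop pressure reversals and density spikes.

    Samples whose depth does not exceed the previously kept depth
    (package reversals during the down-cast) are dropped; samples whose
    sigma deviates from the window median by more than
    ``despike_factor * noise_threshold`` are dropped; optionally the
    result is block-averaged onto a uniform grid of ``bin_size`` m.
    """
    depth = np.asarray(raw.depth, dtype=float)
    sigma = np.asarray(raw.sigma, dtype=float)

    # monotonic depth: keep a sample only if deeper than the last kept one
    keep = np.zeros(depth.size, dtype=bool)
    last = -np.inf
    for i, z in enumerate(depth):
        if z > last:
            keep[i] = True
            last = z
    depth, sigma = depth[keep], sigma[keep]

    # despike against a running window median
    if depth.size >= 3:
        w = max(3, params.despike_window)
        half = w // 2
        med = np.empty_like(sigma)
        for i in range(sigma.size):
            lo, hi = max(0, i - half), min(sigma.size, i + half + 1)
            med[i] = np.median(sigma[lo:hi])
        good = np.abs(sigma - med) <= params.despike_factor * params.noise_threshold
        depth, sigma = depth[good], sigma[good]

    if bin_size is not None and depth.size >= 3:
        edges = np.arange(math.floor(depth.min()), depth.max() + bin_size, bin_size)
        idx = np.digitize(depth, edges) - 1
        zc, sc = [], []
        for b in range(edges.size - 1):
            m = idx == b
            if m.any():
                zc.append(depth[m].mean())
                sc.append(sigma[m].mean())
        depth, sigma = np.array(zc), np.array(sc)

    if depth.size < 3:
        raise DegenerateProfileError(
            f"cast {raw.cast_id}: fewer than 3 valid samples after cleaning"
        )
    return DensityProfile(raw.cast_id, raw.time, depth, sigma)


def thorpe_displacements(p: DensityProfile) -> DisplacementProfile:
    """Thorpe displacement of every sample.

    A stable (mergesort) ascending sort of sigma assigns each sample a
    stable position; the displacement is the depth at that position
    minus the sample's original depth, so equal densities displace by
    zero and displacements over the full profile sum to zero.
    """
    order = np.argsort(p.sigma, kind="stable")
    disp = np.empty_like(p.depth)
    # sample order[j] lands at position j
    disp[order] = p.depth - p.depth[order]
    return DisplacementProfile(depth=p.depth.copy(), displacement=disp)


def _patch_spans(displacement: np.ndarray, tol: float = 1e-9) -> list[tuple[int, int]]:
    """Maximal index spans where the running displacement sum departs
    from zero and returns to zero (inclusive of the closing sample)."""
    csum = np.cumsum(displacement)
    spans: list[tuple[int, int]] = []
    start: int | None = None
    scale = max(1.0, float(np.max(np.abs(displacement), initial=0.0)))
    for i, c in enumerate(csum):
        nonzero = abs(c) > tol * scale
        if nonzero and start is None:
            start = i
        elif not nonzero and start is not None:
            spans.append((start, i))
            start = None
    if start is not None:  # unclosed at profile end; close at last sample
        spans.append((start, csum.size - 1))
    return spans


def detect_overturns(d: DisplacementProfile, p: DensityProfile,
                     params: MixingParams) -> list[OverturnSegment]:
    """Locate overturning patches and compute L_T, N, epsilon, K_z.

    Patches with density range below ``noise_threshold``, with fewer
    than ``min_patch_samples`` samples, or with non-positive stratification
    are rejected.
    """
    segments: list[OverturnSegment] = []
    sigma_sorted_full = np.sort(p.sigma, kind="stable")
    for i0, i1 in _patch_spans(d.displacement):
        n = i1 - i0 + 1
        if n < params.min_patch_samples:
            continue
        sig_patch = np.sort(p.sigma[i0:i1 + 1])
        if sig_patch[-1] - sig_patch[0] < params.noise_threshold:
            continue
        dz = p.depth[i1] - p.depth[i0]
        if dz <= 0:
            continue
        if params.n2_method == "endpoint":
            dsig_dz = (sig_patch[-1] - sig_patch[0]) / dz
        else:
            dsig_dz = np.polyfit(p.depth[i0:i1 + 1], sig_patch, 1)[0]
        n2 = (params.g / params.rho0) * dsig_dz
        if n2 <= 0:
            logger.warning(
                "cast %s: patch %.1f-%.1f m rejected (N^2 = %.3g <= 0)",
                p.cast_id, p.depth[i0], p.depth[i1], n2)
            continue
        disp = d.displacement[i0:i1 + 1]
        L_T = float(np.sqrt(np.mean(disp ** 2)))
        N = math.sqrt(n2)
        eps = (params.ozmidov_ratio * L_T) ** 2 * N ** 3
        kz = params.gamma * eps / n2
        segments.append(OverturnSegment(
            start_depth=float(p.depth[i0]), end_depth=float(p.depth[i1]),
            L_T=L_T, N=N, epsilon=eps, K_z=kz, n_samples=n,
            sum_abs_displacement=float(np.sum(np.abs(disp)))))
    del sigma_sorted_full
    return segments


def cast_kz_profile(segments: Sequence[OverturnSegment], depth_bins: np.ndarray,
                    params: MixingParams) -> np.ndarray:
    """Map patch diffusivities onto uniform depth bins.

    ``depth_bins`` are bin edges.  A bin overlapped by one or more
    patches gets the displacement-weighted mean of the overlapping patch
    K_z (weight = patch L_T times the overlap length); bins with no
    overturn get ``background_kz``.
    """
    edges = np.asarray(depth_bins, dtype=float)
    widths = np.diff(edges)
    if not np.allclose(widths, widths[0]):
        raise ValueError("depth_bins must be uniform")
    nbins = edges.size - 1
    kz = np.full(nbins, params.background_kz)
    for b in range(nbins):
        lo, hi = edges[b], edges[b + 1]
        wsum = 0.0
        acc = 0.0
        for seg in segments:
            ov = min(hi, seg.end_depth) - max(lo, seg.start_depth)
            if ov > 0:
                w = max(seg.L_T, 1e-12) * ov
                wsum += w
                acc += w * seg.K_z
        if wsum > 0:
            kz[b] = max(acc / wsum, params.background_kz)
    return kz


def average_kz(cast_profiles: Sequence[np.ndarray], depth_bins: np.ndarray) -> DiffusivityProfile:
    """Geometric mean of per-cast K_z profiles sharing ``depth_bins`` edges."""
    if len(cast_profiles) == 0:
        raise ValueError("average_kz requires at least one cast profile")
    arr = np.vstack([np.asarray(c, dtype=float) for c in cast_profiles])
    if np.any(arr <= 0):
        raise ValueError("K_z values must be positive for geometric averaging")
    valid = np.isfinite(arr)
    n_casts = valid.sum(axis=0)
    logs = np.where(valid, np.log(arr), 0.0)
    with np.errstate(invalid="ignore"):
        geo = np.exp(logs.sum(axis=0) / np.maximum(n_casts, 1))
    geo[n_casts == 0] = np.nan
    centres = 0.5 * (np.asarray(depth_bins)[:-1] + np.asarray(depth_bins)[1:])
    return DiffusivityProfile(depth_bins=centres, kz_geomean=geo, n_casts=n_casts)


def layer_geomean(profile: DiffusivityProfile, layer: tuple[float, float]) -> float:
    """Geometric-mean K_z over the bins whose centres fall in ``layer``."""
    lo, hi = layer
    m = (profile.depth_bins >= lo) & (profile.depth_bins <= hi) & np.isfinite(profile.kz_geomean)
    if not m.any():
        raise ValueError(f"no diffusivity bins inside layer {layer}")
    return float(np.exp(np.mean(np.log(profile.kz_geomean[m]))))
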