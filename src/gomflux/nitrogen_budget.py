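"""Euphotic-zone nitrogen budget synthesis.

Measured sinking-PON export is compared against the locally estimated
new-nitrogen sources (turbulent nitrate flux, N2-fixation, migrant
transport); the residual is the lateral organic-nitrogen supply the
budget requires.  Helper statistics: 15N tracer uptake rates, the
f-ratio (new / total production), and a two-endmember delta-15N mass
balance bounding the fixation share of export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NATURAL_15N_ATOM_PERCENT",
    "UptakeIncubation",
    "IsotopeEndmembers",
    "NitrogenBudget",
    "tracer_uptake_rate",
    "f_ratio",
    "isotope_fixation_fraction",
    "support_fractions",
    "assemble_budget",
    "mgC_to_umolN",
]

NATURAL_15N_ATOM_PERCENT = 0.3663
REDFIELD_N_PER_C = 16.0 / 106.0
MOLAR_MASS_C = 12.011  # g mol^-1


def mgC_to_umolN(mg_c: float) -> float:
    """Convert a carbon mass flux (mg C m^-2 d^-1) to nitrogen currency
    (umol N m^-2 d^-1) via Redfield 106:16."""
    return mg_c / MOLAR_MASS_C * 1000.0 * REDFIELD_N_PER_C


@dataclass
class UptakeIncubation:
    """End-point 15N tracer incubation."""

    pn: float                      # particulate N at end, umol m^-3
    atom_percent_final: float      # % 15N in PN at end
    atom_percent_enriched: float   # % 15N of labelled substrate pool
    atom_percent_natural: float = NATURAL_15N_ATOM_PERCENT
    duration: float = 1.0          # d

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.atom_percent_final < self.atom_percent_natural:
            raise ValueError("final atom% below natural abundance")


@dataclass
class IsotopeEndmembers:
    """delta-15N (permil) of the source and export pools."""

    delta_nitrate: float
    delta_fixation: float
    delta_export: float

    def __post_init__(self) -> None:
        if self.delta_nitrate == self.delta_fixation:
            raise ValueError("endmember delta-15N values must differ")


@dataclass
class NitrogenBudget:
    """Assembled source/sink table per euphotic-zone layer."""

    export_uez: float
    export_lez: float
    vertical_flux_uez: float
    vertical_flux_lez: float
    n2_fixation: float
    active_transport: float
    lateral_required_uez: float = 0.0
    lateral_required_lez: float = 0.0
    support_uez: dict = field(default_factory=dict)  # percent of export
    support_lez: dict = field(default_factory=dict)
    table: pd.DataFrame | None = None


def tracer_uptake_rate(inc: UptakeIncubation) -> float:
    """Nutrient uptake (umol N m^-3 d^-1) from an end-point 15N incubation."""
    denom = inc.atom_percent_enriched - inc.atom_percent_natural
    if denom <= 0:
        raise ValueError("enriched atom% must exceed natural abundance")
    return inc.pn * (inc.atom_percent_final - inc.atom_percent_natural) / denom \
        / inc.duration


def f_ratio(new_production: float, regenerated_production: float) -> float:
    """f = NP / (NP + RP), the new-production share of total production."""
    if new_production < 0 or regenerated_production < 0:
        raise ValueError("production terms must be non-negative")
    total = new_production + regenerated_production
    if total == 0:
        raise ValueError("f-ratio undefined when NP and RP are both zero")
    return new_production / total


def isotope_fixation_fraction(e: IsotopeEndmembers) -> tuple[float, float]:
    """Fixation share of export N from two-endmember delta-15N balance.

    f = (d15N_nitrate - d15N_export) / (d15N_nitrate - d15N_fixation),
    clipped to [0, 1].  Returns (clipped, raw) so out-of-range mixing
    signals stay visible as a diagnostic.
    """
    raw = (e.delta_nitrate - e.delta_export) / (e.delta_nitrate - e.delta_fixation)
    return float(np.clip(raw, 0.0, 1.0)), float(raw)


def support_fractions(export: float, sources: dict[str, float]) -> dict:
    """Percent of export each source can support, plus the lateral residual.

    lateral_required = max(0, export - sum(local sources)); its share of
    export closes the budget.
    """
    if export <= 0:
        raise ValueError("export must be positive")
    for name, v in sources.items():
        if v < 0:
            raise ValueError(f"source {name!r} must be non-negative")
    shares = {name: 100.0 * v / export for name, v in sources.items()}
    lateral_required = max(0.0, export - sum(sources.values()))
    shares["lateral"] = 100.0 * lateral_required / export
    return {"percent": shares, "lateral_required": lateral_required}


def assemble_budget(export_uez: float, export_lez: float,
                    vertical_flux_uez: float, vertical_flux_lez: float,
                    n2_fixation: float, active_transport: float) -> NitrogenBudget:
    """Collate the measured and computed terms into a per-layer budget.

    All terms in umol N m^-2 d^-1.  Exports and active transport are
    measured inputs; vertical fluxes and fixation are computed upstream.
    The UEZ receives fixation and the (negligible) UEZ vertical flux;
    the LEZ receives the LEZ-boundary vertical flux.  Active transport
    is a loss already realised below the euphotic zone, tabulated for
    context but not counted as a source.
    """
    for name, v in [("export_uez", export_uez), ("export_lez", export_lez)]:
        if v is None or v <= 0:
            raise ValueError(f"missing or non-positive required term {name}")
    for name, v in [("vertical_flux_uez", vertical_flux_uez),
                    ("vertical_flux_lez", vertical_flux_lez),
                    ("n2_fixation", n2_fixation),
                    ("active_transport", active_transport)]:
        if v is None or v < 0:
            raise ValueError(f"missing or negative term {name}")

    uez = support_fractions(export_uez, {"vertical": vertical_flux_uez,
                                         "fixation": n2_fixation})
    lez = support_fractions(export_lez, {"vertical": vertical_flux_lez,
                                         "fixation": n2_fixation})
    rows = [
        ("export_uez", export_uez, "measured"),
        ("export_lez", export_lez, "measured"),
        ("vertical_flux_uez", vertical_flux_uez, "computed"),
        ("vertical_flux_lez", vertical_flux_lez, "computed"),
        ("n2_fixation_uez", n2_fixation, "computed"),
        ("active_transport", active_transport, "computed"),
        ("lateral_required_uez", uez["lateral_required"], "computed"),
        ("lateral_required_lez", lez["lateral_required"], "computed"),
    ]
    table = pd.DataFrame(rows, columns=["term", "umolN_m2_d", "provenance"])
    return NitrogenBudget(
        export_uez=export_uez, export_lez=export_lez,
        vertical_flux_uez=vertical_flux_uez, vertical_flux_lez=vertical_flux_lez,
        n2_fixation=n2_fixation, active_transport=active_transport,
        lateral_required_uez=uez["lateral_required"],
        lateral_required_lez=lez["lateral_required"],
        support_uez=uez["percent"], support_lez=lez["percent"], table=table)
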