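"""Primitive accounting operations of the phosphorus budget.

Each function implements one budget rule on canonical units: pools in
g P m-2, fluxes in g P m-2 yr-1, tissue concentrations in mg P g-1, soil
concentrations in mg P kg-1, bulk density in g cm-3, depths in cm.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import DataError, DomainError

DAYS_PER_YEAR = 365.0


def plant_pool(concentration: float, biomass: float) -> float:
    """Tissue P pool from the concentration-by-biomass rule.

    g P m-2 = (mg P g-1) x (g m-2) / 1000.
    """
    if concentration < 0 or biomass < 0:
        raise DomainError("plant_pool requires non-negative concentration and biomass")
    return concentration * biomass / 1000.0


def soil_pool(
    concentration: float, bulk_density: float, layer: tuple[float, float]
) -> float:
    """Soil P pool for one depth layer.

    g P m-2 = (mg P kg-1) x (g cm-3) x thickness (cm) x 0.01.
    """
    top, bottom = layer
    if bottom <= top:
        raise DomainError(f"inverted depth layer ({top}, {bottom})")
    if concentration < 0 or bulk_density < 0:
        raise DomainError("soil_pool requires non-negative concentration and bulk density")
    return concentration * bulk_density * (bottom - top) * 0.01


def microbial_p(
    fumigated_extract: float, unfumigated_extract: float, kep: float = 0.4
) -> float:
    """Microbial biomass P from a chloroform-fumigation extract pair.

    The fumigation-induced increase in extractable P divided by the
    extraction-efficiency factor ``kep``.  A negative difference (fumigated
    below unfumigated, possible with noisy extracts) is clamped to zero with
    a warning.
    """
    if kep <= 0:
        raise DomainError("kep must be strictly positive")
    if fumigated_extract < 0 or unfumigated_extract < 0:
        raise DomainError("extract concentrations must be non-negative")
    diff = fumigated_extract - unfumigated_extract
    if diff < 0:
        warnings.warn("fumigated extract below unfumigated; clamping difference to 0")
        diff = 0.0
    return diff / kep


@dataclass(frozen=True)
class HedleyGroups:
    """Grouped sequential-extraction fractions (same units as the inputs)."""

    exchangeable_pi: float
    exchangeable_po: float
    moderately_labile_po: float
    residual: float
    flagged: bool  # True when the measured fractions exceeded total P

    def as_dict(self) -> dict[str, float]:
        return {
            "exchangeable_pi": self.exchangeable_pi,
            "exchangeable_po": self.exchangeable_po,
            "moderately_labile_po": self.moderately_labile_po,
            "residual": self.residual,
        }


def hedley_group(fractions: Mapping[str, float], total_p: float) -> HedleyGroups:
    """Group Hedley fractions, defining residual P by difference from total.

    ``fractions`` must provide ``exchangeable_pi``, ``exchangeable_po`` and
    ``moderately_labile_po``.  Residual = total - sum(fractions), floored at
    zero with a flag when the measured fractions overshoot the total.
    """
    if total_p < 0:
        raise DomainError("total P must be non-negative")
    required = ("exchangeable_pi", "exchangeable_po", "moderately_labile_po")
    missing = [k for k in required if k not in fractions]
    if missing:
        raise DataError(f"hedley_group missing fractions: {missing}")
    vals = {k: float(fractions[k]) for k in required}
    if any(v < 0 for v in vals.values()):
        raise DomainError("Hedley fractions must be non-negative")
    residual = total_p - sum(vals.values())
    flagged = residual < 0
    return HedleyGroups(
        exchangeable_pi=vals["exchangeable_pi"],
        exchangeable_po=vals["exchangeable_po"],
        moderately_labile_po=vals["moderately_labile_po"],
        residual=max(residual, 0.0),
        flagged=flagged,
    )


@dataclass(frozen=True)
class AnnualFlux:
    value: float  # g m-2 yr-1
    coverage: float  # fraction of the year covered by measurement intervals


def annualize(
    intervals: Iterable[tuple[_dt.date, _dt.date, float]],
) -> AnnualFlux:
    """Annual flux from dated measurement intervals.

    ``intervals`` are ``(start, end, value)`` with values in g m-2 per
    interval and ``end`` exclusive.  The interval sum is rescaled by
    365 / covered-days, which both fills incomplete coverage and normalizes
    leap years; the coverage fraction is reported alongside.  Overlapping
    intervals indicate double-counted collections and are rejected.
    """
    items = sorted(intervals, key=lambda iv: iv[0])
    if not items:
        raise DataError("annualize requires at least one interval")
    covered = 0
    prev_end: _dt.date | None = None
    total = 0.0
    for start, end, value in items:
        if end <= start:
            raise DataError(f"empty or inverted interval ({start}, {end})")
        if prev_end is not None and start < prev_end:
            raise DataError(f"overlapping flux intervals at {start}")
        covered += (end - start).days
        prev_end = end
        total += float(value)
    return AnnualFlux(value=total * DAYS_PER_YEAR / covered, coverage=covered / DAYS_PER_YEAR)


def canopy_production(litterfall_p: float, herbivory_p: float) -> float:
    """Canopy leaf P production: litter-trap flux plus the frass (herbivory)
    flux, since leaves eaten by insects never reach the traps."""
    if litterfall_p < 0 or herbivory_p < 0:
        raise DomainError("fluxes must be non-negative")
    return litterfall_p + herbivory_p


@dataclass(frozen=True)
class ResorptionFraction:
    fraction: float
    flagged: bool  # senesced tissue exceeded green tissue concentration


def resorption_fraction(green_conc: float, senesced_conc: float) -> ResorptionFraction:
    """Fractional P withdrawal before abscission: (green - senesced)/green,
    clamped to [0, 1] with a flag when senesced exceeds green."""
    if green_conc <= 0:
        raise DomainError("green-tissue concentration must be strictly positive")
    if senesced_conc < 0:
        raise DomainError("senesced-tissue concentration must be non-negative")
    frac = (green_conc - senesced_conc) / green_conc
    flagged = frac < 0
    return ResorptionFraction(fraction=min(max(frac, 0.0), 1.0), flagged=flagged)


def plant_demand(production_fluxes: Mapping[str, float]) -> float:
    """Annual plant P demand: the exact sum of all component production
    fluxes (canopy, wood, branch, bark, twig, reproduction, fine root,
    coarse root, understorey)."""
    if not production_fluxes:
        raise DataError("plant_demand requires at least one production flux")
    return float(sum(production_fluxes.values()))


def plant_uptake(demand: float, total_resorption: float) -> float:
    """Plant P uptake, defined by difference: demand minus resorption.

    A negative value (resorption exceeding demand) is retained but warned
    about, since it signals inconsistent inputs rather than a real flux.
    """
    if demand < 0 or total_resorption < 0:
        raise DomainError("demand and resorption must be non-negative")
    uptake = demand - total_resorption
    if uptake < 0:
        warnings.warn("resorption exceeds demand; negative uptake retained")
    return uptake


def profile_scale(surface_value: float, reference_profile: Sequence[float]) -> list[float]:
    """Extrapolate a surface-layer value down the profile.

    Layer i gets ``surface_value * w_i / w_0`` where ``w`` is a reference
    depth profile (e.g. soil C concentration); the surface layer passes
    through unchanged.
    """
    profile = list(reference_profile)
    if not profile:
        raise DomainError("reference profile must be non-empty")
    if profile[0] <= 0:
        raise DomainError("surface reference weight must be strictly positive")
    return [surface_value * w / profile[0] for w in profile]


def leaching_flux(phosphate_conc: float, drainage_ml_m2_d: float = 20.0) -> float:
    """Leaching below the rooting zone from lysimeter phosphate and an
    assumed drainage water efflux.

    g P m-2 yr-1 = (mg P L-1) x (mL m-2 d-1) x 365 x 1e-6.
    """
    if phosphate_conc < 0 or drainage_ml_m2_d < 0:
        raise DomainError("concentration and drainage must be non-negative")
    return phosphate_conc * drainage_ml_m2_d * DAYS_PER_YEAR * 1e-6


def mean_residence_time(pools: Mapping[str, float], uptake: float) -> float:
    """Mean residence time of P in plants (years): the standing vegetation
    pool - canopy, sapwood, fine root and understorey, excluding heartwood
    and coarse root - over the annual uptake flux."""
    if uptake <= 0:
        raise DomainError("mean residence time undefined for non-positive uptake")
    required = ("canopy", "sapwood", "fine_root", "understorey")
    missing = [k for k in required if k not in pools]
    if missing:
        raise DataError(f"mean_residence_time missing pools: {missing}")
    return sum(float(pools[k]) for k in required) / uptake


@dataclass(frozen=True)
class PUseEfficiencies:
    """Phosphorus-use efficiencies (g C per g P)."""

    pue_gpp_overstorey: float
    pue_gpp_understorey: float
    pue_gpp_total: float
    pue_growth: float


def p_use_efficiencies(
    gpp_overstorey: float,
    gpp_understorey: float,
    npp_total: float,
    canopy_leaf_production_p: float,
    understorey_leaf_production_p: float,
    uptake: float,
) -> PUseEfficiencies:
    """P-use efficiencies: GPP per unit leaf P production (overstorey and
    understorey separately and combined) and NPP per unit plant P uptake."""
    if canopy_leaf_production_p <= 0 or understorey_leaf_production_p <= 0:
        raise DomainError("leaf P production fluxes must be strictly positive")
    if uptake <= 0:
        raise DomainError("uptake must be strictly positive")
    return PUseEfficiencies(
        pue_gpp_overstorey=gpp_overstorey / canopy_leaf_production_p,
        pue_gpp_understorey=gpp_understorey / understorey_leaf_production_p,
        pue_gpp_total=(gpp_overstorey + gpp_understorey)
        / (canopy_leaf_production_p + understorey_leaf_production_p),
        pue_growth=npp_total / uptake,
    )
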