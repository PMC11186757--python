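"""Per-plot phosphorus budget from reduced plot-level inputs.

``compute_budget`` is the single locus of the accounting rules: the synthetic
generator's closed-form truth and the measurement-table pipeline both call it,
the former with configured parameter means, the latter with plot-level means
reduced from raw records.  Every budget identity (demand = sum of production;
uptake = demand - resorption; layer additivity; organic + inorganic = total)
therefore holds by construction on both paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from . import core
from .config import AccountingConstants
from .errors import DataError

#: vegetation components contributing a production flux to plant P demand
PRODUCTION_COMPONENTS = (
    "canopy",
    "wood",
    "branch",
    "bark",
    "twig",
    "reproduction",
    "fine_root",
    "coarse_root",
    "understorey",
)

#: production components with no resorption pathway (shed with full P load)
NON_RESORBING = ("branch", "bark", "twig", "reproduction")

PLANT_POOL_COMPONENTS = (
    "canopy",
    "sapwood",
    "heartwood",
    "fine_root",
    "coarse_root",
    "understorey",
    "forest_floor_litter",
    "standing_dead",
)

WOODY_POOL_COMPONENTS = ("sapwood", "heartwood", "coarse_root", "standing_dead")
FAST_POOL_COMPONENTS = ("canopy", "understorey", "fine_root")


def layer_label(layer: tuple[int, int]) -> str:
    return f"{layer[0]}-{layer[1]}"


@dataclass
class SoilLayerInputs:
    """Reduced soil chemistry for one depth layer (concentrations mg P kg-1,
    soil C g kg-1, bulk density g cm-3)."""

    total_p: float
    inorganic_p: float
    labile_p: float
    microbial_p: float
    soil_c: float
    bulk_density: float


@dataclass
class PlotInputs:
    """Plot-level means feeding the budget.

    ``conc`` keys: canopy_green, canopy_senesced, understorey_green,
    understorey_senesced, sapwood, heartwood, fine_root (mg P g-1).
    ``standing`` keys: canopy, understorey, sapwood, heartwood, fine_root,
    coarse_root, forest_floor_litter, standing_dead (g m-2).
    ``production_mass`` keys: wood, coarse_root, fine_root, understorey
    (g m-2 yr-1); ``litter_mass`` keys: canopy_leaf, branch, bark, twig,
    reproduction (annualized, g m-2 yr-1).
    """

    plot_id: str
    treatment: str
    layers: list[tuple[int, int]]
    conc: dict[str, float]
    standing: dict[str, float]
    production_mass: dict[str, float]
    litter_mass: dict[str, float]
    frass_mass: float
    frass_conc: float
    soil: list[SoilLayerInputs]
    hedley: dict[str, float]
    net_min_surface: float
    lysimeter_conc: float
    gpp_overstorey: float
    gpp_understorey: float
    npp_total: float
    deposition: float = 0.002
    drainage_ml_m2_d: float = 20.0


@dataclass
class PlotBudget:
    """All named pools (g P m-2), fluxes (g P m-2 yr-1) and derived
    indicators for one plot, with data-quality flag counts."""

    plot_id: str
    treatment: str
    values: dict[str, float]
    flags: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def resorption_fluxes(
    production_p: Mapping[str, float],
    conc: Mapping[str, float],
    fine_root_coefficient: float = 0.5,
) -> tuple[dict[str, float], dict[str, float], int]:
    """Per-component resorption fluxes from tissue-concentration contrasts.

    Canopy and understorey use the green-vs-senesced leaf fraction applied to
    their production fluxes; wood uses the sapwood-vs-heartwood fraction;
    coarse root reuses the sapwood fraction; fine root uses a fixed
    coefficient (live/dead separation is impractical).  Returns (fluxes,
    fractions, n_clamped).
    """
    required = ("canopy_green", "canopy_senesced", "understorey_green",
                "understorey_senesced", "sapwood", "heartwood")
    missing = [k for k in required if k not in conc]
    if missing:
        raise DataError(f"resorption_fluxes missing concentrations: {missing}")
    clamped = 0
    fracs: dict[str, float] = {}
    for comp, green, sen in (
        ("canopy", "canopy_green", "canopy_senesced"),
        ("understorey", "understorey_green", "understorey_senesced"),
        ("sapwood", "sapwood", "heartwood"),
    ):
        rf = core.resorption_fraction(conc[green], conc[sen])
        fracs[comp] = rf.fraction
        clamped += int(rf.flagged)
    fracs["fine_root"] = fine_root_coefficient
    fluxes = {
        "canopy": fracs["canopy"] * production_p["canopy"],
        "understorey": fracs["understorey"] * production_p["understorey"],
        "sapwood": fracs["sapwood"] * production_p["wood"],
        "coarse_root": fracs["sapwood"] * production_p["coarse_root"],
        "fine_root": fracs["fine_root"] * production_p["fine_root"],
    }
    return fluxes, fracs, clamped


def compute_budget(
    inputs: PlotInputs, constants: AccountingConstants | None = None
) -> PlotBudget:
    """Evaluate every pool, flux and derived indicator for one plot."""
    constants = constants or AccountingConstants()
    v: dict[str, float] = {}
    flags: dict[str, int] = {"resorption_clamped": 0, "negative_uptake": 0,
                             "hedley_floored": 0, "negative_organic": 0}
    conc = inputs.conc

    # ---- vegetation pools ------------------------------------------------
    v["pool:canopy"] = core.plant_pool(conc["canopy_green"], inputs.standing["canopy"])
    v["pool:sapwood"] = core.plant_pool(conc["sapwood"], inputs.standing["sapwood"])
    v["pool:heartwood"] = core.plant_pool(conc["heartwood"], inputs.standing["heartwood"])
    v["pool:fine_root"] = core.plant_pool(conc["fine_root"], inputs.standing["fine_root"])
    v["pool:coarse_root"] = core.plant_pool(conc["sapwood"], inputs.standing["coarse_root"])
    v["pool:understorey"] = core.plant_pool(
        conc["understorey_green"], inputs.standing["understorey"]
    )
    v["pool:forest_floor_litter"] = core.plant_pool(
        conc["canopy_senesced"], inputs.standing["forest_floor_litter"]
    )
    # standing dead wood shares the live sapwood/heartwood partitioning
    sap_b, heart_b = inputs.standing["sapwood"], inputs.standing["heartwood"]
    f_sap = sap_b / (sap_b + heart_b)
    dead_conc = f_sap * conc["sapwood"] + (1.0 - f_sap) * conc["heartwood"]
    v["pool:standing_dead"] = core.plant_pool(dead_conc, inputs.standing["standing_dead"])
    v["pool:plant_total"] = sum(v[f"pool:{c}"] for c in PLANT_POOL_COMPONENTS)

    # ---- soil pools ------------------------------------------------------
    for i, (layer, soil) in enumerate(zip(inputs.layers, inputs.soil)):
        lab = layer_label(layer)
        bd = soil.bulk_density
        v[f"pool:soil_total:{lab}"] = core.soil_pool(soil.total_p, bd, layer)
        v[f"pool:soil_inorganic:{lab}"] = core.soil_pool(soil.inorganic_p, bd, layer)
        # organic P is defined by difference; with noisy extracts it can go
        # negative, which is flagged but retained so the total identity holds
        organic = v[f"pool:soil_total:{lab}"] - v[f"pool:soil_inorganic:{lab}"]
        flags["negative_organic"] += int(organic < 0)
        v[f"pool:soil_organic:{lab}"] = organic
        v[f"pool:soil_microbial:{lab}"] = core.soil_pool(soil.microbial_p, bd, layer)
        v[f"pool:soil_labile:{lab}"] = core.soil_pool(soil.labile_p, bd, layer)
    for name in ("soil_total", "soil_inorganic", "soil_organic", "soil_microbial",
                 "soil_labile"):
        v[f"pool:{name}"] = sum(
            v[f"pool:{name}:{layer_label(layer)}"] for layer in inputs.layers
        )
    v["pool:soil_organic_residual"] = v["pool:soil_organic"] - v["pool:soil_microbial"]
    v["pool:soil_inorganic_residual"] = v["pool:soil_inorganic"] - v["pool:soil_labile"]

    # Hedley groups, surface layer only
    surface = inputs.layers[0]
    groups = core.hedley_group(inputs.hedley, inputs.soil[0].total_p)
    flags["hedley_floored"] += int(groups.flagged)
    bd0 = inputs.soil[0].bulk_density
    for name, value in groups.as_dict().items():
        v[f"pool:hedley_{name}:{layer_label(surface)}"] = core.soil_pool(
            value, bd0, surface
        )

    # ---- production fluxes ----------------------------------------------
    frass_p = core.plant_pool(inputs.frass_conc, inputs.frass_mass)
    v["flux:frass"] = frass_p
    production: dict[str, float] = {}
    canopy_litter_p = core.plant_pool(
        conc["canopy_green"], inputs.litter_mass["canopy_leaf"]
    )
    production["canopy"] = core.canopy_production(canopy_litter_p, frass_p)
    for comp, key in (("branch", "branch"), ("bark", "bark"), ("twig", "twig"),
                      ("reproduction", "reproduction")):
        production[comp] = core.plant_pool(conc["sapwood"], inputs.litter_mass[key])
    production["wood"] = core.plant_pool(conc["sapwood"], inputs.production_mass["wood"])
    production["coarse_root"] = core.plant_pool(
        conc["sapwood"], inputs.production_mass["coarse_root"]
    )
    production["fine_root"] = core.plant_pool(
        conc["fine_root"], inputs.production_mass["fine_root"]
    )
    production["understorey"] = core.plant_pool(
        conc["understorey_green"], inputs.production_mass["understorey"]
    )
    for comp in PRODUCTION_COMPONENTS:
        v[f"flux:production:{comp}"] = production[comp]

    # litter P returns (senesced-tissue concentrations)
    v["flux:litter:canopy"] = core.plant_pool(
        conc["canopy_senesced"], inputs.litter_mass["canopy_leaf"]
    )
    v["flux:litter:understorey"] = core.plant_pool(
        conc["understorey_senesced"], inputs.production_mass["understorey"]
    )

    # ---- resorption, demand, uptake --------------------------------------
    res_fluxes, res_fracs, clamped = resorption_fluxes(
        production, conc, constants.fine_root_resorption
    )
    flags["resorption_clamped"] += clamped
    for comp, flux in res_fluxes.items():
        v[f"flux:resorption:{comp}"] = flux
    for comp, frac in res_fracs.items():
        v[f"derived:resorption_fraction:{comp}"] = frac
    v["flux:resorption:total"] = sum(res_fluxes.values())
    v["flux:demand"] = core.plant_demand(production)
    uptake = core.plant_uptake(v["flux:demand"], v["flux:resorption:total"])
    flags["negative_uptake"] += int(uptake < 0)
    v["flux:uptake"] = uptake

    # ---- soil fluxes -----------------------------------------------------
    weights = [soil.soil_c for soil in inputs.soil]
    per_layer = core.profile_scale(inputs.net_min_surface, weights)
    for layer, flux in zip(inputs.layers, per_layer):
        v[f"flux:net_mineralization:{layer_label(layer)}"] = flux
    v["flux:net_mineralization:total"] = sum(per_layer)
    v["flux:leaching"] = core.leaching_flux(
        inputs.lysimeter_conc, inputs.drainage_ml_m2_d
    )
    v["flux:deposition"] = inputs.deposition

    # ---- derived indicators ---------------------------------------------
    v["derived:mrt"] = core.mean_residence_time(
        {
            "canopy": v["pool:canopy"],
            "sapwood": v["pool:sapwood"],
            "fine_root": v["pool:fine_root"],
            "understorey": v["pool:understorey"],
        },
        uptake,
    )
    pue = core.p_use_efficiencies(
        inputs.gpp_overstorey,
        inputs.gpp_understorey,
        inputs.npp_total,
        production["canopy"],
        production["understorey"],
        uptake,
    )
    v["derived:pue_gpp_overstorey"] = pue.pue_gpp_overstorey
    v["derived:pue_gpp_understorey"] = pue.pue_gpp_understorey
    v["derived:pue_gpp_total"] = pue.pue_gpp_total
    v["derived:pue_growth"] = pue.pue_growth
    cfrac = constants.carbon_fraction * 1000.0  # g C per g tissue -> per mg P scale
    for comp, key in (("canopy", "canopy_green"), ("understorey", "understorey_green"),
                      ("sapwood", "sapwood"), ("heartwood", "heartwood"),
                      ("fine_root", "fine_root")):
        v[f"derived:cp_ratio:{comp}"] = cfrac / conc[key]

    # share indicators (percent)
    v["derived:resorption_share_pct"] = 100.0 * v["flux:resorption:total"] / v["flux:demand"]
    v["derived:woody_share_pct"] = (
        100.0 * sum(v[f"pool:{c}"] for c in WOODY_POOL_COMPONENTS) / v["pool:plant_total"]
    )
    v["derived:litter_share_pct"] = (
        100.0 * v["pool:forest_floor_litter"] / v["pool:plant_total"]
    )
    v["derived:fast_share_pct"] = (
        100.0 * sum(v[f"pool:{c}"] for c in FAST_POOL_COMPONENTS) / v["pool:plant_total"]
    )
    v["derived:microbial_share_organic_pct"] = (
        100.0 * v["pool:soil_microbial"] / v["pool:soil_organic"]
    )
    v["derived:labile_share_soil_pct"] = 100.0 * v["pool:soil_labile"] / v["pool:soil_total"]
    v["derived:microbial_to_plant_ratio"] = v["pool:soil_microbial"] / v["pool:plant_total"]

    return PlotBudget(
        plot_id=inputs.plot_id, treatment=inputs.treatment, values=v, flags=flags
    )
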