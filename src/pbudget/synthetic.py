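"""Synthetic measurement-table generator for the FACE phosphorus budget.

Emulates the statistical structure of the field campaign - 2 CO2 treatments x
3 plots, 8 litter traps and 4 soil subplots per plot, monthly litterfall,
quarterly soil sampling in the first three years plus one deep-profile
campaign late in the experiment - without any mechanistic P-cycle dynamics.

Noise model: each plot draws one multiplicative factor per underlying
parameter (between-plot CV as configured); each raw record draws a further
factor at ``subreplicate_cv_ratio`` times the plot CV.  Factors are
zero-truncated normal (or mean-preserving lognormal) around 1.  Elevated-CO2
expectations equal ambient expectations times the configured multipliers.

Determinism: plot factors come from one substream keyed ``[seed, 0]`` and are
drawn in a fixed parameter order; each table's record noise comes from its own
substream ``[seed, table_index]``, so generating a subset of tables never
shifts another table's draws.
"""

from __future__ import annotations

import calendar
import datetime as dt
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from . import units
from .budget import PlotBudget, PlotInputs, SoilLayerInputs, compute_budget
from .config import (
    AMBIENT,
    ELEVATED,
    LOGNORMAL,
    TREATMENTS,
    TRUNCATED_NORMAL,
    ParamSpec,
    SiteConfig,
)
from .errors import ConfigurationError

TABLE_NAMES = (
    "tissue_concentration",
    "biomass",
    "litterfall",
    "frass",
    "soil_chemistry",
    "fumigation_pairs",
    "incubation_pairs",
    "lysimeter",
    "bulk_density",
    "carbon_fluxes",
)

#: alias -> canonical budget-variable key for co2_multipliers
_MULTIPLIER_ALIASES = {
    "uptake": "flux:uptake",
    "demand": "flux:demand",
    "net_mineralization": "flux:net_mineralization:total",
    "microbial_p": "pool:soil_microbial",
    "labile_p": "pool:soil_labile",
    "frass": "flux:frass",
    "leaching": "flux:leaching",
}


# ---------------------------------------------------------------------------
# parameter paths
# ---------------------------------------------------------------------------

def iter_params(config: SiteConfig) -> dict[str, ParamSpec]:
    """Flat, ordered map of every plot-level parameter in the configuration.

    The iteration order is the canonical draw order for plot factors.
    """
    params: dict[str, ParamSpec] = {}
    comp = config.component_params
    params["conc:canopy_green"] = comp["canopy"].concentration
    params["conc:canopy_senesced"] = comp["canopy"].senesced_concentration
    params["conc:understorey_green"] = comp["understorey"].concentration
    params["conc:understorey_senesced"] = comp["understorey"].senesced_concentration
    params["conc:sapwood"] = comp["sapwood"].concentration
    params["conc:heartwood"] = comp["heartwood"].concentration
    params["conc:fine_root"] = comp["fine_root"].concentration
    for name in ("canopy", "understorey", "sapwood", "heartwood", "fine_root",
                 "coarse_root", "forest_floor_litter", "standing_dead"):
        params[f"standing:{name}"] = comp[name].standing_biomass
    params["prodmass:wood"] = comp["sapwood"].production_mass
    params["prodmass:coarse_root"] = comp["coarse_root"].production_mass
    params["prodmass:fine_root"] = comp["fine_root"].production_mass
    params["prodmass:understorey"] = comp["understorey"].production_mass
    for name, spec in config.litterfall_params.items():
        params[f"litter:{name}"] = spec
    params["frass_mass"] = config.frass_mass
    params["frass_conc"] = config.frass_concentration
    for i, layer in enumerate(config.soil_params):
        params[f"soil:{i}:total_p"] = layer.total_p
        params[f"soil:{i}:inorganic_p"] = layer.inorganic_p
        params[f"soil:{i}:labile_p"] = layer.labile_p
        params[f"soil:{i}:microbial_p"] = layer.microbial_p
        params[f"soil:{i}:soil_c"] = layer.soil_c
        params[f"soil:{i}:bulk_density"] = layer.bulk_density
    params["hedley:exchangeable_pi"] = config.hedley_params.exchangeable_pi
    params["hedley:exchangeable_po"] = config.hedley_params.exchangeable_po
    params["hedley:moderately_labile_po"] = config.hedley_params.moderately_labile_po
    params["netmin_surface"] = config.soil_flux_params.net_mineralization_surface
    params["lysimeter"] = config.soil_flux_params.lysimeter_p
    params["carbon:gpp_overstorey"] = config.carbon_params.gpp_overstorey
    params["carbon:gpp_understorey"] = config.carbon_params.gpp_understorey
    params["carbon:npp_total"] = config.carbon_params.npp_total
    missing = [k for k, v in params.items() if v is None]
    if missing:
        raise ConfigurationError(f"component_params incomplete: missing {missing}")
    return params


def build_inputs(
    config: SiteConfig,
    value_of: Callable[[str], float],
    plot_id: str = "truth",
    treatment: str = AMBIENT,
) -> PlotInputs:
    """Assemble ``PlotInputs`` from realized parameter values.

    ``value_of(path)`` returns the realized plot-level value for a parameter
    path from :func:`iter_params`.
    """
    conc = {
        key.split(":", 1)[1]: value_of(key)
        for key in (
            "conc:canopy_green", "conc:canopy_senesced", "conc:understorey_green",
            "conc:understorey_senesced", "conc:sapwood", "conc:heartwood",
            "conc:fine_root",
        )
    }
    standing = {
        name: value_of(f"standing:{name}")
        for name in ("canopy", "understorey", "sapwood", "heartwood", "fine_root",
                     "coarse_root", "forest_floor_litter", "standing_dead")
    }
    production_mass = {
        name: value_of(f"prodmass:{name}")
        for name in ("wood", "coarse_root", "fine_root", "understorey")
    }
    litter_mass = {
        name: value_of(f"litter:{name}") for name in config.litterfall_params
    }
    soil = [
        SoilLayerInputs(
            total_p=value_of(f"soil:{i}:total_p"),
            inorganic_p=value_of(f"soil:{i}:inorganic_p"),
            labile_p=value_of(f"soil:{i}:labile_p"),
            microbial_p=value_of(f"soil:{i}:microbial_p"),
            soil_c=value_of(f"soil:{i}:soil_c"),
            bulk_density=value_of(f"soil:{i}:bulk_density"),
        )
        for i in range(len(config.depth_layers))
    ]
    hedley = {
        name: value_of(f"hedley:{name}")
        for name in ("exchangeable_pi", "exchangeable_po", "moderately_labile_po")
    }
    return PlotInputs(
        plot_id=plot_id,
        treatment=treatment,
        layers=list(config.depth_layers),
        conc=conc,
        standing=standing,
        production_mass=production_mass,
        litter_mass=litter_mass,
        frass_mass=value_of("frass_mass"),
        frass_conc=value_of("frass_conc"),
        soil=soil,
        hedley=hedley,
        net_min_surface=value_of("netmin_surface"),
        lysimeter_conc=value_of("lysimeter"),
        gpp_overstorey=value_of("carbon:gpp_overstorey"),
        gpp_understorey=value_of("carbon:gpp_understorey"),
        npp_total=value_of("carbon:npp_total"),
        deposition=config.soil_flux_params.deposition,
        drainage_ml_m2_d=config.soil_flux_params.drainage_ml_m2_d,
    )


# ---------------------------------------------------------------------------
# treatment multipliers
# ---------------------------------------------------------------------------

def _scale_param(spec: ParamSpec, factor: float) -> ParamSpec:
    return ParamSpec(mean=spec.mean * factor, cv=spec.cv)


def effective_config(config: SiteConfig, treatment: str) -> SiteConfig:
    """Configuration with CO2 multipliers folded into the parameter means.

    Multipliers act on the primitive parameter streams that linearly determine
    the targeted budget variable, so mass-balance identities survive: an
    ``uptake`` multiplier scales the non-resorbing production components
    (branch, bark, twig, reproduction), which feed uptake one-for-one, and
    plant demand absorbs the identity residual; a ``demand`` multiplier scales
    every production stream (so resorption and uptake scale with it).  When
    both are given, ``demand`` is applied first and ``uptake`` takes
    precedence for its own value.
    """
    if treatment not in TREATMENTS:
        raise ConfigurationError(f"unknown treatment {treatment!r}")
    if treatment == AMBIENT or not config.co2_multipliers:
        return config
    eff = config.model_copy(deep=True)
    mults = {
        _MULTIPLIER_ALIASES.get(k, k): v for k, v in config.co2_multipliers.items()
    }
    comp = eff.component_params

    def scale_production(factor: float, components: tuple[str, ...] | None = None):
        for name in list(eff.litterfall_params):
            if components is None or name in components:
                eff.litterfall_params[name] = _scale_param(
                    eff.litterfall_params[name], factor
                )
        if components is None:
            eff.frass_mass = _scale_param(eff.frass_mass, factor)
            comp["sapwood"].production_mass = _scale_param(
                comp["sapwood"].production_mass, factor
            )
            for name in ("coarse_root", "fine_root", "understorey"):
                comp[name].production_mass = _scale_param(
                    comp[name].production_mass, factor
                )

    ambient_truth = truth(config, AMBIENT)

    handled: set[str] = set()
    if "flux:demand" in mults:
        scale_production(mults["flux:demand"])
        handled.add("flux:demand")
    if "flux:uptake" in mults:
        current = compute_budget(build_inputs(eff, _mean_of(eff))).values
        target = mults["flux:uptake"] * ambient_truth["flux:uptake"]
        non_resorbing = sum(
            current[f"flux:production:{c}"] for c in ("branch", "bark", "twig",
                                                      "reproduction")
        )
        if non_resorbing <= 0:
            raise ConfigurationError(
                "co2_multipliers['uptake'] requires non-zero branch/bark/twig/"
                "reproduction production to act on"
            )
        factor = 1.0 + (target - current["flux:uptake"]) / non_resorbing
        if factor <= 0:
            raise ConfigurationError("co2_multipliers['uptake'] too small to realize")
        scale_production(factor, components=("branch", "bark", "twig", "reproduction"))
        handled.add("flux:uptake")

    for key, mult in mults.items():
        if key in handled:
            continue
        if key == "flux:net_mineralization:total":
            eff.soil_flux_params.net_mineralization_surface = _scale_param(
                eff.soil_flux_params.net_mineralization_surface, mult
            )
        elif key == "pool:soil_microbial":
            for layer in eff.soil_params:
                layer.microbial_p = _scale_param(layer.microbial_p, mult)
        elif key == "pool:soil_labile":
            for layer in eff.soil_params:
                layer.labile_p = _scale_param(layer.labile_p, mult)
        elif key == "flux:frass":
            eff.frass_mass = _scale_param(eff.frass_mass, mult)
        elif key == "flux:leaching":
            eff.soil_flux_params.lysimeter_p = _scale_param(
                eff.soil_flux_params.lysimeter_p, mult
            )
        elif key.startswith("pool:") and key.split(":", 1)[1] in comp:
            name = key.split(":", 1)[1]
            comp[name].standing_biomass = _scale_param(
                comp[name].standing_biomass, mult
            )
        elif key.startswith("conc:"):
            name = key.split(":", 1)[1]
            if name not in comp or comp[name].concentration is None:
                raise ConfigurationError(f"co2_multipliers: unknown tissue {key!r}")
            comp[name].concentration = _scale_param(comp[name].concentration, mult)
        elif key.startswith("carbon:"):
            name = key.split(":", 1)[1]
            cp = eff.carbon_params
            if not hasattr(cp, name):
                raise ConfigurationError(f"co2_multipliers: unknown carbon flux {key!r}")
            setattr(cp, name, _scale_param(getattr(cp, name), mult))
        else:
            raise ConfigurationError(
                f"co2_multipliers: {key!r} is not a generatable variable"
            )
    return eff


def _mean_of(config: SiteConfig) -> Callable[[str], float]:
    params = iter_params(config)
    return lambda path: params[path].mean


def truth(config: SiteConfig, treatment: str = AMBIENT) -> dict[str, float]:
    """Noise-free expected budget for one treatment (the generator's ground
    truth), computed in closed form through the same accounting rules as the
    pipeline.  Obeys every budget identity by construction."""
    eff = effective_config(config, treatment)
    budget = compute_budget(
        build_inputs(eff, _mean_of(eff), plot_id="truth", treatment=treatment)
    )
    return budget.values


def fig_effect_preset() -> dict[str, float]:
    """Multiplier preset mirroring the reported relative CO2 responses of the
    recycling fluxes (+6% plant P demand, +8% plant P uptake)."""
    return {"demand": 1.06, "uptake": 1.08}


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def _factors(
    rng: np.random.Generator, cv: float, size: int, model: str
) -> np.ndarray:
    """Multiplicative noise factors with mean ~ 1 and sd ~ cv, positive."""
    if cv <= 0:
        return np.ones(size)
    if model == TRUNCATED_NORMAL:
        return stats.truncnorm.rvs(
            a=-1.0 / cv, b=np.inf, loc=1.0, scale=cv, size=size, random_state=rng
        )
    if model == LOGNORMAL:
        s = np.sqrt(np.log1p(cv * cv))
        return np.exp(rng.normal(-0.5 * s * s, s, size=size))
    raise ConfigurationError(f"unknown noise_model {model!r}")


class _PlotEffects:
    """Per-plot multiplicative factors for every parameter path, drawn once
    from the dedicated substream in canonical order."""

    def __init__(self, config: SiteConfig, seed: int):
        rng = np.random.default_rng([seed, 0])
        self.plots: dict[str, list[str]] = {
            AMBIENT: [f"A{i+1}" for i in range(config.n_plots_per_treatment)],
            ELEVATED: [f"E{i+1}" for i in range(config.n_plots_per_treatment)],
        }
        self.configs = {t: effective_config(config, t) for t in TREATMENTS}
        self.params = {t: iter_params(self.configs[t]) for t in TREATMENTS}
        n = config.n_plots_per_treatment
        self.factors: dict[tuple[str, str], np.ndarray] = {}
        for treatment in TREATMENTS:
            for path, spec in self.params[treatment].items():
                self.factors[(treatment, path)] = _factors(
                    rng, spec.cv, n, config.noise_model
                )

    def plot_value(self, treatment: str, plot_index: int, path: str) -> float:
        spec = self.params[treatment][path]
        return spec.mean * self.factors[(treatment, path)][plot_index]

    def record_cv(self, config: SiteConfig, treatment: str, path: str) -> float:
        return self.params[treatment][path].cv * config.subreplicate_cv_ratio


# ---------------------------------------------------------------------------
# date layouts
# ---------------------------------------------------------------------------

def _month_ends(years: list[int]) -> list[dt.date]:
    return [
        dt.date(y, m, calendar.monthrange(y, m)[1]) for y in years for m in range(1, 13)
    ]


def _quarter_dates(years: list[int]) -> list[dt.date]:
    return [dt.date(y, m, 15) for y in years for m in (2, 5, 8, 11)]


def _quarter_ends(years: list[int]) -> list[dt.date]:
    return [
        dt.date(y, m, calendar.monthrange(y, m)[1]) for y in years for m in (3, 6, 9, 12)
    ]


class _Design:
    """Campaign calendar derived from the configured years, mirroring the
    field design: monthly litter traps throughout; quarterly surface soil
    sampling in the first three years; one deep-profile campaign in the
    second-to-last year; fumigation in years 2-3; lysimeters in years 1-4."""

    def __init__(self, config: SiteConfig):
        years = config.years
        n = len(years)
        self.years = years
        self.quarter_years = years[: min(3, n)]
        self.fum_years = years[1:3] if n >= 3 else years[: min(2, n)]
        self.deep_year = years[-2] if n >= 2 else years[-1]
        self.lys_years = years[: min(4, n)]
        self.frass_years = years[: min(2, n)]
        self.under_prod_years = years[1:5] if n >= 2 else years
        self.first_year = years[0]


# ---------------------------------------------------------------------------
# table generation
# ---------------------------------------------------------------------------

def _rows(
    plot_id, treatment, date, component, depth, subrep, variable, value, unit
) -> dict:
    top, bottom = depth if depth is not None else (np.nan, np.nan)
    return {
        "plot_id": plot_id,
        "treatment": treatment,
        "date": date.isoformat() if isinstance(date, dt.date) else date,
        "component": component,
        "depth_top_cm": top,
        "depth_bottom_cm": bottom,
        "subrep": subrep,
        "variable": variable,
        "value": value,
        "unit": unit,
    }


def generate_measurements(
    config: SiteConfig, seed: int | None = None
) -> dict[str, pd.DataFrame]:
    """Generate the full set of raw measurement tables.

    Returns one long-format DataFrame per table (see ``TABLE_NAMES``), with
    the fixed column order of ``units.COLUMNS``.  Identical ``(config, seed)``
    yields bit-identical output.
    """
    seed = config.seed if seed is None else seed
    effects = _PlotEffects(config, seed)
    design = _Design(config)
    tables: dict[str, pd.DataFrame] = {}
    builders = {
        "tissue_concentration": _gen_tissue,
        "biomass": _gen_biomass,
        "litterfall": _gen_litterfall,
        "frass": _gen_frass,
        "soil_chemistry": _gen_soil_chemistry,
        "fumigation_pairs": _gen_fumigation,
        "incubation_pairs": _gen_incubation,
        "lysimeter": _gen_lysimeter,
        "bulk_density": _gen_bulk_density,
        "carbon_fluxes": _gen_carbon,
    }
    for idx, name in enumerate(TABLE_NAMES, start=1):
        rng = np.random.default_rng([seed, idx])
        rows = builders[name](config, effects, design, rng)
        frame = pd.DataFrame(rows, columns=units.COLUMNS)
        tables[name] = frame
    return tables


def _each_plot(effects: _PlotEffects):
    for treatment in TREATMENTS:
        for i, plot_id in enumerate(effects.plots[treatment]):
            yield treatment, i, plot_id


def _noisy(
    effects: _PlotEffects,
    config: SiteConfig,
    rng: np.random.Generator,
    treatment: str,
    plot_index: int,
    path: str,
    n: int,
) -> np.ndarray:
    base = effects.plot_value(treatment, plot_index, path)
    cv = effects.record_cv(config, treatment, path)
    return base * _factors(rng, cv, n, config.noise_model)


def _gen_tissue(config, effects, design, rng):
    rows = []
    canopy_green_dates = [dt.date(y, m, 15) for y in design.years for m in (2, 5, 10)]
    canopy_sen_dates = [dt.date(y, 2, 15) for y in design.years]
    under_green_dates = [dt.date(y, 3, 15) for y in design.years[::2][:3]]
    under_sen_dates = [dt.date(design.deep_year, 6, 15)]
    wood_year = design.years[min(2, len(design.years) - 1)]
    wood_dates = [dt.date(wood_year, 11, 15)]
    fine_dates = _quarter_dates(design.quarter_years)
    layout = [
        ("canopy_green", canopy_green_dates, 3),
        ("canopy_senesced", canopy_sen_dates, 3),
        ("understorey_green", under_green_dates, 2),
        ("understorey_senesced", under_sen_dates, 2),
        ("sapwood", wood_dates, 3),
        ("heartwood", wood_dates, 3),
        ("fine_root", fine_dates, 4),
    ]
    for treatment, i, plot_id in _each_plot(effects):
        for component, dates, n_sub in layout:
            n = len(dates) * n_sub
            values = _noisy(effects, config, rng, treatment, i, f"conc:{component}", n)
            k = 0
            for date in dates:
                for sub in range(1, n_sub + 1):
                    rows.append(
                        _rows(plot_id, treatment, date, component, None, sub,
                              "p_concentration", values[k], units.MG_P_PER_G)
                    )
                    k += 1
    return rows


def _gen_biomass(config, effects, design, rng):
    rows = []
    standing_comps = ("canopy", "understorey", "sapwood", "heartwood", "fine_root",
                      "coarse_root", "forest_floor_litter", "standing_dead")
    prod_layout = [
        ("wood", "prodmass:wood", design.years, 1),
        ("coarse_root", "prodmass:coarse_root", design.years, 1),
        ("fine_root", "prodmass:fine_root", design.years, 4),
        ("understorey", "prodmass:understorey", design.under_prod_years, 1),
    ]
    for treatment, i, plot_id in _each_plot(effects):
        for comp in standing_comps:
            values = _noisy(
                effects, config, rng, treatment, i, f"standing:{comp}",
                len(design.years),
            )
            for year, value in zip(design.years, values):
                rows.append(
                    _rows(plot_id, treatment, dt.date(year, 7, 1), comp, None, 0,
                          "standing_biomass", value, units.G_PER_M2)
                )
        for comp, path, years, n_sub in prod_layout:
            values = _noisy(effects, config, rng, treatment, i, path,
                            len(years) * n_sub)
            k = 0
            for year in years:
                for sub in range(n_sub):
                    rows.append(
                        _rows(plot_id, treatment, dt.date(year, 12, 31), comp, None,
                              sub, "production_mass", values[k],
                              units.G_PER_M2_PER_INTERVAL)
                    )
                    k += 1
    return rows


def _gen_litterfall(config, effects, design, rng):
    rows = []
    dates = _month_ends(design.years)
    days = np.array([
        calendar.monthrange(d.year, d.month)[1] for d in dates
    ], dtype=float)
    traps = range(1, config.n_litter_traps + 1)
    for treatment, i, plot_id in _each_plot(effects):
        for comp in config.litterfall_params:
            annual = effects.plot_value(treatment, i, f"litter:{comp}")
            cv = effects.record_cv(config, treatment, f"litter:{comp}")
            noise = _factors(rng, cv, len(dates) * len(traps), config.noise_model)
            k = 0
            for d, nd in zip(dates, days):
                monthly = annual * nd / 365.0
                for trap in traps:
                    rows.append(
                        _rows(plot_id, treatment, d, comp, None, trap, "litter_mass",
                              monthly * noise[k], units.G_PER_M2_PER_INTERVAL)
                    )
                    k += 1
    return rows


def _gen_frass(config, effects, design, rng):
    rows = []
    dates = _month_ends(design.frass_years)
    days = np.array([calendar.monthrange(d.year, d.month)[1] for d in dates],
                    dtype=float)
    traps = range(1, config.n_litter_traps + 1)
    for treatment, i, plot_id in _each_plot(effects):
        annual = effects.plot_value(treatment, i, "frass_mass")
        cv = effects.record_cv(config, treatment, "frass_mass")
        noise = _factors(rng, cv, len(dates) * len(traps), config.noise_model)
        k = 0
        for d, nd in zip(dates, days):
            monthly = annual * nd / 365.0
            for trap in traps:
                rows.append(
                    _rows(plot_id, treatment, d, "frass", None, trap, "frass_mass",
                          monthly * noise[k], units.G_PER_M2_PER_INTERVAL)
                )
                k += 1
        concs = _noisy(effects, config, rng, treatment, i, "frass_conc", len(dates))
        for d, c in zip(dates, concs):
            rows.append(
                _rows(plot_id, treatment, d, "frass", None, 0, "p_concentration",
                      c, units.MG_P_PER_G)
            )
    return rows


def _gen_soil_chemistry(config, effects, design, rng):
    rows = []
    layers = config.depth_layers
    surface_dates = _quarter_dates(design.quarter_years)
    deep_date = dt.date(design.deep_year, 9, 15)
    mid_date = dt.date(design.first_year, 8, 15)
    subs = range(1, config.n_soil_subplots + 1)

    def emit(treatment, i, plot_id, date, layer_idx, variable, path, unit):
        values = _noisy(effects, config, rng, treatment, i, path, len(list(subs)))
        for sub, value in zip(subs, values):
            rows.append(
                _rows(plot_id, treatment, date, "soil", layers[layer_idx], sub,
                      variable, value, unit)
            )

    for treatment, i, plot_id in _each_plot(effects):
        # quarterly surface chemistry
        for date in surface_dates:
            for variable in ("total_p", "inorganic_p", "labile_p"):
                emit(treatment, i, plot_id, date, 0, variable,
                     f"soil:0:{variable}", units.MG_P_PER_KG)
        # one early mid-layer campaign
        if len(layers) > 1:
            for variable in ("total_p", "inorganic_p"):
                emit(treatment, i, plot_id, mid_date, 1, variable,
                     f"soil:1:{variable}", units.MG_P_PER_KG)
        # deep-profile campaign: full chemistry plus soil C at every layer
        for li in range(len(layers)):
            for variable in ("total_p", "inorganic_p", "labile_p"):
                emit(treatment, i, plot_id, deep_date, li, variable,
                     f"soil:{li}:{variable}", units.MG_P_PER_KG)
            emit(treatment, i, plot_id, deep_date, li, "soil_c",
                 f"soil:{li}:soil_c", units.G_C_PER_KG)
        # Hedley sequential fractions, surface layer, first year
        for variable in ("exchangeable_pi", "exchangeable_po",
                         "moderately_labile_po"):
            emit(treatment, i, plot_id, mid_date, 0, f"hedley_{variable}",
                 f"hedley:{variable}", units.MG_P_PER_KG)
    return rows


def _gen_fumigation(config, effects, design, rng):
    rows = []
    layers = config.depth_layers
    dates = _quarter_dates(design.fum_years)
    deep_date = dt.date(design.deep_year, 9, 15)
    subs = range(1, config.n_soil_subplots + 1)
    kep = config.constants.kep
    for treatment, i, plot_id in _each_plot(effects):
        campaigns = [(d, 0) for d in dates] + [(deep_date, li) for li in
                                               range(len(layers))]
        for date, li in campaigns:
            unfum = _noisy(effects, config, rng, treatment, i,
                           f"soil:{li}:labile_p", len(list(subs)))
            gap = kep * _noisy(effects, config, rng, treatment, i,
                               f"soil:{li}:microbial_p", len(list(subs)))
            for sub, u, g in zip(subs, unfum, gap):
                rows.append(
                    _rows(plot_id, treatment, date, "soil", layers[li], sub,
                          "unfumigated_p", u, units.MG_P_PER_KG)
                )
                rows.append(
                    _rows(plot_id, treatment, date, "soil", layers[li], sub,
                          "fumigated_p", u + g, units.MG_P_PER_KG)
                )
    return rows


def _gen_incubation(config, effects, design, rng):
    """In-situ net-mineralization incubations: quarterly phosphate pairs in
    the surface layer.  The configured annual rate (g P m-2 yr-1) is encoded
    as a concentration change over each quarter using the true surface bulk
    density, so the pipeline's concentration x bulk-density x depth conversion
    recovers the rate."""
    rows = []
    layer = config.depth_layers[0]
    thickness = layer[1] - layer[0]
    bd = config.soil_params[0].bulk_density.mean
    dates = _quarter_ends(design.quarter_years)
    subs = range(1, config.n_soil_subplots + 1)
    for treatment, i, plot_id in _each_plot(effects):
        rate = effects.plot_value(treatment, i, "netmin_surface")
        cv = effects.record_cv(config, treatment, "netmin_surface")
        for date in dates:
            q_start = dt.date(date.year, date.month - 2, 1)
            days = (date - q_start).days + 1
            flux_q = rate * days / 365.0
            delta = flux_q / (bd * thickness * 0.01)
            initial = _noisy(effects, config, rng, treatment, i,
                             "soil:0:labile_p", len(list(subs)))
            deltas = delta * _factors(rng, cv, len(list(subs)), config.noise_model)
            for sub, ini, dlt in zip(subs, initial, deltas):
                rows.append(
                    _rows(plot_id, treatment, date, "soil", layer, sub,
                          "phosphate_initial", ini, units.MG_P_PER_KG)
                )
                rows.append(
                    _rows(plot_id, treatment, date, "soil", layer, sub,
                          "phosphate_final", ini + dlt, units.MG_P_PER_KG)
                )
    return rows


def _gen_lysimeter(config, effects, design, rng):
    rows = []
    dates = _month_ends(design.lys_years)
    for treatment, i, plot_id in _each_plot(effects):
        values = _noisy(effects, config, rng, treatment, i, "lysimeter",
                        len(dates) * 2)
        k = 0
        for date in dates:
            for sub in (1, 2):
                rows.append(
                    _rows(plot_id, treatment, date, "soil_water", (35, 75), sub,
                          "phosphate_p", values[k], units.MG_P_PER_L)
                )
                k += 1
    return rows


def _gen_bulk_density(config, effects, design, rng):
    rows = []
    date = dt.date(design.first_year, 8, 1)
    for treatment, i, plot_id in _each_plot(effects):
        for li, layer in enumerate(config.depth_layers):
            values = _noisy(effects, config, rng, treatment, i,
                            f"soil:{li}:bulk_density", 2)
            for sub, value in zip((1, 2), values):
                rows.append(
                    _rows(plot_id, treatment, date, "soil", layer, sub,
                          "bulk_density", value, units.G_PER_CM3)
                )
    return rows


def _gen_carbon(config, effects, design, rng):
    rows = []
    for treatment, i, plot_id in _each_plot(effects):
        for variable in ("gpp_overstorey", "gpp_understorey", "npp_total"):
            values = _noisy(effects, config, rng, treatment, i,
                            f"carbon:{variable}", len(design.years))
            for year, value in zip(design.years, values):
                rows.append(
                    _rows(plot_id, treatment, dt.date(year, 12, 31), "", None, 0,
                          variable, value, units.G_C_PER_M2_PER_YR)
                )
    return rows


# ---------------------------------------------------------------------------
# plot-level sampling (coverage / calibration harness)
# ---------------------------------------------------------------------------

def sample_plot_budgets(
    config: SiteConfig,
    treatment: str,
    n_plots: int,
    rng: np.random.Generator,
) -> list[PlotBudget]:
    """Draw ``n_plots`` independent plot-level budgets from the generator's
    between-plot distribution (plot factors only, no sub-replicate noise or
    table plumbing).  Used by the coverage and null-calibration harnesses,
    where thousands of synthetic experiments are needed."""
    eff = effective_config(config, treatment)
    params = iter_params(eff)
    factors = {
        path: _factors(rng, spec.cv, n_plots, config.noise_model)
        for path, spec in params.items()
    }
    budgets = []
    for j in range(n_plots):
        value_of = lambda path, _j=j: params[path].mean * factors[path][_j]
        budgets.append(
            compute_budget(
                build_inputs(eff, value_of, plot_id=f"{treatment[0].upper()}{j+1}",
                             treatment=treatment)
            )
        )
    return budgets


def sample_plot_values(
    config: SiteConfig,
    treatment: str,
    variable: str,
    n_plots: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Plot-level values of one budget variable (see sample_plot_budgets)."""
    return np.array(
        [b[variable] for b in sample_plot_budgets(config, treatment, n_plots, rng)]
    )
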