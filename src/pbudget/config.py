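"""Site configuration for the synthetic FACE experiment.

The configuration fully parameterizes a two-treatment (ambient vs elevated CO2)
forest site: experimental design (plots, sub-replicates, years, soil depth
layers), the plot-level means and coefficients of variation of every measured
quantity, multiplicative CO2 treatment effects, and the noise model.

``default_config`` is calibrated so that the generator's closed-form expected
budget reproduces the ambient phosphorus pools and fluxes of a mature,
P-limited *Eucalyptus* woodland: a soil P pool of 31.8 g P m-2 over the top
60 cm (25.1 organic + 6.7 inorganic), a microbial P pool of 5.97 g P m-2,
labile P of 1.15 g P m-2, a plant-and-litter pool of 1.61 g P m-2, an annual
plant P demand of 0.71 g P m-2 yr-1 met by 0.32 resorption and 0.39 uptake,
and a net P-mineralization flux of 0.67 g P m-2 yr-1.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigurationError

TRUNCATED_NORMAL = "truncated-normal"
LOGNORMAL = "lognormal"

AMBIENT = "ambient"
ELEVATED = "elevated"
TREATMENTS = (AMBIENT, ELEVATED)


class ParamSpec(BaseModel):
    """A plot-level quantity: mean and between-plot coefficient of variation."""

    mean: float = Field(ge=0)
    cv: float = Field(default=0.0, ge=0, lt=1)

    model_config = {"frozen": True}


class ComponentParams(BaseModel):
    """Concentration / mass parameters for one vegetation component.

    ``concentration`` is the live-tissue P concentration (mg P g-1);
    ``senesced_concentration`` applies to leaf components only.  Biomass is
    the standing stock (g m-2), ``production_mass`` the annual biomass
    production rate (g m-2 yr-1) where production is measured directly rather
    than through litter traps.
    """

    concentration: Optional[ParamSpec] = None
    senesced_concentration: Optional[ParamSpec] = None
    standing_biomass: Optional[ParamSpec] = None
    production_mass: Optional[ParamSpec] = None


class LayerParams(BaseModel):
    """Soil chemistry for one depth layer (concentrations in mg P kg-1)."""

    total_p: ParamSpec
    inorganic_p: ParamSpec
    labile_p: ParamSpec
    microbial_p: ParamSpec
    soil_c: ParamSpec  # g C kg-1; sets the depth profile of net mineralization
    bulk_density: ParamSpec  # g cm-3


class HedleyParams(BaseModel):
    """Sequential-extraction fractions for the surface layer (mg P kg-1).

    The residual fraction is never configured: it is defined as total P minus
    the sum of the measured fractions.
    """

    exchangeable_pi: ParamSpec
    exchangeable_po: ParamSpec
    moderately_labile_po: ParamSpec


class CarbonParams(BaseModel):
    """Per-plot carbon fluxes (g C m-2 yr-1), inputs to P-use efficiencies."""

    gpp_overstorey: ParamSpec
    gpp_understorey: ParamSpec
    npp_total: ParamSpec


class SoilFluxParams(BaseModel):
    net_mineralization_surface: ParamSpec  # g P m-2 yr-1 in the 0-10 cm layer
    lysimeter_p: ParamSpec  # phosphate in deep soil water, mg P L-1
    drainage_ml_m2_d: float = Field(default=20.0, gt=0)
    deposition: float = Field(default=0.002, ge=0)  # g P m-2 yr-1, constant


class AccountingConstants(BaseModel):
    """Fixed coefficients of the budget accounting rules."""

    kep: float = Field(default=0.4, gt=0)  # fumigation-extraction efficiency
    fine_root_resorption: float = Field(default=0.5, ge=0, le=1)
    carbon_fraction: float = Field(default=0.48, gt=0)  # g C per g biomass


class SiteConfig(BaseModel):
    n_plots_per_treatment: int = Field(default=3, ge=1)
    years: list[int] = Field(default_factory=lambda: list(range(2013, 2019)))
    depth_layers: list[tuple[int, int]] = Field(
        default_factory=lambda: [(0, 10), (10, 30), (30, 60)]
    )
    n_litter_traps: int = Field(default=8, ge=1)
    n_soil_subplots: int = Field(default=4, ge=1)
    component_params: dict[str, ComponentParams]
    litterfall_params: dict[str, ParamSpec]
    frass_mass: ParamSpec
    frass_concentration: ParamSpec
    soil_params: list[LayerParams]
    hedley_params: HedleyParams
    carbon_params: CarbonParams
    soil_flux_params: SoilFluxParams
    constants: AccountingConstants = Field(default_factory=AccountingConstants)
    co2_multipliers: dict[str, float] = Field(default_factory=dict)
    noise_model: str = Field(default=TRUNCATED_NORMAL)
    subreplicate_cv_ratio: float = Field(default=0.5, ge=0)
    seed: int = 0

    @field_validator("noise_model")
    @classmethod
    def _check_noise_model(cls, v: str) -> str:
        if v not in (TRUNCATED_NORMAL, LOGNORMAL):
            raise ValueError(f"noise_model must be one of {TRUNCATED_NORMAL!r}, {LOGNORMAL!r}")
        return v

    @field_validator("co2_multipliers")
    @classmethod
    def _check_multipliers(cls, v: dict[str, float]) -> dict[str, float]:
        for key, mult in v.items():
            if not mult > 0:
                raise ValueError(f"co2_multipliers[{key!r}] must be strictly positive")
        return v

    @field_validator("years")
    @classmethod
    def _check_years(cls, v: list[int]) -> list[int]:
        if not v or sorted(v) != v or len(set(v)) != len(v):
            raise ValueError("years must be a non-empty strictly ascending list")
        return v

    @model_validator(mode="after")
    def _check_layers(self) -> "SiteConfig":
        layers = self.depth_layers
        if not layers:
            raise ValueError("depth_layers must be non-empty")
        for top, bottom in layers:
            if bottom <= top or top < 0:
                raise ValueError(f"depth_layers entry ({top}, {bottom}) is not ascending")
        for (_, b0), (t1, _) in zip(layers, layers[1:]):
            if t1 != b0:
                raise ValueError("depth_layers must be contiguous and non-overlapping")
        if len(self.soil_params) != len(layers):
            raise ValueError("soil_params must align with depth_layers")
        return self

    # -- convenience -------------------------------------------------------

    def with_cv_scale(self, factor: float) -> "SiteConfig":
        """Return a copy with every coefficient of variation multiplied by
        ``factor`` (``factor=0`` yields a noise-free site)."""

        def scale(spec: Optional[ParamSpec]) -> Optional[ParamSpec]:
            if spec is None:
                return None
            return ParamSpec(mean=spec.mean, cv=spec.cv * factor)

        data = self.model_copy(deep=True)
        for comp in data.component_params.values():
            comp.concentration = scale(comp.concentration)
            comp.senesced_concentration = scale(comp.senesced_concentration)
            comp.standing_biomass = scale(comp.standing_biomass)
            comp.production_mass = scale(comp.production_mass)
        data.litterfall_params = {k: scale(v) for k, v in data.litterfall_params.items()}
        data.frass_mass = scale(data.frass_mass)
        data.frass_concentration = scale(data.frass_concentration)
        for layer in data.soil_params:
            layer.total_p = scale(layer.total_p)
            layer.inorganic_p = scale(layer.inorganic_p)
            layer.labile_p = scale(layer.labile_p)
            layer.microbial_p = scale(layer.microbial_p)
            layer.soil_c = scale(layer.soil_c)
            layer.bulk_density = scale(layer.bulk_density)
        hp = data.hedley_params
        data.hedley_params = HedleyParams(
            exchangeable_pi=scale(hp.exchangeable_pi),
            exchangeable_po=scale(hp.exchangeable_po),
            moderately_labile_po=scale(hp.moderately_labile_po),
        )
        cp = data.carbon_params
        data.carbon_params = CarbonParams(
            gpp_overstorey=scale(cp.gpp_overstorey),
            gpp_understorey=scale(cp.gpp_understorey),
            npp_total=scale(cp.npp_total),
        )
        sf = data.soil_flux_params
        data.soil_flux_params = SoilFluxParams(
            net_mineralization_surface=scale(sf.net_mineralization_surface),
            lysimeter_p=scale(sf.lysimeter_p),
            drainage_ml_m2_d=sf.drainage_ml_m2_d,
            deposition=sf.deposition,
        )
        return data

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def load_config(path) -> SiteConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return SiteConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError names the field path
        raise ConfigurationError(str(exc)) from exc


def validate_config(raw: dict) -> SiteConfig:
    try:
        return SiteConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigurationError(str(exc)) from exc


def default_config(seed: int = 0) -> SiteConfig:
    """The calibrated synthetic site (see module docstring for targets).

    Between-plot CVs are back-computed from the reported treatment SD/mean
    ratios where available (e.g. total soil P 5.7/31.8 ~ 18%) and set to
    field-plausible values elsewhere.  The standing dead wood CV is capped at
    0.5 (its reported SD equals its mean, but the zero-truncated noise model
    is strongly biased at CV ~ 1).
    """
    p = ParamSpec
    components = {
        # canopy green 0.5 mg/g over 460 g/m2 -> pool 0.23; senesced 0.225
        # gives a 55% leaf resorption fraction.
        "canopy": ComponentParams(
            concentration=p(mean=0.5, cv=0.05),
            senesced_concentration=p(mean=0.225, cv=0.05),
            standing_biomass=p(mean=460.0, cv=0.07),
        ),
        # understorey senesced/green = 41/70 -> resorption fraction 29/70,
        # chosen so total plant resorption closes at 0.32 g P m-2 yr-1.
        "understorey": ComponentParams(
            concentration=p(mean=1.0, cv=0.08),
            senesced_concentration=p(mean=41.0 / 70.0, cv=0.08),
            standing_biomass=p(mean=230.0, cv=0.15),
            production_mass=p(mean=280.0, cv=0.12),
        ),
        "sapwood": ComponentParams(
            concentration=p(mean=0.08, cv=0.15),
            standing_biomass=p(mean=4500.0, cv=0.15),
            production_mass=p(mean=375.0, cv=0.30),  # annual wood increment
        ),
        "heartwood": ComponentParams(
            concentration=p(mean=0.04, cv=0.03),
            standing_biomass=p(mean=7500.0, cv=0.03),
        ),
        "fine_root": ComponentParams(
            concentration=p(mean=0.4, cv=0.08),
            standing_biomass=p(mean=600.0, cv=0.10),
            production_mass=p(mean=150.0, cv=0.15),
        ),
        # coarse root and the litter/dead pools carry no concentration of
        # their own: coarse root uses sapwood P, the forest floor uses the
        # senesced canopy P, standing dead wood uses the plot's sapwood/
        # heartwood partitioning.
        "coarse_root": ComponentParams(
            standing_biomass=p(mean=1875.0, cv=0.15),
            production_mass=p(mean=125.0, cv=0.30),
        ),
        "forest_floor_litter": ComponentParams(
            standing_biomass=p(mean=0.06 * 1000.0 / 0.225, cv=0.08),
        ),
        "standing_dead": ComponentParams(
            standing_biomass=p(mean=727.2727272727273, cv=0.5),
        ),
    }
    litterfall = {
        "canopy_leaf": p(mean=480.0, cv=0.10),
        "branch": p(mean=125.0, cv=0.20),
        "bark": p(mean=125.0, cv=0.20),
        "twig": p(mean=125.0, cv=0.20),
        "reproduction": p(mean=250.0, cv=0.30),
    }
    # Soil: organic P = total - inorganic; layer concentrations chosen so the
    # three-layer pools close at organic 25.1 / inorganic 6.7 / total 31.8,
    # microbial 5.97 and labile 1.15 g P m-2 with the bulk densities below.
    soil = [
        LayerParams(
            total_p=p(mean=90.0, cv=0.18),
            inorganic_p=p(mean=15.0, cv=0.17),
            labile_p=p(mean=5.0, cv=0.22),
            microbial_p=p(mean=25.0, cv=0.20),
            soil_c=p(mean=20.0, cv=0.15),
            bulk_density=p(mean=1.32, cv=0.05),
        ),
        LayerParams(
            total_p=p(mean=43.0, cv=0.18),
            inorganic_p=p(mean=8.0, cv=0.17),
            labile_p=p(mean=1.2, cv=0.22),
            microbial_p=p(mean=7.0, cv=0.20),
            soil_c=p(mean=9.0, cv=0.15),
            bulk_density=p(mean=1.45, cv=0.05),
        ),
        LayerParams(
            total_p=p(mean=5.05 / 0.48 + 5.0, cv=0.18),
            inorganic_p=p(mean=5.0, cv=0.17),
            labile_p=p(mean=0.142 / 0.48, cv=0.22),
            microbial_p=p(mean=4.0 / 3.0, cv=0.20),
            soil_c=p(mean=4.5, cv=0.15),
            bulk_density=p(mean=1.60, cv=0.05),
        ),
    ]
    hedley = HedleyParams(
        exchangeable_pi=p(mean=1.0, cv=0.20),
        exchangeable_po=p(mean=1.0, cv=0.20),
        moderately_labile_po=p(mean=15.0, cv=0.20),
    )
    carbon = CarbonParams(
        gpp_overstorey=p(mean=1500.0, cv=0.05),
        gpp_understorey=p(mean=380.0, cv=0.08),
        npp_total=p(mean=507.0, cv=0.07),
    )
    soil_flux = SoilFluxParams(
        net_mineralization_surface=p(mean=0.40, cv=0.20),
        lysimeter_p=p(mean=0.004, cv=0.30),
    )
    return SiteConfig(
        component_params=components,
        litterfall_params=litterfall,
        frass_mass=p(mean=40.0, cv=0.20),
        frass_concentration=p(mean=1.0, cv=0.10),
        soil_params=soil,
        hedley_params=hedley,
        carbon_params=carbon,
        soil_flux_params=soil_flux,
        seed=seed,
    )
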