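"""Reduce raw measurement tables to per-plot budgets and treatment summaries.

Aggregation follows the plot-then-treatment principle: sub-replicates are
averaged to a plot value per sampling date, repeated measurements are first
annualized (fluxes) or averaged within years (pools), multi-year values are
averaged per plot, and only then are treatment means and SDs computed with
n = number of plots.  Aggregated variables (totals) are summed within each
plot before the cross-plot SD is taken.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core
from .budget import PlotBudget, PlotInputs, SoilLayerInputs, compute_budget, layer_label
from .config import AccountingConstants
from .errors import DataError

REQUIRED_TABLES = (
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

REQUIRED_CONCENTRATIONS = (
    "canopy_green", "canopy_senesced", "understorey_green", "understorey_senesced",
    "sapwood", "heartwood", "fine_root",
)
REQUIRED_STANDING = (
    "canopy", "understorey", "sapwood", "heartwood", "fine_root", "coarse_root",
    "forest_floor_litter", "standing_dead",
)
REQUIRED_PRODUCTION = ("wood", "coarse_root", "fine_root", "understorey")
REQUIRED_LITTER = ("canopy_leaf", "branch", "bark", "twig", "reproduction")


@dataclass
class AssemblyOptions:
    """Accounting parameters of the reduction that are not measurements."""

    constants: AccountingConstants = field(default_factory=AccountingConstants)
    deposition: float = 0.002  # g P m-2 yr-1, atmospheric input
    drainage_ml_m2_d: float = 20.0


def _check_tables(tables: dict[str, pd.DataFrame]) -> None:
    missing = [name for name in REQUIRED_TABLES if name not in tables]
    if missing:
        raise DataError(f"missing measurement tables: {missing}")
    for name, frame in tables.items():
        for col in ("plot_id", "treatment", "date", "variable", "value"):
            if col not in frame.columns:
                raise DataError(f"table {name!r} lacks required column {col!r}")


def _plot_map(tables: dict[str, pd.DataFrame]) -> dict[str, str]:
    """plot_id -> treatment; errors if any plot appears under two treatments."""
    pairs = pd.concat(
        [t[["plot_id", "treatment"]] for t in tables.values()]
    ).drop_duplicates()
    dup = pairs["plot_id"].duplicated()
    if dup.any():
        raise DataError(
            f"plots assigned to multiple treatments: {sorted(pairs['plot_id'][dup])}"
        )
    return dict(zip(pairs["plot_id"], pairs["treatment"]))


def _date_mean(group: pd.DataFrame) -> float:
    """Sub-replicates -> date mean -> plot mean over dates."""
    return float(group.groupby("date")["value"].mean().mean())


def _month_interval(date: dt.date) -> tuple[dt.date, dt.date]:
    start = dt.date(date.year, date.month, 1)
    end = (dt.date(date.year + 1, 1, 1) if date.month == 12
           else dt.date(date.year, date.month + 1, 1))
    return start, end


def _quarter_interval(date: dt.date) -> tuple[dt.date, dt.date]:
    q_month = 3 * ((date.month - 1) // 3) + 1
    start = dt.date(date.year, q_month, 1)
    end = (dt.date(date.year + 1, 1, 1) if q_month == 10
           else dt.date(date.year, q_month + 3, 1))
    return start, end


def _annual_mean_flux(
    plot_frame: pd.DataFrame, interval_of, value_col: str = "value"
) -> float:
    """Mean annual flux: sub-replicate mean per date, annualize within each
    year from dated intervals, then average across years."""
    by_date = plot_frame.groupby("date")[value_col].mean()
    intervals = []
    for date_str, value in by_date.items():
        date = dt.date.fromisoformat(str(date_str)[:10])
        start, end = interval_of(date)
        intervals.append((start, end, float(value)))
    years = sorted({iv[0].year for iv in intervals})
    annuals = [
        core.annualize([iv for iv in intervals if iv[0].year == y]).value
        for y in years
    ]
    return float(np.mean(annuals))


def _layer_key(frame: pd.DataFrame) -> pd.Series:
    return (
        frame["depth_top_cm"].astype(float).astype(int).astype(str)
        + "-"
        + frame["depth_bottom_cm"].astype(float).astype(int).astype(str)
    )


def assemble_budgets(
    tables: dict[str, pd.DataFrame], options: AssemblyOptions | None = None
) -> list[PlotBudget]:
    """Compute one :class:`PlotBudget` per plot from raw measurement tables."""
    options = options or AssemblyOptions()
    _check_tables(tables)
    plot_map = _plot_map(tables)

    tissue = tables["tissue_concentration"]
    biomass = tables["biomass"]
    litterfall = tables["litterfall"]
    frass = tables["frass"]
    soil = tables["soil_chemistry"]
    fum = tables["fumigation_pairs"]
    inc = tables["incubation_pairs"]
    lys = tables["lysimeter"]
    bulk = tables["bulk_density"]
    carbon = tables["carbon_fluxes"]

    # depth layers from the soil table, ordered by top depth
    soil = soil.assign(_layer=_layer_key(soil))
    layer_labels = sorted(
        soil["_layer"].unique(), key=lambda s: int(s.split("-")[0])
    )
    layers = [tuple(int(x) for x in lab.split("-")) for lab in layer_labels]
    tops = [t for t, _ in layers]
    for (t0, b0), (t1, _) in zip(layers, layers[1:]):
        if t1 != b0:
            raise DataError(f"soil depth layers not contiguous: {layers}")
    surface = layer_labels[0]

    fum = fum.assign(_layer=_layer_key(fum))
    inc = inc.assign(_layer=_layer_key(inc))
    bulk = bulk.assign(_layer=_layer_key(bulk))

    budgets: list[PlotBudget] = []
    for plot_id in sorted(plot_map):
        treatment = plot_map[plot_id]
        flags: dict[str, int] = {"microbial_clamped": 0}

        # ---- tissue concentrations --------------------------------------
        t = tissue[tissue["plot_id"] == plot_id]
        conc = {
            comp: _date_mean(grp) for comp, grp in t.groupby("component")
        }
        missing = [c for c in REQUIRED_CONCENTRATIONS if c not in conc]
        if missing:
            raise DataError(f"plot {plot_id}: missing tissue concentrations {missing}")

        # ---- biomass -----------------------------------------------------
        b = biomass[biomass["plot_id"] == plot_id]
        standing = {
            comp: _date_mean(grp)
            for comp, grp in b[b["variable"] == "standing_biomass"].groupby("component")
        }
        production_mass = {
            comp: _date_mean(grp)
            for comp, grp in b[b["variable"] == "production_mass"].groupby("component")
        }
        for name, have, req in (
            ("standing biomass", standing, REQUIRED_STANDING),
            ("production mass", production_mass, REQUIRED_PRODUCTION),
        ):
            gap = [c for c in req if c not in have]
            if gap:
                raise DataError(f"plot {plot_id}: missing {name} for {gap}")

        # ---- litter and frass fluxes ------------------------------------
        lf = litterfall[litterfall["plot_id"] == plot_id]
        litter_mass = {}
        for comp, grp in lf.groupby("component"):
            litter_mass[comp] = _annual_mean_flux(grp, _month_interval)
        gap = [c for c in REQUIRED_LITTER if c not in litter_mass]
        if gap:
            raise DataError(f"plot {plot_id}: missing litterfall components {gap}")
        fr = frass[frass["plot_id"] == plot_id]
        frass_mass = _annual_mean_flux(
            fr[fr["variable"] == "frass_mass"], _month_interval
        )
        frass_conc = _date_mean(fr[fr["variable"] == "p_concentration"])

        # ---- soil chemistry ---------------------------------------------
        s = soil[soil["plot_id"] == plot_id]
        bd_plot = bulk[bulk["plot_id"] == plot_id]
        bd = {
            lab: _date_mean(grp) for lab, grp in
            bd_plot[bd_plot["variable"] == "bulk_density"].groupby("_layer")
        }
        gap = [lab for lab in layer_labels if lab not in bd]
        if gap:
            raise DataError(f"plot {plot_id}: missing bulk density for layers {gap}")

        def layer_mean(variable: str, lab: str) -> float:
            sel = s[(s["variable"] == variable) & (s["_layer"] == lab)]
            if sel.empty:
                raise DataError(
                    f"plot {plot_id}: no {variable!r} measurements in layer {lab}"
                )
            return _date_mean(sel)

        total = {lab: layer_mean("total_p", lab) for lab in layer_labels}
        inorganic = {lab: layer_mean("inorganic_p", lab) for lab in layer_labels}

        # labile P: multiyear surface mean, extrapolated down-profile with
        # the deep-campaign concentration ratios
        labile_surface = layer_mean("labile_p", surface)
        lab_rows = s[s["variable"] == "labile_p"]
        deep_rows = lab_rows[lab_rows["_layer"] != surface]
        if len(layer_labels) > 1:
            if deep_rows.empty:
                raise DataError(
                    f"plot {plot_id}: no deep-profile labile P campaign"
                )
            campaign_date = deep_rows["date"].max()
            campaign = lab_rows[lab_rows["date"] == campaign_date]
            weights = [
                float(campaign[campaign["_layer"] == lab]["value"].mean())
                for lab in layer_labels
            ]
            labile = dict(zip(layer_labels, core.profile_scale(labile_surface, weights)))
        else:
            labile = {surface: labile_surface}

        # microbial P from fumigation pairs, same down-profile treatment
        f = fum[fum["plot_id"] == plot_id]
        paired = f.pivot_table(
            index=["date", "_layer", "subrep"], columns="variable", values="value"
        ).reset_index()
        if not {"fumigated_p", "unfumigated_p"} <= set(paired.columns):
            raise DataError(f"plot {plot_id}: incomplete fumigation pairs")
        diff = paired["fumigated_p"] - paired["unfumigated_p"]
        flags["microbial_clamped"] += int((diff < 0).sum())
        paired["microbial"] = diff.clip(lower=0) / options.constants.kep
        micro_surface = _date_mean(
            paired[paired["_layer"] == surface].rename(columns={"microbial": "value"})
        )
        deep_micro = paired[paired["_layer"] != surface]
        if len(layer_labels) > 1:
            if deep_micro.empty:
                raise DataError(f"plot {plot_id}: no deep-profile fumigation campaign")
            campaign_date = deep_micro["date"].max()
            campaign = paired[paired["date"] == campaign_date]
            weights = [
                float(campaign[campaign["_layer"] == lab]["microbial"].mean())
                for lab in layer_labels
            ]
            microbial = dict(zip(layer_labels, core.profile_scale(micro_surface, weights)))
        else:
            microbial = {surface: micro_surface}

        soil_c = {lab: layer_mean("soil_c", lab) for lab in layer_labels}

        hed = {}
        for variable in ("hedley_exchangeable_pi", "hedley_exchangeable_po",
                         "hedley_moderately_labile_po"):
            sel = s[s["variable"] == variable]
            if sel.empty:
                raise DataError(f"plot {plot_id}: missing {variable} measurements")
            hed[variable.removeprefix("hedley_")] = _date_mean(sel)

        soil_inputs = [
            SoilLayerInputs(
                total_p=total[lab],
                inorganic_p=inorganic[lab],
                labile_p=labile[lab],
                microbial_p=microbial[lab],
                soil_c=soil_c[lab],
                bulk_density=bd[lab],
            )
            for lab in layer_labels
        ]

        # ---- net mineralization (surface incubations) --------------------
        ic = inc[(inc["plot_id"] == plot_id) & (inc["_layer"] == surface)]
        pairs = ic.pivot_table(
            index=["date", "subrep"], columns="variable", values="value"
        ).reset_index()
        if not {"phosphate_initial", "phosphate_final"} <= set(pairs.columns):
            raise DataError(f"plot {plot_id}: incomplete incubation pairs")
        thickness = layers[0][1] - layers[0][0]
        pairs["value"] = (
            (pairs["phosphate_final"] - pairs["phosphate_initial"])
            * bd[surface] * thickness * 0.01
        )
        net_min_surface = _annual_mean_flux(pairs, _quarter_interval)

        # ---- water and carbon -------------------------------------------
        lys_plot = lys[lys["plot_id"] == plot_id]
        lys_conc = _date_mean(lys_plot[lys_plot["variable"] == "phosphate_p"])
        cb = carbon[carbon["plot_id"] == plot_id]
        carbon_means = {
            var: _date_mean(grp) for var, grp in cb.groupby("variable")
        }
        gap = [v for v in ("gpp_overstorey", "gpp_understorey", "npp_total")
               if v not in carbon_means]
        if gap:
            raise DataError(f"plot {plot_id}: missing carbon fluxes {gap}")

        inputs = PlotInputs(
            plot_id=plot_id,
            treatment=treatment,
            layers=layers,
            conc=conc,
            standing=standing,
            production_mass=production_mass,
            litter_mass=litter_mass,
            frass_mass=frass_mass,
            frass_conc=frass_conc,
            soil=soil_inputs,
            hedley=hed,
            net_min_surface=net_min_surface,
            lysimeter_conc=lys_conc,
            gpp_overstorey=carbon_means["gpp_overstorey"],
            gpp_understorey=carbon_means["gpp_understorey"],
            npp_total=carbon_means["npp_total"],
            deposition=options.deposition,
            drainage_ml_m2_d=options.drainage_ml_m2_d,
        )
        budget = compute_budget(inputs, options.constants)
        budget.flags.update(flags)
        budgets.append(budget)
    return budgets


# ---------------------------------------------------------------------------
# aggregation and export
# ---------------------------------------------------------------------------

def unit_for(variable: str) -> str:
    if variable.startswith("pool:"):
        return "g_P_per_m2"
    if variable.startswith("flux:"):
        return "g_P_per_m2_per_yr"
    if variable == "derived:mrt":
        return "yr"
    if variable.startswith("derived:pue") or variable.startswith("derived:cp_ratio"):
        return "g_C_per_g_P"
    if variable.endswith("_pct"):
        return "percent"
    return "dimensionless"


def plot_budget_frame(budgets: list[PlotBudget]) -> pd.DataFrame:
    """Long per-plot export: plot, treatment, variable, value, unit."""
    rows = [
        {
            "plot_id": b.plot_id,
            "treatment": b.treatment,
            "variable": var,
            "value": value,
            "unit": unit_for(var),
        }
        for b in budgets
        for var, value in b.values.items()
    ]
    return pd.DataFrame(rows)


def aggregate(budgets: list[PlotBudget]) -> pd.DataFrame:
    """Treatment summaries: mean, SD and n (plots) per budget variable.

    Totals were already summed within each plot by ``compute_budget``, so the
    SD of an aggregated variable is the cross-plot SD of per-plot sums.
    """
    frame = plot_budget_frame(budgets)
    treatments = frame["treatment"].unique()
    if len(treatments) < 1:
        raise DataError("no treatments present")
    counts = frame.groupby("treatment")["plot_id"].nunique()
    low = counts[counts < 2]
    if not low.empty:
        raise DataError(
            f"need >= 2 plots per treatment for SDs; got {dict(low)}"
        )
    out = (
        frame.groupby(["variable", "treatment"])["value"]
        .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)), n="count")
        .reset_index()
    )
    out["unit"] = out["variable"].map(unit_for)
    return out


def summary_json(summary: pd.DataFrame) -> dict:
    """Nested mean +- SD mirror of the budget diagram, keyed by treatment."""
    result: dict = {}
    for (treatment, variable), grp in summary.groupby(["treatment", "variable"]):
        row = grp.iloc[0]
        section = ("pools" if variable.startswith("pool:")
                   else "fluxes" if variable.startswith("flux:") else "derived")
        result.setdefault(treatment, {}).setdefault(section, {})[variable] = {
            "mean": float(row["mean"]),
            "sd": float(row["sd"]),
            "n": int(row["n"]),
            "unit": row["unit"],
        }
    return result
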