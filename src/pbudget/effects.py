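"""CO2 effect-size machinery: pooled SD, t-based confidence intervals at
three confidence levels, relative effects, bootstrap resampling, and
simulation harnesses for interval coverage and null calibration.

The experimental unit is the plot (n = 3 per CO2 treatment in the reference
design).  The treatment effect on a variable is the difference of treatment
means (elevated minus ambient); its SD pools the two treatment SDs,

    SD_eff = sqrt((SD_amb^2 + SD_ele^2) / 2),

and the confidence interval at level L is

    CI_eff = t_L(n1 + n2 - 2) * SD_eff * sqrt(1/n1 + 1/n2)

with t_L the two-tailed critical value.  The bootstrap resamples values with
replacement within each treatment arm and takes percentile intervals of the
resampled effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .budget import PlotBudget
from .config import AMBIENT, ELEVATED, SiteConfig
from .errors import DataError, DomainError
from .synthetic import sample_plot_budgets, truth

DEFAULT_LEVELS = (75, 85, 95)


def pooled_sd(sd_amb: float, sd_ele: float) -> float:
    """Pooled effect SD of two equally weighted treatment SDs."""
    if sd_amb < 0 or sd_ele < 0:
        raise DomainError("standard deviations must be non-negative")
    return float(np.sqrt((sd_amb**2 + sd_ele**2) / 2.0))


@lru_cache(maxsize=256)
def _t_crit(level: float, df: int) -> float:
    return float(stats.t.ppf(0.5 + level / 200.0, df))


def ci_eff(sd_eff: float, n1: int, n2: int, level: float) -> float:
    """Half-width of the two-tailed t confidence interval for the treatment
    effect at ``level`` percent, with n1 + n2 - 2 degrees of freedom."""
    if not 0 < level < 100:
        raise DomainError("confidence level must be in (0, 100)")
    df = n1 + n2 - 2
    if df <= 0:
        raise DomainError("need n1 + n2 - 2 > 0 degrees of freedom")
    if sd_eff < 0:
        raise DomainError("sd_eff must be non-negative")
    return float(_t_crit(level, df) * sd_eff * np.sqrt(1.0 / n1 + 1.0 / n2))


@dataclass
class EffectEstimate:
    """Absolute and relative CO2 effect on one variable with t-based CIs."""

    variable: str
    n1: int
    n2: int
    ambient_mean: float
    elevated_mean: float
    delta: float
    sd_eff: float
    sem: float
    relative_pct: float
    ci: dict[int, tuple[float, float]] = field(default_factory=dict)

    def significant(self, level: int) -> bool:
        """True when the CI at ``level`` excludes zero."""
        lo, hi = self.ci[level]
        return lo > 0 or hi < 0


def effect_estimate(
    ambient: np.ndarray,
    elevated: np.ndarray,
    variable: str = "",
    levels: tuple[int, ...] = DEFAULT_LEVELS,
) -> EffectEstimate:
    """Treatment effect from plot-level values of the two arms."""
    amb = np.asarray(ambient, dtype=float)
    ele = np.asarray(elevated, dtype=float)
    if amb.size < 2 or ele.size < 2:
        raise DataError("need at least 2 plots per treatment arm")
    n1, n2 = amb.size, ele.size
    delta = float(ele.mean() - amb.mean())
    sd_eff = pooled_sd(float(amb.std(ddof=1)), float(ele.std(ddof=1)))
    sem = float(sd_eff * np.sqrt(1.0 / n1 + 1.0 / n2))
    rel = 100.0 * delta / amb.mean() if amb.mean() != 0 else float("nan")
    ci = {}
    for level in levels:
        half = ci_eff(sd_eff, n1, n2, level)
        ci[int(level)] = (delta - half, delta + half)
    return EffectEstimate(
        variable=variable, n1=n1, n2=n2,
        ambient_mean=float(amb.mean()), elevated_mean=float(ele.mean()),
        delta=delta, sd_eff=sd_eff, sem=sem, relative_pct=float(rel), ci=ci,
    )


@dataclass
class BootstrapResult:
    """Percentile bootstrap of the treatment effect.

    ``deltas`` holds the resampled effects (elevated-arm mean minus
    ambient-arm mean per resample).  The resampling unit is whatever the
    caller passes in - plot means for plot-level inference (the default in
    the pipeline), or raw records for a sensitivity analysis.
    """

    variable: str
    n_resamples: int
    seed: int
    delta_mean: float
    delta_sd: float
    ci: dict[int, tuple[float, float]]
    deltas: np.ndarray = field(repr=False, default=None)

    def significant(self, level: int) -> bool:
        lo, hi = self.ci[level]
        return lo > 0 or hi < 0


def bootstrap_effect(
    ambient: np.ndarray,
    elevated: np.ndarray,
    n_resamples: int = 1000,
    seed: int = 0,
    variable: str = "",
    levels: tuple[int, ...] = DEFAULT_LEVELS,
) -> BootstrapResult:
    """Resample each arm with replacement and recompute the effect."""
    amb = np.asarray(ambient, dtype=float)
    ele = np.asarray(elevated, dtype=float)
    if amb.size < 2 or ele.size < 2:
        raise DataError("need at least 2 records per treatment arm")
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, amb.size, size=(n_resamples, amb.size))
    idx_e = rng.integers(0, ele.size, size=(n_resamples, ele.size))
    deltas = ele[idx_e].mean(axis=1) - amb[idx_a].mean(axis=1)
    ci = {
        int(level): (
            float(np.percentile(deltas, (100 - level) / 2.0)),
            float(np.percentile(deltas, 100 - (100 - level) / 2.0)),
        )
        for level in levels
    }
    return BootstrapResult(
        variable=variable, n_resamples=n_resamples, seed=seed,
        delta_mean=float(deltas.mean()), delta_sd=float(deltas.std(ddof=1)),
        ci=ci, deltas=deltas,
    )


# ---------------------------------------------------------------------------
# effect tables over assembled budgets
# ---------------------------------------------------------------------------

def arm_values(budgets: list[PlotBudget], variable: str) -> dict[str, np.ndarray]:
    """Plot-level values of one variable per treatment arm, plots sorted."""
    arms: dict[str, list[float]] = {}
    for b in sorted(budgets, key=lambda b: b.plot_id):
        arms.setdefault(b.treatment, []).append(b[variable])
    return {t: np.array(v) for t, v in arms.items()}


def effects_table(
    budgets: list[PlotBudget],
    n_boot: int = 1000,
    seed: int = 0,
    levels: tuple[int, ...] = DEFAULT_LEVELS,
) -> pd.DataFrame:
    """t-based and bootstrap effect estimates for every budget variable."""
    if not budgets:
        raise DataError("no budgets supplied")
    variables = list(budgets[0].values)
    rows = []
    for k, variable in enumerate(variables):
        arms = arm_values(budgets, variable)
        if AMBIENT not in arms or ELEVATED not in arms:
            raise DataError("effects require both ambient and elevated budgets")
        est = effect_estimate(arms[AMBIENT], arms[ELEVATED], variable, levels)
        boot = bootstrap_effect(
            arms[AMBIENT], arms[ELEVATED], n_resamples=n_boot,
            seed=np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31),
            variable=variable, levels=levels,
        )
        row = {
            "variable": variable,
            "ambient_mean": est.ambient_mean,
            "elevated_mean": est.elevated_mean,
            "delta": est.delta,
            "sd_eff": est.sd_eff,
            "sem": est.sem,
            "rel_pct": est.relative_pct,
        }
        for level in levels:
            lo, hi = est.ci[int(level)]
            row[f"ci{level}_lo"], row[f"ci{level}_hi"] = lo, hi
            row[f"sig{level}"] = est.significant(int(level))
        for level in levels:
            lo, hi = boot.ci[int(level)]
            row[f"boot_ci{level}_lo"], row[f"boot_ci{level}_hi"] = lo, hi
        row["n_boot"] = n_boot
        row["seed"] = seed
        rows.append(row)
    return pd.DataFrame(rows)


def lmm_long_table(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Model-ready long table (value ~ treatment * year + (1 | plot)) for
    external mixed-model tools; the mixed model itself is out of scope here.
    """
    frames = []
    for name, frame in tables.items():
        f = frame.copy()
        f["table"] = name
        f["year"] = f["date"].astype(str).str[:4].astype(int)
        frames.append(f[["table", "variable", "component", "plot_id", "treatment",
                         "year", "value", "unit"]])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# simulation harnesses
# ---------------------------------------------------------------------------

#: budget variables with genuine between-plot variability under the default
#: site (constants like deposition or the fixed fine-root resorption
#: coefficient carry no noise and would trivially never be flagged)
DEFAULT_CALIBRATION_VARIABLES = (
    "pool:canopy", "pool:sapwood", "pool:heartwood", "pool:fine_root",
    "pool:coarse_root", "pool:understorey", "pool:forest_floor_litter",
    "pool:plant_total", "pool:soil_total", "pool:soil_organic",
    "pool:soil_inorganic", "pool:soil_microbial", "pool:soil_labile",
    "flux:demand", "flux:uptake", "flux:resorption:total",
    "flux:net_mineralization:total", "flux:frass", "flux:leaching",
    "derived:mrt", "derived:pue_growth", "derived:pue_gpp_overstorey",
)


def coverage_simulation(
    config: SiteConfig,
    variable: str,
    true_multiplier: float,
    n_sims: int,
    seed: int = 0,
    n_plots: int | None = None,
    levels: tuple[int, ...] = DEFAULT_LEVELS,
    n_boot: int = 0,
) -> dict[str, dict[int, float]]:
    """Fraction of simulated experiments whose CI contains the true effect.

    Each simulation draws fresh plot-level budgets from the generator's
    between-plot distribution for both arms (the elevated arm under
    ``{variable: true_multiplier}``), estimates the effect, and checks the
    t-based (and optionally bootstrap-percentile) interval at each level
    against the closed-form true effect.
    """
    if n_sims < 100:
        raise DataError("coverage simulation needs n_sims >= 100")
    n_plots = n_plots or config.n_plots_per_treatment
    base = config.model_copy(update={"co2_multipliers": {}})
    treated = config.model_copy(
        update={"co2_multipliers": {variable: true_multiplier}}
    )
    true_delta = truth(treated, ELEVATED)[_canonical(variable)] - truth(base, AMBIENT)[
        _canonical(variable)
    ]
    rng = np.random.default_rng([seed, 1])
    # one batch draw per arm: simulations are independent slices of iid plots
    amb_all = np.reshape(
        [b[_canonical(variable)]
         for b in sample_plot_budgets(base, AMBIENT, n_sims * n_plots, rng)],
        (n_sims, n_plots),
    )
    ele_all = np.reshape(
        [b[_canonical(variable)]
         for b in sample_plot_budgets(treated, ELEVATED, n_sims * n_plots, rng)],
        (n_sims, n_plots),
    )
    hits_t = {int(level): 0 for level in levels}
    hits_b = {int(level): 0 for level in levels}
    for s in range(n_sims):
        amb, ele = amb_all[s], ele_all[s]
        est = effect_estimate(amb, ele, variable, levels)
        for level in levels:
            lo, hi = est.ci[int(level)]
            hits_t[int(level)] += int(lo <= true_delta <= hi)
        if n_boot:
            boot = bootstrap_effect(
                amb, ele, n_resamples=n_boot, seed=int(rng.integers(2**31)),
                levels=levels,
            )
            for level in levels:
                lo, hi = boot.ci[int(level)]
                hits_b[int(level)] += int(lo <= true_delta <= hi)
    out = {"t": {lvl: hits / n_sims for lvl, hits in hits_t.items()}}
    if n_boot:
        out["bootstrap"] = {lvl: hits / n_sims for lvl, hits in hits_b.items()}
    return out


def _canonical(variable: str) -> str:
    from .synthetic import _MULTIPLIER_ALIASES

    return _MULTIPLIER_ALIASES.get(variable, variable)


def null_calibration(
    config: SiteConfig,
    n_sims: int = 500,
    seed: int = 0,
    variables: tuple[str, ...] = DEFAULT_CALIBRATION_VARIABLES,
    level: int = 95,
) -> float:
    """Long-run false-positive rate under no CO2 effect.

    Simulates experiments with all multipliers at 1 and returns the fraction
    of (simulation, variable) pairs whose CI at ``level`` excludes zero;
    a calibrated interval procedure yields ~ (100 - level) percent.
    """
    base = config.model_copy(update={"co2_multipliers": {}})
    rng = np.random.default_rng([seed, 2])
    n = config.n_plots_per_treatment
    amb_all = sample_plot_budgets(base, AMBIENT, n_sims * n, rng)
    ele_all = sample_plot_budgets(base, ELEVATED, n_sims * n, rng)
    flagged = 0
    total = 0
    for s in range(n_sims):
        amb = amb_all[s * n:(s + 1) * n]
        ele = ele_all[s * n:(s + 1) * n]
        for variable in variables:
            est = effect_estimate(
                np.array([b[variable] for b in amb]),
                np.array([b[variable] for b in ele]),
                variable, (level,),
            )
            flagged += int(est.significant(level))
            total += 1
    return flagged / total


def recovery_simulation(
    config: SiteConfig,
    variable: str,
    multiplier: float,
    n_sims: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Average recovered effect across simulated experiments for a configured
    multiplicative treatment effect (parameter-recovery check)."""
    base = config.model_copy(update={"co2_multipliers": {}})
    treated = config.model_copy(update={"co2_multipliers": {variable: multiplier}})
    rng = np.random.default_rng([seed, 3])
    n = config.n_plots_per_treatment
    canonical = _canonical(variable)
    amb_all = np.reshape(
        [b[canonical] for b in sample_plot_budgets(base, AMBIENT, n_sims * n, rng)],
        (n_sims, n),
    )
    ele_all = np.reshape(
        [b[canonical] for b in sample_plot_budgets(treated, ELEVATED, n_sims * n, rng)],
        (n_sims, n),
    )
    rels = np.empty(n_sims)
    sig = 0
    for s in range(n_sims):
        est = effect_estimate(amb_all[s], ele_all[s], variable)
        rels[s] = est.relative_pct
        sig += int(est.significant(95))
    return {
        "mean_rel_pct": float(rels.mean()),
        "sd_rel_pct": float(rels.std(ddof=1)),
        "detection_rate_95": sig / n_sims,
        "n_sims": n_sims,
    }
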