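"""Closure-identity validation of assembled budgets.

Identities that hold by construction (uptake defined by difference, totals
as within-plot sums) are checked at a tight tolerance as a guard against
plumbing regressions; the ecosystem openness summary quantifies how close
the P cycle is to closed (external inputs and losses versus internal
recycling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .budget import PLANT_POOL_COMPONENTS, PRODUCTION_COMPONENTS, PlotBudget

EXACT_TOL = 1e-9


@dataclass
class IdentityCheck:
    plot_id: str
    name: str
    residual: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.residual) <= self.tolerance


@dataclass
class ValidationReport:
    checks: list[IdentityCheck] = field(default_factory=list)
    flags: dict[str, int] = field(default_factory=dict)
    openness: dict[str, float] = field(default_factory=dict)

    @property
    def all_pass(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[IdentityCheck]:
        return [c for c in self.checks if not c.passed]

    def to_dict(self) -> dict:
        return {
            "all_pass": self.all_pass,
            "checks": [
                {
                    "plot_id": c.plot_id,
                    "name": c.name,
                    "residual": c.residual,
                    "tolerance": c.tolerance,
                    "passed": c.passed,
                }
                for c in self.checks
            ],
            "flags": self.flags,
            "openness": self.openness,
        }


def validate_budgets(budgets: list[PlotBudget]) -> ValidationReport:
    report = ValidationReport()
    for b in budgets:
        v = b.values
        layers = sorted(
            {
                key.split(":")[2]
                for key in v
                if key.startswith("pool:soil_total:")
            },
            key=lambda lab: int(lab.split("-")[0]),
        )
        report.checks.append(
            IdentityCheck(
                b.plot_id, "demand = sum(production)",
                v["flux:demand"]
                - sum(v[f"flux:production:{c}"] for c in PRODUCTION_COMPONENTS),
                EXACT_TOL,
            )
        )
        report.checks.append(
            IdentityCheck(
                b.plot_id, "demand = resorption + uptake",
                v["flux:demand"] - v["flux:resorption:total"] - v["flux:uptake"],
                EXACT_TOL,
            )
        )
        report.checks.append(
            IdentityCheck(
                b.plot_id, "plant pool = sum(components)",
                v["pool:plant_total"]
                - sum(v[f"pool:{c}"] for c in PLANT_POOL_COMPONENTS),
                EXACT_TOL,
            )
        )
        for name in ("soil_total", "soil_organic", "soil_inorganic",
                     "soil_microbial", "soil_labile"):
            report.checks.append(
                IdentityCheck(
                    b.plot_id, f"{name} = sum(layers)",
                    v[f"pool:{name}"]
                    - sum(v[f"pool:{name}:{lab}"] for lab in layers),
                    EXACT_TOL,
                )
            )
        for lab in layers:
            report.checks.append(
                IdentityCheck(
                    b.plot_id, f"organic + inorganic = total ({lab} cm)",
                    v[f"pool:soil_organic:{lab}"] + v[f"pool:soil_inorganic:{lab}"]
                    - v[f"pool:soil_total:{lab}"],
                    EXACT_TOL,
                )
            )
        for key, count in b.flags.items():
            report.flags[key] = report.flags.get(key, 0) + count

    # ecosystem openness: external inputs/outputs vs internal recycling
    uptake = [b["flux:uptake"] for b in budgets]
    dep = [b["flux:deposition"] for b in budgets]
    leach = [b["flux:leaching"] for b in budgets]
    n = len(budgets)
    if n:
        mean_uptake = sum(uptake) / n
        net_external = sum(dep) / n - sum(leach) / n
        report.openness = {
            "mean_deposition": sum(dep) / n,
            "mean_leaching": sum(leach) / n,
            "net_external_input": net_external,
            "mean_uptake": mean_uptake,
            "external_to_uptake_ratio": (
                abs(net_external) / mean_uptake if mean_uptake else float("nan")
            ),
        }
    return report
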