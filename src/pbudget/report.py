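"""Human-readable budget summary: the pool/flux diagram rendered as markdown
tables (treatment mean +- SD), share percentages, and the effect table with
text CI bars."""

from __future__ import annotations

import pandas as pd

from .config import AMBIENT, ELEVATED


def _fmt(mean: float, sd: float) -> str:
    return f"{mean:.3g} ± {sd:.2g}"


def _section(summary: pd.DataFrame, prefix: str, title: str, unit: str) -> list[str]:
    lines = [f"## {title} ({unit})", "",
             "| variable | ambient | elevated |", "| --- | --- | --- |"]
    sel = summary[summary["variable"].str.startswith(prefix)]
    for variable in sorted(sel["variable"].unique()):
        row = {"variable": variable.removeprefix(prefix)}
        for treatment in (AMBIENT, ELEVATED):
            r = sel[(sel["variable"] == variable) & (sel["treatment"] == treatment)]
            row[treatment] = _fmt(float(r["mean"].iloc[0]), float(r["sd"].iloc[0])) \
                if not r.empty else "-"
        lines.append(f"| {row['variable']} | {row[AMBIENT]} | {row[ELEVATED]} |")
    lines.append("")
    return lines


def _get(summary: pd.DataFrame, variable: str, treatment: str = AMBIENT) -> float:
    sel = summary[(summary["variable"] == variable)
                  & (summary["treatment"] == treatment)]
    return float(sel["mean"].iloc[0])


def _ci_bar(row: pd.Series, width: float) -> str:
    """Text rendering of the nested 75/85/95% intervals around zero."""
    marks = []
    for level in (95, 85, 75):
        lo, hi = row[f"ci{level}_lo"], row[f"ci{level}_hi"]
        sig = "*" if lo > 0 or hi < 0 else " "
        marks.append(f"{level}%[{lo:+.3g}, {hi:+.3g}]{sig}")
    return " ".join(marks)


def render_report(summary: pd.DataFrame, effects: pd.DataFrame | None = None) -> str:
    """Markdown report over a treatment summary (and optional effect table)."""
    lines = ["# Ecosystem phosphorus budget", ""]
    lines += _section(summary, "pool:", "P pools", "g P m-2")
    lines += _section(summary, "flux:", "P fluxes", "g P m-2 yr-1")
    lines += _section(summary, "derived:", "Derived indicators", "various units")

    lines += ["## Budget structure (ambient)", ""]
    shares = [
        ("resorption share of plant P demand",
         _get(summary, "derived:resorption_share_pct")),
        ("woody share of plant-and-litter P pool",
         _get(summary, "derived:woody_share_pct")),
        ("forest-floor litter share of plant-and-litter P pool",
         _get(summary, "derived:litter_share_pct")),
        ("fast-turnover share of plant-and-litter P pool",
         _get(summary, "derived:fast_share_pct")),
        ("microbial share of organic soil P",
         _get(summary, "derived:microbial_share_organic_pct")),
        ("labile share of total soil P",
         _get(summary, "derived:labile_share_soil_pct")),
    ]
    for label, value in shares:
        lines.append(f"- {label}: {value:.1f}%")
    lines.append(
        f"- microbial-to-plant P pool ratio: "
        f"{_get(summary, 'derived:microbial_to_plant_ratio'):.2f}"
    )
    lines.append("")

    if effects is not None and not effects.empty:
        lines += ["## CO2 effects (elevated - ambient)", "",
                  "| variable | delta | rel % | confidence intervals |",
                  "| --- | --- | --- | --- |"]
        span = (effects["ci95_hi"] - effects["ci95_lo"]).abs().max()
        for _, row in effects.iterrows():
            lines.append(
                f"| {row['variable']} | {row['delta']:+.3g} | "
                f"{row['rel_pct']:+.1f} | {_ci_bar(row, span)} |"
            )
        lines.append("")
        lines.append("`*` marks intervals excluding zero at that level.")
        lines.append("")
    return "\n".join(lines)
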