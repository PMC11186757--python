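#!/usr/bin/env python
"""Render the assembled budget and effect table as a markdown report
(results/report.md): the pool/flux diagram as tables, share percentages and
CI bars per variable.
"""

import argparse
from pathlib import Path

import pandas as pd

from pbudget.report import render_report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in", dest="indir", type=Path, default=Path("results"))
    parser.add_argument("--out", type=Path, default=Path("results/report.md"))
    args = parser.parse_args()

    summary_path = args.indir / "treatment_summary.csv"
    if not summary_path.exists():
        raise SystemExit("no treatment_summary.csv found; run assemble first")
    summary = pd.read_csv(summary_path)
    effects_path = args.indir / "effects.csv"
    effects = pd.read_csv(effects_path) if effects_path.exists() else None
    text = render_report(summary, effects)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(text)
    print(f"wrote {args.out} ({len(text.splitlines())} lines)")


if __name__ == "__main__":
    main()
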