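"""CSV persistence for measurement tables, budgets and run manifests."""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from . import units
from .errors import DataError
from .synthetic import TABLE_NAMES


def _pipeline_version() -> str:
    try:
        return version("pbudget")
    except PackageNotFoundError:
        return "unknown"


def write_tables(tables: dict[str, pd.DataFrame], out_dir: Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in tables.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False, columns=units.COLUMNS)
        paths.append(path)
    return paths


def read_tables(in_dir: Path) -> dict[str, pd.DataFrame]:
    in_dir = Path(in_dir)
    tables = {}
    for name in TABLE_NAMES:
        path = in_dir / f"{name}.csv"
        if not path.exists():
            raise DataError(f"missing measurement table {path.name} in {in_dir}")
        frame = pd.read_csv(path, dtype={"date": str, "plot_id": str})
        bad = set(frame["unit"].dropna().unique()) - units.VOCABULARY
        if bad:
            raise DataError(f"table {name!r} uses unknown units {sorted(bad)}")
        tables[name] = frame
    return tables


def checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(
    out_dir: Path, config_hash: str, seed: int, files: list[Path]
) -> Path:
    manifest = {
        "config_hash": config_hash,
        "seed": seed,
        "pipeline_version": _pipeline_version(),
        "created": dt.datetime.now(dt.timezone.utc).isoformat(),
        "files": {Path(p).name: checksum(p) for p in sorted(files)},
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
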