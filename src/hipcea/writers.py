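"""Result tables, run manifests, and the run log.

Money is carried at full precision internally and rounded to whole yen
only here; QALYs are written with three decimals.  Every run emits a
manifest (config snapshot, parameter checksum, seed, package version,
stage runtimes) sufficient to reproduce it exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import pandas as pd

from .cea import CEARow
from .engine import SimulationConfig
from .life_tables import Sex

__all__ = ["frontier_table", "write_table", "write_manifest", "config_to_dict"]

FRONTIER_COLUMNS = [
    "Intervention", "Cost", "Incremental cost", "QALYs", "Incremental QALYs", "ICER", "Status",
]


def _money(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    return str(int(round(v)))


def _qaly(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    return f"{v:.3f}"


def frontier_table(rows: list[CEARow]) -> pd.DataFrame:
    """Incremental cost-effectiveness table with display rounding."""
    records = []
    for r in rows:
        records.append({
            "Intervention": r.strategy.value,
            "Cost": _money(r.cost),
            "Incremental cost": _money(r.incr_cost),
            "QALYs": _qaly(r.qaly),
            "Incremental QALYs": _qaly(r.incr_qaly),
            "ICER": _money(r.icer),
            "Status": str(r.status),
        })
    return pd.DataFrame(records, columns=FRONTIER_COLUMNS)


def write_table(df: pd.DataFrame, path: str | Path, money_cols: tuple[str, ...] = (),
                qaly_cols: tuple[str, ...] = ()) -> Path:
    """Write a delimited result table with fixed column order and rounding."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for c in money_cols:
        if c in out.columns:
            out[c] = pd.to_numeric(out[c], errors="coerce").map(_money)
    for c in qaly_cols:
        if c in out.columns:
            out[c] = pd.to_numeric(out[c], errors="coerce").map(_qaly)
    out.to_csv(path, index=False)
    return path


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sex"] = config.sex.value if isinstance(config.sex, Sex) else config.sex
    return d


def write_manifest(path: str | Path, config: SimulationConfig, *,
                   parameter_file: str | Path | None = None,
                   runtimes: dict[str, float] | None = None,
                   log: dict | None = None) -> Path:
    """Machine-readable run manifest: everything needed to re-run bit-for-bit."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    checksum = None
    if parameter_file is not None:
        checksum = hashlib.sha256(Path(parameter_file).read_bytes()).hexdigest()
    manifest = {
        "package_version": __version__,
        "config": config_to_dict(config),
        "seed": config.seed,
        "parameter_file": str(parameter_file) if parameter_file else "packaged",
        "parameter_sha256": checksum,
        "runtimes_s": runtimes or {},
        "log": log or {},
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
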