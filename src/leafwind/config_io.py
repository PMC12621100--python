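"""Run configuration, tabular I/O and run metadata.

Results are written as plain delimited text with an explicit unit header
(comment lines starting ``#``), a JSON summary and a JSON run-metadata log
(resolved parameters, seed, package version) so every run carries enough
information to reproduce itself.  A small importer maps gas-exchange
instrument style CSV column names onto the package's forcing columns.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .params import ParameterSet, load_preset
from .scenarios import ScenarioResult

__all__ = ["RunConfig", "load_config", "write_result", "read_table",
           "read_forcing", "COLUMN_UNITS"]

#: canonical column -> unit registry for forcing and result tables
COLUMN_UNITS = {
    "time": "s", "z": "m", "PPFD": "umol m-2 s-1", "Tair": "degC",
    "T": "degC", "T_air": "degC", "Trefl": "degC", "Tleaf": "degC",
    "ea": "kPa", "VPD": "kPa", "VPD_air": "kPa", "Ds": "kPa",
    "Ca": "umol mol-1", "Ca_air": "umol mol-1", "Cs": "umol mol-1",
    "Ci": "umol mol-1", "Cc": "umol mol-1",
    "u": "m s-1", "A": "umol m-2 s-1", "A_star": "umol m-2 s-1",
    "E": "mol m-2 s-1", "gbw": "mol m-2 s-1", "gbw_one_sided": "mol m-2 s-1",
    "gbw_total": "mol m-2 s-1", "gs": "mol m-2 s-1", "gs_star": "mol m-2 s-1",
    "gsw": "mol m-2 s-1", "net_flux": "W m-2", "L": "m",
    "mean_A": "umol m-2 s-1", "mean_E": "mmol m-2 s-1",
}

#: gas-exchange-instrument-style column aliases accepted by read_forcing
_FORCING_ALIASES = {
    "Qin": "PPFD", "Qamb": "PPFD", "PARi": "PPFD", "ppfd": "PPFD",
    "Tair": "Tair", "Tamb": "Tair",
    "CO2_r": "Ca", "CO2R": "Ca", "ca": "Ca",
    "H2O_r": "ea", "ea": "ea", "time": "time", "elapsed": "time",
}

_KNOWN_KEYS = {"scenario", "preset", "overrides", "forcing", "solver",
               "out_dir", "seed"}


@dataclass
class RunConfig:
    """Fully resolved configuration of one scenario run."""

    scenario: str
    preset: str = "tomato_greenhouse"
    overrides: dict[str, Any] = field(default_factory=dict)
    forcing: dict[str, Any] = field(default_factory=dict)
    solver: dict[str, Any] = field(default_factory=dict)
    out_dir: str = "results"
    seed: int = 0

    def parameter_set(self) -> ParameterSet:
        params = load_preset(self.preset)
        if self.overrides:
            params = params.with_overrides(self.overrides)
        return params

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown top-level keys are rejected; the preset (plus any overrides) is
    resolved eagerly so schema violations surface at load time.  The
    round trip load -> serialise -> load is the identity.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "scenario" not in raw:
        raise ValueError("config must be a mapping with at least a 'scenario' key")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.parameter_set()  # validates preset name and override keys/invariants
    if cfg.scenario not in {"worked-example", "diurnal", "sweep", "profile",
                            "gb-dist", "synth"}:
        raise ValueError(f"unknown scenario {cfg.scenario!r}")
    return cfg


def _write_table(df: pd.DataFrame, path: Path) -> None:
    units = [COLUMN_UNITS.get(c, "-") for c in df.columns]
    with open(path, "w") as fh:
        fh.write("# columns: " + ",".join(df.columns) + "\n")
        fh.write("# units: " + ",".join(units) + "\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a result/forcing table written by :func:`write_result`."""
    return pd.read_csv(path, comment="#")


def read_forcing(path: str | Path) -> pd.DataFrame:
    """Read a forcing table, accepting instrument-style column aliases."""
    df = read_table(path)
    renames = {c: _FORCING_ALIASES[c] for c in df.columns if c in _FORCING_ALIASES}
    return df.rename(columns=renames)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    if isinstance(obj, float) and obj != obj:
        return None
    return obj


def write_result(result: ScenarioResult, out_dir: str | Path,
                 config: RunConfig | None = None) -> dict[str, Path]:
    """Write a scenario result: data table, summary and run metadata.

    Emits ``<name>_table.csv`` (unit-annotated delimited text),
    ``<name>_summary.json`` and ``<name>_run_meta.json``.  Re-reading the
    table with :func:`read_table` reproduces the in-memory values.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    table_path = out / f"{result.name}_table.csv"
    _write_table(result.table, table_path)
    paths["table"] = table_path

    summary_path = out / f"{result.name}_summary.json"
    summary_path.write_text(json.dumps(_jsonable(result.summaries), indent=2))
    paths["summary"] = summary_path

    from . import __version__

    meta = {
        "scenario": result.name,
        "baseline": result.baseline,
        "package_version": __version__,
        "meta": _jsonable(result.meta),
    }
    if config is not None:
        meta["config"] = _jsonable(config.to_dict())
    meta_path = out / f"{result.name}_run_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    paths["run_meta"] = meta_path
    return paths
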