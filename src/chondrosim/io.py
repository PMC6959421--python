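"""Scenario configuration files, structured outputs and the run manifest.

Configs are YAML or JSON mappings whose keys mirror the model symbols in
ASCII (c_sat, K_half, k_GAG, ...).  Outputs are RFC-4180 CSV files plus a
JSON manifest; the pipeline is deterministic, so reruns with an identical
config are byte-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .parameters import ModelParameters, ParameterError
from .simulation import DAY, ScenarioConfig, TimeSeriesRecord, scenario_presets


_version = "0.1.0"


class ConfigError(ParameterError):
    pass


_SCENARIO_KEYS = {"preset", "N", "dt", "T_end", "tend_days", "A_n", "A_v",
                  "A_q", "A_ECM", "T_b", "V_b", "c_ext", "fixed_point_tol",
                  "max_inner_iters", "sample_every", "name",
                  "abort_on_nonconvergence"}


def _resolve(raw: dict) -> tuple[ScenarioConfig, dict]:
    """Build a ScenarioConfig from a raw mapping; returns (config, overrides)."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    raw = dict(raw)
    # T_b / V_b in a config file mean the applied boundary data of the run
    # (the identically named tabulated constants only feed the presets)
    param_names = set(ModelParameters.field_names()) - {"T_b", "V_b"}
    unknown = set(raw) - _SCENARIO_KEYS - param_names
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    preset = raw.pop("preset", None)
    if preset is not None:
        presets = scenario_presets()
        if preset not in presets:
            raise ConfigError(f"unknown preset {preset!r}; "
                              f"choose from {sorted(presets)}")
        cfg = presets[preset]
    else:
        cfg = ScenarioConfig()

    defaults = ModelParameters()
    p_overrides = {k: raw.pop(k) for k in list(raw) if k in param_names}
    flagged = {k: v for k, v in p_overrides.items()
               if v != getattr(defaults, k)}
    if p_overrides:
        cfg.params = cfg.params.with_updates(**p_overrides)

    if "tend_days" in raw:
        raw["T_end"] = float(raw.pop("tend_days")) * DAY
    for key, val in raw.items():
        setattr(cfg, key, type(getattr(cfg, key))(val)
                if not isinstance(val, bool) else val)
    cfg.validate()
    return cfg, flagged


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Read a YAML/JSON scenario file and return a fully resolved config.

    Unspecified physical parameters fall back to the standard defaults.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    raw = yaml.safe_load(text) or {}
    cfg, _ = _resolve(raw)
    return cfg


def scenario_from_mapping(raw: dict) -> tuple[ScenarioConfig, dict]:
    """As :func:`load_scenario`, for an in-memory mapping."""
    return _resolve(raw)


def save_scenario(cfg: ScenarioConfig, path: str | Path) -> Path:
    """Write a fully resolved scenario to YAML.

    Loading the file back yields an identical configuration (round-trip).
    """
    path = Path(path)
    out = cfg.params.to_dict()
    out.update({k: getattr(cfg, k) for k in _SCENARIO_KEYS
                if k not in ("preset", "tend_days") and hasattr(cfg, k)})
    path.write_text(yaml.safe_dump(out, sort_keys=True))
    return path


@dataclass
class RunManifest:
    """Provenance record written next to every result set."""

    scenario: str
    parameters: dict
    overrides: dict          # parameters that differ from the defaults
    code_version: str
    deterministic: bool
    wall_time_s: float
    max_inner_sweeps: int
    mean_inner_sweeps: float
    all_converged: bool

    @classmethod
    def from_record(cls, rec: TimeSeriesRecord, wall_time_s: float,
                    overrides: dict | None = None) -> "RunManifest":
        sweeps = rec.sweeps[1:] if rec.sweeps.size > 1 else rec.sweeps
        return cls(
            scenario=rec.config.name,
            parameters=rec.config.params.to_dict(),
            overrides=overrides or {},
            code_version=_version,
            deterministic=True,   # no random number source anywhere in the pipeline
            wall_time_s=wall_time_s,
            max_inner_sweeps=int(sweeps.max()) if sweeps.size else 0,
            mean_inner_sweeps=float(sweeps.mean()) if sweeps.size else 0.0,
            all_converged=rec.all_converged,
        )


def write_outputs(rec: TimeSeriesRecord, manifest: RunManifest,
                  outdir: str | Path) -> dict[str, Path]:
    """Write midpoint CSV, x–t grids and the JSON manifest.

    Returns a mapping of logical name to written path.
    """
    if rec.times.size == 0:
        raise ValueError("empty record")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    mid = pd.DataFrame({"t_s": rec.times, "t_days": rec.days})
    for name in ("phi_n", "phi_v", "phi_q", "phi_ECM", "phi_fl", "c", "u",
                 "p", "r", "xi"):
        mid[name] = rec.midpoint[name]
    path = outdir / "midpoint_timeseries.csv"
    mid.to_csv(path, index=False, lineterminator="\r\n", float_format="%.10e")
    written["midpoint"] = path

    for grid_name, grid in (("c", rec.c_grid), ("xi", rec.xi_grid)):
        if grid is None:
            continue
        t = np.repeat(rec.times, rec.x.size)
        x = np.tile(rec.x, rec.times.size)
        df = pd.DataFrame({"t_s": t, "x_cm": x, "value": grid.ravel()})
        path = outdir / f"{grid_name}_grid.csv"
        df.to_csv(path, index=False, lineterminator="\r\n",
                  float_format="%.10e")
        written[f"{grid_name}_grid"] = path

    path = outdir / "manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=2, sort_keys=True)
                    + "\n")
    written["manifest"] = path
    return written


def run_and_write(cfg: ScenarioConfig, outdir: str | Path,
                  overrides: dict | None = None) -> dict[str, Path]:
    """Convenience wrapper: run a scenario and persist all outputs."""
    from .simulation import run_simulation

    t0 = time.perf_counter()
    rec = run_simulation(cfg)
    manifest = RunManifest.from_record(rec, time.perf_counter() - t0,
                                       overrides)
    return write_outputs(rec, manifest, outdir)
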