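"""Delimited-text readers/writers, scenario configs, and run manifests.

All tabular schemas are comma-delimited UTF-8 with "." decimals and fixed
canonical headers; no dialect sniffing.  Every CLI run writes exactly one
JSON manifest recording the command, input digests, seed, and the density
and unit settings in force — enough to re-run the computation byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .chem_registry import Chemical, SamplerSpec
from .kinetics import KineticFit, UptakeObservation, UptakeSeries
from .synthetic_data import ChamberScenario, ChemicalTruth

logger = logging.getLogger("swbair")

__all__ = [
    "SchemaError",
    "read_uptake_file",
    "write_uptake_file",
    "read_deployment_file",
    "read_scenario_config",
    "kinetic_fits_to_frame",
    "write_manifest",
]

UPTAKE_COLUMNS = ["chemical", "replicate", "time_value", "time_unit",
                  "amount_ng", "below_lod", "ca_ng_per_l"]
DEPLOYMENT_COLUMNS = ["chemical", "amount_ng", "sampler_mass_g", "days_worn"]

_TIME_UNIT_TO_DAYS = {"d": 1.0, "day": 1.0, "days": 1.0, "h": 1.0 / 24.0,
                      "hr": 1.0 / 24.0, "hours": 1.0 / 24.0}


class SchemaError(ValueError):
    """A delimited input file does not match its declared schema."""


def read_uptake_file(
    path,
    chemicals: dict[str, Chemical],
    sampler: Optional[SamplerSpec] = None,
) -> list[UptakeSeries]:
    """Read an uptake time-series file, grouping rows by chemical.

    The ``time_unit`` column ("d" or "h") is honored: hours are converted to
    days.  Replicate labels are preserved so pooled or per-replicate fitting
    can be chosen downstream.  Malformed rows raise :class:`SchemaError`
    naming the 1-based data line.
    """
    sampler = sampler or SamplerSpec()
    df = pd.read_csv(path, dtype={"chemical": str, "replicate": str, "time_unit": str},
                     float_precision="round_trip")
    unknown = [c for c in df.columns if c not in UPTAKE_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown column(s) {unknown} in {path}")
    missing = [c for c in UPTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    if df.empty:
        logger.warning("uptake file %s has an empty data section", path)
        return []

    series_map: dict[str, dict] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        unit = str(row["time_unit"]).strip().lower()
        if unit not in _TIME_UNIT_TO_DAYS:
            raise SchemaError(f"line {line}: unknown time unit {row['time_unit']!r}")
        t = float(row["time_value"]) * _TIME_UNIT_TO_DAYS[unit]
        if t < 0:
            raise SchemaError(f"line {line}: negative time")
        ca = row["ca_ng_per_l"]
        if pd.isna(ca):
            raise SchemaError(f"line {line}: missing ca_ng_per_l")
        name = str(row["chemical"])
        if name not in chemicals:
            raise SchemaError(f"line {line}: unknown chemical {name!r}")
        obs = UptakeObservation(
            t=t,
            amount_ng=float(row["amount_ng"]),
            replicate=str(row["replicate"]),
            below_lod=_parse_bool(row["below_lod"], line),
        )
        bucket = series_map.setdefault(name, {"ca": float(ca), "obs": []})
        if bucket["ca"] != float(ca):
            raise SchemaError(f"line {line}: conflicting ca_ng_per_l for {name!r}")
        bucket["obs"].append(obs)

    return [
        UptakeSeries(chemical=chemicals[name], sampler=sampler,
                     ca_ng_per_l=bucket["ca"], observations=tuple(bucket["obs"]))
        for name, bucket in series_map.items()
    ]


def _parse_bool(v, line: int) -> bool:
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", "nan", ""):
        return False
    raise SchemaError(f"line {line}: bad boolean {v!r}")


def write_uptake_file(series: Sequence[UptakeSeries], path) -> None:
    """Write uptake series in the canonical schema (times in days)."""
    rows = []
    for s in series:
        for o in s.observations:
            rows.append({
                "chemical": s.chemical.name,
                "replicate": o.replicate,
                "time_value": repr(o.t),
                "time_unit": "d",
                "amount_ng": repr(o.amount_ng),
                "below_lod": o.below_lod,
                "ca_ng_per_l": repr(s.ca_ng_per_l),
            })
    pd.DataFrame(rows, columns=UPTAKE_COLUMNS).to_csv(path, index=False)


def read_deployment_file(path, chemicals: dict[str, Chemical],
                         density_g_per_ml: float = 1.10) -> pd.DataFrame:
    """Read worn-sampler deployment queries; returns the raw frame validated."""
    df = pd.read_csv(path, dtype={"chemical": str})
    missing = [c for c in DEPLOYMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    for i, row in df.iterrows():
        if str(row["chemical"]) not in chemicals:
            raise SchemaError(f"line {i + 2}: unknown chemical {row['chemical']!r}")
    return df


def read_scenario_config(path, chemicals: dict[str, Chemical]) -> ChamberScenario:
    """Build a ChamberScenario from a YAML config mirroring its fields.

    Expected layout::

        sampler: {mass_g: 4.76, density_g_per_ml: 1.10}
        timepoints: [0.25, 0.5, 1, 3, 7, 14]
        n_replicate_series: 3
        noise_cv: 0.1
        lod_ng: 0.0
        seed: 42
        chemicals:
          - {name: Benzene, ksa: 2800, ke_per_day: 1.2, ca_ng_per_l: 1600}
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    sampler = SamplerSpec(**cfg.get("sampler", {}))
    truths = []
    for entry in cfg["chemicals"]:
        name = entry["name"]
        if name not in chemicals:
            raise SchemaError(f"scenario references unknown chemical {name!r}")
        truths.append(ChemicalTruth(
            chemical=chemicals[name],
            ksa=float(entry["ksa"]),
            ke_per_day=float(entry["ke_per_day"]),
            ca_ng_per_l=float(entry["ca_ng_per_l"]),
        ))
    kwargs = {}
    for key in ("timepoints", "n_replicate_series", "noise_cv", "lod_ng", "seed"):
        if key in cfg:
            kwargs[key] = cfg[key]
    if "timepoints" in kwargs:
        kwargs["timepoints"] = tuple(float(t) for t in kwargs["timepoints"])
    return ChamberScenario(truths=tuple(truths), sampler=sampler, **kwargs)


def kinetic_fits_to_frame(fits: dict[str, KineticFit]) -> pd.DataFrame:
    """Flatten KineticFit results (keyed by chemical name) into a table."""
    rows = []
    for name, f in fits.items():
        rows.append({
            "chemical": name,
            "model_form": f.model_form.value,
            "sqrt_time": f.sqrt_time_used,
            "ns_eq_ng": f.ns_eq_ng.value, "ns_eq_sd": f.ns_eq_ng.sd,
            "ksa": f.ksa.value, "ksa_sd": f.ksa.sd,
            "log_ksa": f.log_ksa.value, "log_ksa_sd": f.log_ksa.sd,
            "ke_per_day": f.ke_per_day.value, "ke_sd": f.ke_per_day.sd,
            "log_ke": f.log_ke.value, "log_ke_sd": f.log_ke.sd,
            "rs_l_per_day": f.rs_l_per_day.value, "rs_sd": f.rs_l_per_day.sd,
            "equilibrium_status": f.equilibrium_status.value,
            "n_obs": f.n_obs,
            "density_g_per_ml": f.density_g_per_ml,
        })
    return pd.DataFrame(rows)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir,
    command: str,
    inputs: Sequence[str],
    seed: Optional[int] = None,
    settings: Optional[dict] = None,
) -> Path:
    """Write the run manifest JSON next to the outputs; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "inputs": {str(p): _digest(p) for p in inputs if Path(p).is_file()},
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "settings": settings or {},
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
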