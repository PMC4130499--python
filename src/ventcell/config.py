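"""Configuration ingestion, result serialization and run manifests.

Config files are YAML (JSON is valid YAML and therefore also accepted) with
the nested schema of :data:`DEFAULT_CONFIG`.  Validation is strict: unknown
keys are rejected with their full path rather than ignored, so a mistyped
constant cannot silently fall back to a default.  All quantities are given
in the field's customary units (cm/s, mol/L, nm2, kJ/mol, um) and converted
to SI exactly once, here.
"""

from __future__ import annotations

import copy
import datetime as _dt
import json
import numbers
import os
from dataclasses import asdict, dataclass
from importlib.metadata import PackageNotFoundError, version as _pkg_version

import pandas as pd
import yaml

from .constants import (
    DEFAULT_CL_PERMEABILITY_CM_S,
    DEFAULT_EFFICIENCY_SCALE,
    DEFAULT_H2,
    DEFAULT_OCEAN_K,
    DEFAULT_OCEAN_NA,
    NA_TO_H_PERMEABILITY_RATIO,
    PROTEIN_DEFAULTS,
    cm_per_s,
    nm2,
)
from .membrane import MembraneGeometry
from .proteins import ProteinKind, ProteinSpec
from .simulator import Environment, RunSpec, SimConfig, SimResult

__all__ = [
    "DEFAULT_CONFIG",
    "default_config",
    "merge_config",
    "set_by_path",
    "validate_config",
    "build_runspec",
    "load_config",
    "RunManifest",
    "write_results",
]


def _protein_defaults(kind: str) -> dict:
    entry = PROTEIN_DEFAULTS[kind]
    block = {
        "surface_fraction": 0.0,
        "max_turnover_per_s": entry["max_turnover"],
        "unit_footprint_nm2": entry["unit_footprint_nm2"],
        "ions_per_cycle": entry["ions_per_cycle"],
        "efficiency_scale": DEFAULT_EFFICIENCY_SCALE,
    }
    if kind == "pump":
        block["pumped_ion"] = "H"
    return block


DEFAULT_CONFIG: dict = {
    "environment": {
        "ph_acid": 7.0,
        "ph_alk": 10.0,
        "temperature_k": 298.0,
        "ocean_na_mol_l": DEFAULT_OCEAN_NA,
        "ocean_k_mol_l": DEFAULT_OCEAN_K,
        "ocean_cl_mol_l": None,  # charge-balancing when null
        "h2_mol_l": DEFAULT_H2,
    },
    "membrane": {
        "permeability_h_cm_s": 1e-3,
        "permeability_cl_cm_s": DEFAULT_CL_PERMEABILITY_CM_S,
        "na_to_h_permeability_ratio": NA_TO_H_PERMEABILITY_RATIO,
        "radius_um": 1.0,
        "acid_face_fraction": 0.5,
    },
    "proteins": {kind: _protein_defaults(kind) for kind in PROTEIN_DEFAULTS},
    "sim": {
        "dt_s": 1e-3,
        "t_end_s": 600.0,
        "steady_tol_kj_mol_s": 1e-4,
        "steady_window_s": 10.0,
        "record_interval_s": 0.5,
        "seed": None,
        "audit": False,
    },
    "combine": "sum",
}

_NULLABLE_KEYS = {
    "environment.ocean_cl_mol_l",
    "sim.seed",
}
_NON_NUMERIC_KEYS = {
    "proteins.pump.pumped_ion",
    "combine",
    "sim.audit",
}


def default_config() -> dict:
    """A deep copy of the fully defaulted configuration."""
    return copy.deepcopy(DEFAULT_CONFIG)


def validate_config(config: dict, _template: dict | None = None, _path: str = "") -> None:
    """Reject unknown keys and non-numeric values, naming the exact path."""
    template = DEFAULT_CONFIG if _template is None else _template
    if not isinstance(config, dict):
        raise ValueError(f"config section {_path or '<root>'} must be a mapping")
    for key, value in config.items():
        path = f"{_path}.{key}" if _path else key
        if key not in template:
            raise ValueError(f"unknown config key: {path}")
        if isinstance(template[key], dict):
            validate_config(value, template[key], path)
            continue
        if value is None:
            if path in _NULLABLE_KEYS:
                continue
            raise ValueError(f"config key {path} may not be null")
        if path in _NON_NUMERIC_KEYS:
            continue
        if not isinstance(value, numbers.Real):
            raise ValueError(
                f"config key {path} must be a number, got {type(value).__name__}"
            )


def merge_config(base: dict, overrides: dict | None) -> dict:
    """Recursively merge ``overrides`` into a copy of ``base`` (strictly)."""
    merged = copy.deepcopy(base)
    if not overrides:
        return merged

    def _merge(dst: dict, src: dict, path: str) -> None:
        for key, value in src.items():
            here = f"{path}.{key}" if path else key
            if key not in dst:
                raise ValueError(f"unknown config key: {here}")
            if isinstance(dst[key], dict) and isinstance(value, dict):
                _merge(dst[key], value, here)
            else:
                dst[key] = value

    _merge(merged, overrides, "")
    return merged


def set_by_path(config: dict, dotted: str, value) -> None:
    """Set ``config['a']['b'] = value`` from ``'a.b'``; unknown paths raise."""
    node = config
    parts = dotted.split(".")
    for part in parts[:-1]:
        if part not in node or not isinstance(node[part], dict):
            raise ValueError(f"unknown config path: {dotted}")
        node = node[part]
    if parts[-1] not in node:
        raise ValueError(f"unknown config path: {dotted}")
    node[parts[-1]] = value


def build_runspec(config: dict) -> RunSpec:
    """Validate a (possibly sparse) config mapping and resolve it to a RunSpec."""
    validate_config(config)
    cfg = merge_config(DEFAULT_CONFIG, config)
    envc = cfg["environment"]
    env = Environment(
        ph_acid=envc["ph_acid"],
        ph_alk=envc["ph_alk"],
        temperature=envc["temperature_k"],
        ocean_na=envc["ocean_na_mol_l"],
        ocean_k=envc["ocean_k_mol_l"],
        ocean_cl=envc["ocean_cl_mol_l"],
        h2=envc["h2_mol_l"],
    )
    memc = cfg["membrane"]
    geometry = MembraneGeometry(
        radius=memc["radius_um"] * 1e-6,
        acid_face_fraction=memc["acid_face_fraction"],
    )
    permeability_h = cm_per_s(memc["permeability_h_cm_s"])
    overrides = {}
    ratio = memc["na_to_h_permeability_ratio"]
    if ratio != NA_TO_H_PERMEABILITY_RATIO:
        p_na = permeability_h * ratio
        overrides.update({"Na": p_na, "K": p_na})
    if memc["permeability_cl_cm_s"] != DEFAULT_CL_PERMEABILITY_CM_S:
        overrides["Cl"] = cm_per_s(memc["permeability_cl_cm_s"])
    overrides = overrides or None
    proteins = []
    for kind, block in cfg["proteins"].items():
        if block["surface_fraction"] <= 0.0:
            continue
        proteins.append(
            ProteinSpec(
                kind=ProteinKind(kind),
                surface_fraction=block["surface_fraction"],
                unit_footprint=nm2(block["unit_footprint_nm2"]),
                max_turnover=block["max_turnover_per_s"],
                ions_per_cycle=block["ions_per_cycle"],
                efficiency_scale=block["efficiency_scale"],
                pumped_ion=block.get("pumped_ion") if kind == "pump" else None,
            )
        )
    simc = cfg["sim"]
    sim = SimConfig(
        dt=simc["dt_s"],
        t_end=simc["t_end_s"],
        steady_tol=simc["steady_tol_kj_mol_s"],
        steady_window=simc["steady_window_s"],
        record_interval=simc["record_interval_s"],
        seed=simc["seed"],
        audit=bool(simc["audit"]),
    )
    return RunSpec(
        environment=env,
        geometry=geometry,
        proteins=tuple(proteins),
        permeability_h=permeability_h,
        sim=sim,
        permeability_overrides=overrides,
        combine=cfg["combine"],
    )


def load_config(path: str) -> dict:
    """Read and validate a YAML/JSON config file (sparse keys allowed)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if raw is None:
        raw = {}
    validate_config(raw)
    return raw


# ---------------------------------------------------------------------------
# Manifests and result serialization
# ---------------------------------------------------------------------------

def _package_version() -> str:
    try:
        return _pkg_version("ventcell")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunManifest:
    """Provenance record written alongside every result file."""

    resolved_config: dict
    package_version: str
    seed: int | None
    created_utc: str
    audit_status: dict | None = None

    @classmethod
    def for_config(
        cls, config: dict, seed: int | None = None, audit_status: dict | None = None
    ) -> "RunManifest":
        return cls(
            resolved_config=merge_config(DEFAULT_CONFIG, config),
            package_version=_package_version(),
            seed=seed,
            created_utc=_dt.datetime.now(_dt.timezone.utc).isoformat(),
            audit_status=audit_status,
        )

    def write(self, path: str) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2, sort_keys=True)
            handle.write("\n")


def write_results(
    result: SimResult | pd.DataFrame,
    path: str,
    manifest: RunManifest | None = None,
    sep: str = ",",
) -> list[str]:
    """Write a trajectory or sweep table plus its JSON manifest sidecar.

    Numbers are serialized with ``repr`` round-trip precision.  Returns the
    list of files written.
    """
    frame = result.timeseries if isinstance(result, SimResult) else result
    if frame.empty:
        raise ValueError("refusing to write an empty result table")
    frame.to_csv(path, sep=sep, index=False, float_format=lambda x: repr(float(x)))
    written = [path]
    if manifest is not None:
        sidecar = os.path.splitext(path)[0] + ".manifest.json"
        manifest.write(sidecar)
        written.append(sidecar)
    return written
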