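"""Versioned configuration: property coefficients, geometry and solver knobs.

All correlation constants and dimensions live in one YAML document so an
installation can swap them (different glass, recalibrated cp fit, another
convection correlation) without code changes.  ``load_config`` merges a
user file over the packaged defaults; ``config_hash`` gives the short
digest the CLI prints in its reproducibility block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .energy_balance import BalanceOptions, DryerGeometry
from .properties import PropertyCoefficients
from .tout_solver import SolverSettings

__all__ = ["ModelConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class ModelConfig:
    version: str
    coefficients: PropertyCoefficients
    geometry: DryerGeometry
    balance: BalanceOptions
    solver: SolverSettings
    ambient: dict  # design-space ambient conditions {Text, RHext}

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "properties": vars(self.coefficients),
            "geometry": {
                k: getattr(self.geometry, k)
                for k in (
                    "tower_diameter",
                    "tower_height",
                    "glass_thickness",
                    "glass_conductivity",
                    "glass_emissivity",
                )
            },
            "balance": {
                "cp_mode": self.balance.cp_mode,
                "correlation": self.balance.correlation,
                "pressure": self.balance.pressure,
            },
            "solver": vars(self.solver),
            "ambient": dict(self.ambient),
        }


def _defaults() -> dict:
    text = resources.files("spraydry.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load the packaged default config, optionally overlaid with a user file."""
    data = _defaults()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        data = _merge(data, user)
    coeffs = PropertyCoefficients(**data["properties"])
    geometry = DryerGeometry(**data["geometry"])
    balance = BalanceOptions(coefficients=coeffs, **data["balance"])
    solver = SolverSettings(**data["solver"])
    return ModelConfig(
        version=str(data["version"]),
        coefficients=coeffs,
        geometry=geometry,
        balance=balance,
        solver=solver,
        ambient=data["ambient"],
    )


def config_hash(config: ModelConfig) -> str:
    """Short deterministic digest of the full configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
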