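"""YAML run configuration with a strict schema.

One file carries the input paths, the model parameter block, solver
tolerances and the chemostat setup; unknown keys are rejected so typos
fail loudly.  All randomness in a run flows from the single ``seed``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


_KNOWN_TOP = {"paths", "parameters", "solver", "chemostat", "seed"}
_KNOWN_PATHS = {"network", "fluxes", "exchanges", "expression", "intensities", "output"}
_KNOWN_PARAMS = {
    "alpha", "beta", "lambda", "inhibition", "woa_uptake", "atp_per_woa", "phi",
    "lowess_span",
}
_KNOWN_SOLVER = {"tol_residual", "max_iter"}
_KNOWN_CHEMOSTAT = {
    "dilution_rate", "biomass_floor", "glucose_uptake_reaction", "glucose_species",
    "feed_glucose", "reference_biomass",
}


@dataclass
class RunConfig:
    paths: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    chemostat: dict = field(default_factory=dict)
    seed: int = 0

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _check_keys(block: dict, known: set[str], where: str) -> None:
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def load_config(path: str | Path, require_paths: bool = True) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")
    _check_keys(doc, _KNOWN_TOP, "config")
    _check_keys(doc.get("paths", {}), _KNOWN_PATHS, "paths")
    _check_keys(doc.get("parameters", {}), _KNOWN_PARAMS, "parameters")
    _check_keys(doc.get("solver", {}), _KNOWN_SOLVER, "solver")
    _check_keys(doc.get("chemostat", {}), _KNOWN_CHEMOSTAT, "chemostat")
    cfg = RunConfig(
        paths=doc.get("paths", {}),
        parameters=doc.get("parameters", {}),
        solver=doc.get("solver", {}),
        chemostat=doc.get("chemostat", {}),
        seed=int(doc.get("seed", 0)),
    )
    if require_paths:
        base = Path(path).parent
        for key, p in cfg.paths.items():
            if key == "output":
                continue
            candidate = Path(p)
            if not candidate.is_absolute():
                candidate = base / candidate
            if not candidate.exists():
                raise ConfigError(f"paths.{key}: file not found: {candidate}")
            cfg.paths[key] = str(candidate)
    return cfg


def rate_parameters_from_config(cfg: RunConfig, phi: dict | None = None):
    from .ratelaws import RateParameters

    p = cfg.parameters
    return RateParameters(
        alpha=float(p.get("alpha", 0.1)),
        beta_global=float(p.get("beta", 30.0)),
        lambda_growth=float(p.get("lambda", 1.0)),
        inhibition={k: float(v) for k, v in (p.get("inhibition") or {}).items()},
        woa_uptake=float(p.get("woa_uptake", 0.0)),
        atp_per_woa=float(p.get("atp_per_woa", 2.0)),
        phi={k: float(v) for k, v in (p.get("phi") or (phi or {})).items()},
    )
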