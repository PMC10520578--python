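"""YAML pipeline configuration: loading, validation, defaults, manifest echo.

A run is described by one YAML file with optional blocks; every default is
filled at load time so the emitted manifest always shows the complete
effective configuration.  Exactly one input source must be given: either
``input_csv`` (an external panel) or a ``simulation`` block.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .impute import ImputationSpec
from .mediation import AnalysisConfig
from .preprocess import VariableRoles
from .simulate import SimParams

__all__ = ["PipelineConfig", "load_validate_config", "ConfigError", "DEFAULTS"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


#: Central numeric defaults (one place, echoed into every manifest).
DEFAULTS = {
    "m_imputations": 20,          # twenty imputed datasets
    "n_bootstrap": 1000,          # 1000 bootstrap re-samplings
    "smd_negligible": 0.1,
    "smd_reasonable": 0.2,
    "caseness_cutoff": 4,         # GHQ-12 >= 4
    "poverty_fraction": 0.6,      # < 60% of median income, after housing costs
    "age_min": 25,
    "age_max": 64,
    "drop_rule_max_missing": 9,   # drop rows missing > 9 of the 22 variables
    "drop_rule_n_variables": 22,
}

_TOP_KEYS = {
    "input_csv",
    "simulation",
    "roles",
    "imputation",
    "analysis",
    "truncation",
    "output_dir",
    "seed",
}


@dataclass
class PipelineConfig:
    """Validated configuration for one end-to-end run."""

    input_csv: str | None = None
    sim_params: SimParams | None = None
    roles: VariableRoles = field(default_factory=VariableRoles)
    imputation: ImputationSpec = field(default_factory=lambda: ImputationSpec(m=DEFAULTS["m_imputations"]))
    analysis: AnalysisConfig = field(default_factory=lambda: AnalysisConfig(n_boot=DEFAULTS["n_bootstrap"], m=DEFAULTS["m_imputations"]))
    output_dir: str = "msmediate_out"
    seed: int = 0

    def validate(self) -> None:
        if (self.input_csv is None) == (self.sim_params is None):
            raise ConfigError("exactly one of input_csv or a simulation block is required")
        self.analysis.validate()
        self.imputation.validate()
        if self.sim_params is not None:
            self.sim_params.validate()

    def to_dict(self) -> dict:
        return {
            "input_csv": self.input_csv,
            "simulation": self.sim_params.to_dict() if self.sim_params else None,
            "roles": dataclasses.asdict(self.roles),
            "imputation": {
                "m": self.imputation.m,
                "n_chain_iterations": self.imputation.n_chain_iterations,
                "k_pmm": self.imputation.k_pmm,
                "seed": self.imputation.seed,
            },
            "analysis": dataclasses.asdict(self.analysis),
            # output_dir deliberately not echoed: reports are reproducible
            # wherever they are written
            "seed": self.seed,
            "defaults": dict(DEFAULTS),
        }


def _build_dataclass(cls, block: dict, label: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"unknown keys in {label} block: {sorted(unknown)}")
    coerced = {}
    for k, v in block.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return cls(**coerced)


def load_validate_config(path) -> PipelineConfig:
    """Load a YAML config, fill defaults, and validate it."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top-level YAML must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    seed = int(raw.get("seed", 0))
    sim = None
    if "simulation" in raw:
        sim_block = dict(raw["simulation"] or {})
        sim_block.setdefault("seed", seed)
        sim = _build_dataclass(SimParams, sim_block, "simulation")
    roles = _build_dataclass(VariableRoles, dict(raw.get("roles") or {}), "roles")
    imp_block = dict(raw.get("imputation") or {})
    imp_block.setdefault("m", DEFAULTS["m_imputations"])
    imputation = _build_dataclass(ImputationSpec, imp_block, "imputation")
    ana_block = dict(raw.get("analysis") or {})
    ana_block.setdefault("n_boot", DEFAULTS["n_bootstrap"])
    ana_block.setdefault("m", imputation.m)
    ana_block.setdefault("seed", seed)
    analysis = _build_dataclass(AnalysisConfig, ana_block, "analysis")
    if "truncation" in raw and raw["truncation"] is not None:
        trunc = raw["truncation"]
        if trunc is not False:
            analysis.truncate = (float(trunc["lower_pct"]), float(trunc["upper_pct"]))

    cfg = PipelineConfig(
        input_csv=raw.get("input_csv"),
        sim_params=sim,
        roles=roles,
        imputation=imputation,
        analysis=analysis,
        output_dir=str(raw.get("output_dir", "msmediate_out")),
        seed=seed,
    )
    cfg.validate()
    return cfg
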