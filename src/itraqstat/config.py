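"""Flat run configuration for the end-to-end pipeline.

A run is described by a single flat key-value mapping (YAML on disk).
Simulation keys carry a ``sim_`` prefix and mirror the ``SimDesign``
fields (``sim_n_proteins``, ``sim_s_b``, ...); everything else is a
stage parameter.  Defaults reproduce the study settings the analysis
assumes: reference channel 114, minimum spectral count 2 for both
filters, ANOVA alpha 0.05, power 0.8, s_b 0.16, s_t 0.10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .synthetic_data import SimDesign, design_from_mapping

STAGES = ("simulate", "quantify", "stats", "power", "coverage")

_SIM_PREFIX = "sim_"


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "itraqstat_run"
    stages: tuple[str, ...] = STAGES
    log_level: str = "INFO"

    # quantify
    reference_channel: int = 114
    min_sc_id: int = 2
    min_sc_quant: int = 2

    # stats
    alpha: float = 0.05
    anova_log2: bool = False
    quantile_mode: str = "linear"
    min_workflow_reps: int = 2

    # power (s_b/s_t default to the stats stage's own estimates)
    power: float = 0.8
    power_mode: str = "approximate"
    power_n_min: int = 2
    power_n_max: int = 20
    power_m_min: int = 1
    power_m_max: int = 4

    # coverage (optional reference accession list)
    reference_list: str | None = None

    sim: SimDesign = field(default_factory=SimDesign)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.reference_channel not in (114, 115, 116, 117):
            raise ValueError("reference_channel must be one of 114-117")
        if self.min_sc_id < 1 or self.min_sc_quant < 1:
            raise ValueError("min_sc thresholds must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        self.sim.validate()


def config_from_mapping(params: dict) -> RunConfig:
    """Build a RunConfig from a flat mapping (e.g. a parsed YAML file)."""
    params = dict(params)
    sim_params = {
        key[len(_SIM_PREFIX) :]: params.pop(key)
        for key in list(params)
        if key.startswith(_SIM_PREFIX)
    }
    own = {f.name for f in fields(RunConfig)} - {"sim"}
    unknown = set(params) - own
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "stages" in params:
        params["stages"] = tuple(params["stages"])
    cfg = RunConfig(**params, sim=design_from_mapping(sim_params))
    # the global seed drives the simulation unless one was given explicitly
    if "seed" not in sim_params:
        cfg.sim.seed = cfg.seed
    cfg.validate()
    return cfg


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        params = yaml.safe_load(fh) or {}
    if not isinstance(params, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return config_from_mapping(params)


def config_to_mapping(cfg: RunConfig) -> dict:
    """Flatten a RunConfig back to the on-disk key-value form."""
    out = {}
    for f in fields(RunConfig):
        if f.name == "sim":
            continue
        v = getattr(cfg, f.name)
        out[f.name] = list(v) if isinstance(v, tuple) else v
    for f in fields(SimDesign):
        v = getattr(cfg.sim, f.name)
        out[_SIM_PREFIX + f.name] = list(v) if isinstance(v, tuple) else v
    return out
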