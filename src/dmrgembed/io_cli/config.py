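"""Run configuration: schema-validated YAML with strict unknown-key rejection."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from ..backend.system import ConfigurationError

__all__ = ["RunConfig", "load_config", "dump_config"]

_WF_SOLVERS = ("HF", "FCI", "DMRG")


@dataclass
class RunConfig:
    # geometry: either a fixture name (+params) or an XYZ path
    fixture: str | None = None
    fixture_params: dict = field(default_factory=dict)
    geometry: str | None = None              # path to XYZ
    basis: str = "sto-3g"
    active_atoms: list = field(default_factory=list)
    env_level: str = "hf"
    active_level: str = "hf"            # mean-field level inside the span
    wf_solver: str = "HF"
    mu: float = 1.0e6
    n_shells: int = 2
    all_virtuals: bool = False
    spade_k: int | None = None
    frozen_core: bool = False
    tre_target: float = 1.0e-6
    m_min: int = 2
    m_max: int = 256
    max_sweeps: int = 12
    e_conv: float = 1.0e-8
    warmup: str = "determinant+noise"
    use_fiedler: bool = False
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        if (self.fixture is None) == (self.geometry is None):
            raise ConfigurationError(
                "exactly one of 'fixture' or 'geometry' must be given")
        if self.wf_solver not in _WF_SOLVERS:
            raise ConfigurationError(
                f"wf_solver must be one of {_WF_SOLVERS}, got {self.wf_solver!r}")
        if not self.active_atoms:
            raise ConfigurationError("active_atoms must be non-empty")
        if self.mu <= 0 or self.tre_target < 0 or self.tre_target >= 1:
            raise ConfigurationError("mu must be > 0 and tre_target in [0, 1)")
        if self.n_shells < 1 or self.m_min > self.m_max:
            raise ConfigurationError("need n_shells >= 1 and m_min <= m_max")


def load_config(path) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown configuration keys {sorted(unknown)}")
    return RunConfig(**data)


def dump_config(cfg: RunConfig, path):
    with open(path, "w") as f:
        yaml.safe_dump(asdict(cfg), f, sort_keys=True)
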