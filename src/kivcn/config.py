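"""Run configuration: defaults, YAML round-trip, validation.

A flat key-value YAML file; unknown keys are rejected so typos fail loudly.
CLI options override file values.  Every pipeline output directory receives a
serialized copy of the effective configuration for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from . import simulator as _sim


@dataclass
class RunConfig:
    # database
    k: int = 31
    repeat_multiplicity: int = 6
    norm_multiplicity: int = 1
    # estimation
    diploid_factor: float = 2.0
    min_alt_count: int = 1
    # simulator
    unit_length: int = _sim.DEFAULT_UNIT_LENGTH
    n_units: int = _sim.DEFAULT_N_UNITS
    unit_divergence: float = _sim.DEFAULT_UNIT_DIVERGENCE
    norm_length: int = _sim.DEFAULT_NORM_LENGTH
    flank_length: int = _sim.DEFAULT_FLANK_LENGTH
    snp_rate: float = _sim.DEFAULT_SNP_RATE
    read_length: int = _sim.DEFAULT_READ_LENGTH
    insert_mean: float = _sim.DEFAULT_INSERT_MEAN
    insert_sd: float = _sim.DEFAULT_INSERT_SD
    # run
    seed: int = 1
    verbosity: str = "info"
    # paths (optional; subcommands require the ones they use)
    reference: str | None = None
    repeat_bed: str | None = None
    norm_bed: str | None = None
    db_dir: str | None = None
    panel: str | None = None

    def __post_init__(self) -> None:
        if not 2 <= self.k <= 31:
            raise ValueError("k must be in [2, 31]")
        if self.repeat_multiplicity < 1 or self.norm_multiplicity < 1:
            raise ValueError("multiplicities must be >= 1")
        if self.diploid_factor <= 0:
            raise ValueError("diploid_factor must be > 0")

    def require(self, *keys: str) -> None:
        for key in keys:
            if getattr(self, key) is None:
                raise ValueError(f"configuration key {key!r} is required but unset")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config (optional), apply overrides, validate.

    Unknown keys — in the file or the overrides — raise.
    """
    known = {f.name for f in fields(RunConfig)}
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: expected a mapping of keys to values")
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
        values.update(loaded)
    unknown = {k for k, v in overrides.items() if k not in known}
    if unknown:
        raise ValueError(f"unknown configuration keys {sorted(unknown)}")
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
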