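"""Run configuration: every analysis threshold in one declarative place.

Defaults are the framework's published operating points (strain-evidence
ANI gate 99.8%, CI gate 99.5%, alignment identity gate 99% with the
99-101% length window, recoverability gates 0.7/0.9, coverage gate 2.5x,
at most 3 strain clusters per species, D = 20 context samples). A YAML
file can override any field; the effective configuration can be dumped
back out so each run's provenance is self-contained.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # k-mer / sketching
    k: int = 21
    sketch_size: int = 1000
    # strain-evidence gate
    ani_gate: float = 99.8
    ci_gate: float = 99.5
    max_strains: int = 3
    # ground-truth alignment filter
    identity_gate: float = 99.0
    length_gate: tuple[float, float] = (0.99, 1.01)
    # downstream filters
    recall_gate: float = 0.7
    precision_gate: float = 0.9
    coverage_gate: float = 2.5
    # clustering / context
    strain_ani_cutoff: float = 98.0
    context_size: int = 20  # D nearest samples by Mash distance
    # simulation
    read_length: int = 126
    seed: int = 0
    binning_mode: str = "single"  # single | multi | partial_multi
    dialect_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.binning_mode not in ("single", "multi", "partial_multi"):
            raise ValueError(f"unknown binning_mode {self.binning_mode!r}")

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        data.update(overrides)
        if "length_gate" in data:
            data["length_gate"] = tuple(data["length_gate"])
        defaults = cls()
        for key, value in data.items():
            if not hasattr(defaults, key):
                raise ValueError(f"unknown configuration key {key!r}")
            if getattr(defaults, key) != value:
                logger.info("config override: %s = %r", key, value)
        return cls(**data)

    def dump(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["length_gate"] = list(payload["length_gate"])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
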