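"""Run configuration: thresholds, seeds, species declarations.

All analysis constants live here with their defaults: the homology E-value
cutoff (1e-5), the strong-conservation score cutoff (0.99), the profile
correlation thresholds (0.5, 0.7, 0.9), the dendrogram cut height (0.75),
the significance level (0.05) and the youngest-phylostratum boundary (8).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .copsets import DEFAULT_CLADES, DEFAULT_EXEMPT, DEFAULT_MODELS, DEFAULT_NEWICK
from .errors import ValidationError


@dataclass
class RunConfig:
    seed: int = 0
    evalue_threshold: float = 1e-5
    conservation_cutoff: float = 0.99
    correlation_thresholds: tuple[float, ...] = (0.5, 0.7, 0.9)
    cluster_cut_height: float = 0.75
    alpha: float = 0.05
    young_min: int = 8
    n_background_reps: int = 100
    newick: str = DEFAULT_NEWICK
    clades: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CLADES))
    model_species: tuple[str, ...] = tuple(sorted(DEFAULT_MODELS))
    exempt_species: tuple[str, ...] = tuple(sorted(DEFAULT_EXEMPT))
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.conservation_cutoff < 1:
            raise ValidationError("conservation cutoff must lie in (0, 1)")
        if self.evalue_threshold <= 0:
            raise ValidationError("E-value threshold must be positive")
        if self.cluster_cut_height <= 0:
            raise ValidationError("cluster cut height must be positive")
        if any(not -1 <= t <= 1 for t in self.correlation_thresholds):
            raise ValidationError("correlation thresholds must lie in [-1, 1]")
        if self.young_min < 1:
            raise ValidationError("young_min must be a positive stratum index")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load a YAML (or TOML) key-value config; absent keys take defaults.

    Unknown keys raise an error listing the valid ones.
    """
    data: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".toml", ".tml"):
            import tomllib

            data = tomllib.loads(text)
        else:
            data = yaml.safe_load(text) or {}
    if overrides:
        data.update(overrides)
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValidationError(
            f"unknown config key(s) {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    for key in ("correlation_thresholds", "model_species", "exempt_species"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)
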