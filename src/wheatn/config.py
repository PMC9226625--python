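"""Run configuration: defaults, YAML round-trip, strict validation.

A run is fully described by a :class:`RunConfig`; every stage of the
pipeline consumes only this object plus prior-stage files, and all
randomness flows from its single root seed (split deterministically per
stage), so stages are independently re-runnable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .comparison import DEFAULT_COMBO_GRID
from .indices import TARGETS, ZONES
from .modeling import DEFAULT_RFR_GRID

__all__ = ["RunConfig", "load_config", "save_config"]

_ZONE_SETS = ("AZ1", "AZ2", "AZ1+2")
_STRATEGIES = ("pcc", "virrfr", "both")
_GRID_KEYS = {"n_estimators", "max_depth", "min_samples_split"}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``rfr_grid`` accepts the literal string ``"full"`` for the exhaustive
    360-point tuning grid; the default is the reduced grid that keeps a
    whole-study run tractable on one CPU (see docs/methods.md).
    """

    seed: int = 42
    out_dir: str = "wheatn_run"
    train_fraction: float = 0.7
    folds: int = 5
    rfr_grid: dict = field(default_factory=lambda: dict(DEFAULT_COMBO_GRID))
    selection_strategy: str = "both"
    use_all_variables: bool = False
    zones: list = field(default_factory=lambda: list(_ZONE_SETS))
    targets: list = field(default_factory=lambda: list(TARGETS))
    replicate_scale: float = 1.0  # shrink replicates for quick runs

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed: must be an integer")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction: must lie strictly between 0 and 1")
        if self.folds < 2:
            raise ValueError("folds: must be at least 2")
        if self.rfr_grid == "full":
            self.rfr_grid = dict(DEFAULT_RFR_GRID)
        if not isinstance(self.rfr_grid, dict) or not set(self.rfr_grid) <= _GRID_KEYS:
            raise ValueError(f"rfr_grid: keys must be a subset of {sorted(_GRID_KEYS)}")
        for k, v in self.rfr_grid.items():
            if not v or any(int(c) != c or c < 1 for c in v):
                raise ValueError(f"rfr_grid.{k}: needs a non-empty positive-int list")
        if self.selection_strategy not in _STRATEGIES:
            raise ValueError(f"selection_strategy: must be one of {_STRATEGIES}")
        bad = [z for z in self.zones if z not in _ZONE_SETS]
        if bad:
            raise ValueError(f"zones: unknown entries {bad}")
        bad = [t for t in self.targets if t not in TARGETS]
        if bad:
            raise ValueError(f"targets: unknown entries {bad}")
        if not 0.0 < self.replicate_scale <= 1.0:
            raise ValueError("replicate_scale: must lie in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML config; omitted keys take defaults, unknown keys error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ValueError(str(exc)) from exc


def save_config(config: RunConfig, path) -> None:
    """Write the normalized configuration back to YAML (lossless)."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False)
    )
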