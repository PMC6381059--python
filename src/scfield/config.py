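"""Declarative run configuration with lossless YAML round-tripping.

An empty configuration reproduces the baseline simulation; every field
constant, timeline event, latency window and post-hoc option can be
overridden.  The manifest written with each run is a serialized RunConfig
plus the package version, and suffices to reproduce the run bit-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Tuple, Union

import yaml

from .engine import RunOptions
from .params import ClassificationWindows, FieldParams, TrialTimeline

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class GridOptions:
    """Which part of the factorial design to run."""

    tasks: Tuple[str, ...] = ("pro", "anti")
    side: str = "right"
    limit: Optional[int] = None  # truncate each task block (smoke runs)


@dataclass(frozen=True)
class RunConfig:
    schema_version: int = SCHEMA_VERSION
    field: FieldParams = dc_field(default_factory=FieldParams)
    timeline: TrialTimeline = dc_field(default_factory=TrialTimeline)
    windows: ClassificationWindows = dc_field(default_factory=ClassificationWindows)
    grid: GridOptions = dc_field(default_factory=GridOptions)
    options: RunOptions = dc_field(default_factory=RunOptions)

    def is_baseline(self) -> bool:
        """True when every parameter equals the baseline simulation's."""
        return self == RunConfig()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["options"]["ablations"] = sorted(self.options.ablations)
        d["grid"]["tasks"] = list(self.grid.tasks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        version = d.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        opts = dict(d.get("options", {}))
        if "ablations" in opts:
            opts["ablations"] = frozenset(opts["ablations"])
        grid = dict(d.get("grid", {}))
        if "tasks" in grid:
            grid["tasks"] = tuple(grid["tasks"])
        return cls(
            field=FieldParams(**d.get("field", {})),
            timeline=TrialTimeline(**d.get("timeline", {})),
            windows=ClassificationWindows(**d.get("windows", {})),
            grid=GridOptions(**grid),
            options=RunOptions(**opts),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


__all__ = ["SCHEMA_VERSION", "GridOptions", "RunConfig"]
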