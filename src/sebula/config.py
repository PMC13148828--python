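"""Validated run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All pipeline defaults in one validated record.

    Field defaults mirror the per-module defaults: 900 bp insert cap,
    coverage >= 3 for a high-coverage locus, 120 histogram bins, 7 spline
    degrees of freedom, a 20th-60th percentile central window, lfdr call
    threshold 0.8, tail-FDR target 0.2, and automatic truncation-point
    selection.
    """

    max_insert: int = 900
    min_cov: int = 3
    bins: int = 120
    spline_df: int = 7
    window: tuple[float, float] = (20.0, 60.0)
    lfdr_threshold: float = 0.8
    fdr_target: float = 0.2
    x_min: int | str = 0
    min_cells: int = 200

    def __post_init__(self) -> None:
        if self.max_insert <= 0:
            raise ValueError("max_insert must be positive")
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if self.bins < 20:
            raise ValueError("bins must be >= 20")
        if self.spline_df < 3:
            raise ValueError("spline_df must be >= 3")
        lo, hi = self.window
        if not 0 <= lo < hi <= 100:
            raise ValueError(f"window must be percentiles 0 <= lo < hi <= 100, got {self.window}")
        if not 0 < self.lfdr_threshold < 1:
            raise ValueError("lfdr_threshold must be in (0, 1)")
        if not 0 < self.fdr_target < 1:
            raise ValueError("fdr_target must be in (0, 1)")
        if self.x_min != "auto":
            if not isinstance(self.x_min, int) or self.x_min < 0:
                raise ValueError("x_min must be 'auto' or a non-negative integer")
        if self.min_cells < 50:
            raise ValueError("min_cells must be >= 50")
        self.window = (float(lo), float(hi))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a YAML mapping; keyword overrides win over the file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "window" in data:
            data["window"] = tuple(data["window"])
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = list(self.window)
        return d
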