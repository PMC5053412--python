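"""Run configuration: one dataclass holding every tunable stage parameter.

Defaults follow the published operating point where one exists (10-px
spur threshold, gray-level 64 channel mean cutoff, 3..11 scale-space
windows, twelve 15-degree kernels, diagnostic-region multipliers 4/6/8);
the remaining defaults are this package's documented design choices.
Configs round-trip through YAML; CLI flags override file values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    method: str = "morphology"            # morphology | matched_filter | scale_space
    # preprocessing
    eye_margin: int = 5                   # px, eye-mask erosion after ring removal
    mean_cutoff: float = 64.0             # gray levels, channel mean rule
    # segmentation
    blur_length: int = 9                  # px, oriented unsharp mask
    sigma: float = 2.0                    # px, matched-filter cross-profile
    kernel_length: float = 9.0            # px, matched-filter axis length
    island_min: int = 20                  # px, per-scale island removal
    od_halo: int = 5                      # px, OD-boundary exclusion widening
    # skeleton post-processing
    spur_len: int = 10                    # px, terminal-branch pruning
    prune_passes: int = 1
    area_min: int = 20                    # px, post-hoc segment area threshold
    area_threshold_morphology: bool = False   # applied to the other two by default
    # features
    tortuosity_mode: str = "arc_chord"    # arc_chord | literal
    loop_cap: float = 10.0
    percentile: float = 75.0
    # classifier
    ridge: float = 1e-6
    standardize: bool = True
    # bookkeeping
    seed: int = 0
    outdir: str = "ropscreen-out"

    _METHODS = ("morphology", "matched_filter", "scale_space")

    def __post_init__(self) -> None:
        if self.method not in self._METHODS:
            raise ValueError(f"method must be one of {self._METHODS}")
        if self.spur_len < 0 or self.area_min < 0 or self.island_min < 0:
            raise ValueError("pixel thresholds must be non-negative")
        if self.tortuosity_mode not in ("arc_chord", "literal"):
            raise ValueError("tortuosity_mode must be arc_chord or literal")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must lie in (0, 100]")

    @property
    def apply_area_threshold(self) -> bool:
        """The area threshold is standard for the matched-filter and
        scale-space networks (their raw output is fragmentary) and
        optional for morphology."""
        if self.method == "morphology":
            return self.area_threshold_morphology
        return True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
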