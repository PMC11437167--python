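"""Run configuration for the two workflow variants.

``hpc_two_season`` is the full workflow: summer (Jun-Sep) and winter
(Nov-Apr) median composites, 16 feature layers including the inter-seasonal
SAVI/NDWI differences, a dual random forest fused by per-pixel minimum
probability, and a probability output thresholded at the kappa optimum.

``gee_four_season`` mirrors the cloud-platform variant: four two-month
seasons (Feb-Mar, Jun-Jul, Aug-Sep, Nov-Dec), 28 feature layers with no
difference features, a single unbalanced forest with sqrt(k) variables per
split, and presence/absence output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import FOUR_SEASON_WINDOWS, TWO_SEASON_WINDOWS, validate_season_windows


@dataclass
class RunConfig:
    workflow: str = "hpc_two_season"
    season_windows: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_trees: int = 500
    vars_per_split: int | str = 3
    fusion: str = "dual_min"          # dual_min | single
    output: str = "probability"       # probability | presence
    balanced_second_forest: bool = True
    n_points_per_polygon: int = 100
    dos_percentile: float = 0.01
    max_shift: int = 3
    min_valid_fraction: float = 0.03
    slope_max: float = 10.0           # degrees
    alt_max: float = 470.0            # metres
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.workflow not in ("hpc_two_season", "gee_four_season"):
            raise ValueError(f"unknown workflow {self.workflow!r}")
        if not self.season_windows:
            self.season_windows = dict(
                TWO_SEASON_WINDOWS if self.workflow == "hpc_two_season"
                else FOUR_SEASON_WINDOWS)
        self.season_windows = {s: tuple(w) for s, w in self.season_windows.items()}
        validate_season_windows(self.season_windows)
        if self.workflow == "gee_four_season":
            # platform constraints of the four-season variant
            self.fusion = "single"
            self.output = "presence"
            self.vars_per_split = "sqrt"
            self.balanced_second_forest = False

    @property
    def season_mode(self) -> str:
        return "two_season" if self.workflow == "hpc_two_season" else "four_season"

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["season_windows"] = {s: list(w) for s, w in self.season_windows.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)
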