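"""Core grid containers and season calendars.

All rasters live on a single 10 m pixel grid: 0-based (row, col) with the
origin at the top-left, rows increasing southwards.  Spectral data are
unitless top-of-atmosphere-style reflectances, nominally in [0, 1].

Band order follows the Sentinel-2 MSI convention with B8A slotted after B8,
giving 13 bands: B1, B2, B3, B4, B5, B6, B7, B8, B8A, B9, B10, B11, B12.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

BAND_NAMES: tuple[str, ...] = (
    "B1", "B2", "B3", "B4", "B5", "B6", "B7",
    "B8", "B8A", "B9", "B10", "B11", "B12",
)
N_BANDS = len(BAND_NAMES)
BAND_INDEX = {name: i for i, name in enumerate(BAND_NAMES)}

#: Season calendars as {label: (start_month, end_month)}; windows are
#: inclusive of both months and may wrap the year end (e.g. Nov-Apr).
TWO_SEASON_WINDOWS: dict[str, tuple[int, int]] = {
    "summer": (6, 9),   # reedbed 'green'
    "winter": (11, 4),  # reedbed 'brown'
}
FOUR_SEASON_WINDOWS: dict[str, tuple[int, int]] = {
    "feb_mar": (2, 3),
    "jun_jul": (6, 7),
    "aug_sep": (8, 9),
    "nov_dec": (11, 12),
}


class ReedmapError(Exception):
    """Base class for pipeline errors."""


class NoValidPixelsError(ReedmapError):
    pass


class RegistrationFailureError(ReedmapError):
    """Co-registration refused: secondary image has too little valid content."""


class SeasonError(ReedmapError):
    """A date maps to no season, or a season lacks coverage."""


class GridMismatchError(ReedmapError):
    pass


def month_in_window(month: int, window: tuple[int, int]) -> bool:
    lo, hi = window
    if lo <= hi:
        return lo <= month <= hi
    return month >= lo or month <= hi  # wraps the year end


def season_of(date: dt.date, season_windows: dict[str, tuple[int, int]]) -> str | None:
    """Return the season label for ``date``, or None if it falls in a gap.

    Raises :class:`SeasonError` if windows overlap on the date's month.
    """
    hits = [s for s, w in season_windows.items() if month_in_window(date.month, w)]
    if len(hits) > 1:
        raise SeasonError(f"date {date} falls in overlapping seasons {hits}")
    return hits[0] if hits else None


def validate_season_windows(season_windows: dict[str, tuple[int, int]]) -> None:
    """Check that no calendar month belongs to more than one window."""
    for m in range(1, 13):
        hits = [s for s, w in season_windows.items() if month_in_window(m, w)]
        if len(hits) > 1:
            raise SeasonError(f"month {m} belongs to overlapping seasons {hits}")


@dataclass
class MultibandPass:
    """One satellite acquisition: 13 reflectance grids, a date, a validity mask."""

    bands: np.ndarray  # (13, H, W) float
    date: dt.date
    valid_mask: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.bands.ndim != 3 or self.bands.shape[0] != N_BANDS:
            raise ValueError(f"bands must be ({N_BANDS}, H, W), got {self.bands.shape}")
        if self.valid_mask.shape != self.bands.shape[1:]:
            raise GridMismatchError(
                f"valid_mask shape {self.valid_mask.shape} != grid {self.bands.shape[1:]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    def band(self, name: str) -> np.ndarray:
        return self.bands[BAND_INDEX[name]]

    @property
    def valid_fraction(self) -> float:
        return float(self.valid_mask.mean())

    def copy(self) -> "MultibandPass":
        return MultibandPass(self.bands.copy(), self.date, self.valid_mask.copy())


@dataclass
class SeasonalComposite:
    """Per-season per-band median reflectance with per-pixel pass counts."""

    season: str
    bands: np.ndarray      # (13, H, W); NaN where coverage == 0
    coverage: np.ndarray   # (H, W) int

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        self.coverage = np.asarray(self.coverage)
        if self.coverage.shape != self.bands.shape[1:]:
            raise GridMismatchError("coverage shape does not match bands")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    @property
    def valid(self) -> np.ndarray:
        return self.coverage > 0

    def band(self, name: str) -> np.ndarray:
        return self.bands[BAND_INDEX[name]]


@dataclass
class FeatureStack:
    """Named spectral-index layers aligned to the 10 m grid.

    ``season_mode`` is ``two_season`` (7 indices x 2 seasons + dSAVI, dNDWI
    = 16 layers) or ``four_season`` (7 x 4 = 28 layers, no differences).
    Invalid pixels are NaN.
    """

    layers: np.ndarray  # (L, H, W)
    names: list[str]
    season_mode: str

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.shape[0] != len(self.names):
            raise ValueError("layer count does not match names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers.shape[1:]

    @property
    def valid(self) -> np.ndarray:
        """Pixels with a complete (all-finite) feature vector."""
        return np.isfinite(self.layers).all(axis=0)

    def layer(self, name: str) -> np.ndarray:
        return self.layers[self.names.index(name)]

    def matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_pixels, L) feature matrix over ``mask`` (default: valid pixels)."""
        if mask is None:
            mask = self.valid
        return self.layers[:, mask].T


@dataclass
class ReedProbabilityMap:
    """Per-pixel reedbed probability at 10 m with a presence threshold."""

    p: np.ndarray  # (H, W); NaN invalid
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.p)

    @property
    def presence(self) -> np.ndarray:
        """Boolean presence grid: p > threshold on valid pixels."""
        if self.threshold is None:
            raise ValueError("threshold not set")
        out = np.zeros(self.p.shape, dtype=bool)
        v = self.valid
        out[v] = self.p[v] > self.threshold
        return out


@dataclass
class HectareCoverMap:
    """Proportional reedbed cover on the 100 m (1 ha) grid; NaN invalid."""

    cover: np.ndarray  # (h, w) float in [0, 1]
    valid_pixels: np.ndarray | None = None  # (h, w) count of valid 10 m pixels

    def __post_init__(self) -> None:
        self.cover = np.asarray(self.cover, dtype=float)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.cover)

    def copy(self) -> "HectareCoverMap":
        vp = None if self.valid_pixels is None else self.valid_pixels.copy()
        return HectareCoverMap(self.cover.copy(), vp)
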