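"""Terrain masking, hectare aggregation, mosaicking and extent totals.

The 10 m presence map is block-averaged to proportional cover on the 100 m
(1 ha) grid; hectare cells on slopes above 10 degrees or above 470 m (the
highest recorded altitude for Reed in Britain) are zeroed, since reedbed
cannot occur there; extent is the sum of cover over valid hectare cells.
"""

from __future__ import annotations

import numpy as np

from .core import GridMismatchError, HectareCoverMap


def slope_from_dem(dem: np.ndarray, cell_size: float = 10.0) -> np.ndarray:
    """Slope in degrees from a DEM via Horn's 3x3 finite differences.

    ``cell_size`` is the pixel edge in the same units as the DEM values
    (metres).  Edge cells use replicated margins.
    """
    dem = np.asarray(dem, dtype=float)
    if dem.ndim != 2 or min(dem.shape) < 2:
        raise ValueError("DEM must be at least 2x2")
    z = np.pad(dem, 1, mode="edge")
    # neighbours: z1 z2 z3 / z4 . z6 / z7 z8 z9 (row-major, top-left z1)
    z1, z2, z3 = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    z4, z6 = z[1:-1, :-2], z[1:-1, 2:]
    z7, z8, z9 = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((z3 + 2 * z6 + z9) - (z1 + 2 * z4 + z7)) / (8.0 * cell_size)
    dzdy = ((z7 + 2 * z8 + z9) - (z1 + 2 * z2 + z3)) / (8.0 * cell_size)
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


def block_reduce_mean(grid: np.ndarray, valid: np.ndarray, block: int = 10
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Mean of ``grid`` over ``block`` x ``block`` origin-aligned tiles.

    Returns (means, valid_counts); partial edge blocks use the pixels they
    have.  Cells with zero valid pixels are NaN.
    """
    h, w = grid.shape
    r_edges = np.arange(0, h, block)
    c_edges = np.arange(0, w, block)
    vals = np.where(valid, grid, 0.0)
    sums = np.add.reduceat(np.add.reduceat(vals, r_edges, axis=0), c_edges, axis=1)
    counts = np.add.reduceat(np.add.reduceat(valid.astype(float), r_edges, axis=0),
                             c_edges, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    return means, counts


def aggregate_to_hectare(
    presence: np.ndarray, valid: np.ndarray | None = None, block: int = 10
) -> HectareCoverMap:
    """10 m presence -> 100 m proportional cover.

    cover = (presence pixels) / (valid pixels) per block, so
    sum(cover x valid-count) over blocks conserves the presence pixel count.
    """
    presence = np.asarray(presence, dtype=bool)
    if valid is None:
        valid = np.ones(presence.shape, dtype=bool)
    cover, counts = block_reduce_mean(presence.astype(float), valid, block)
    return HectareCoverMap(cover, counts)


def terrain_mask(
    cover: HectareCoverMap,
    slope: np.ndarray,
    altitude: np.ndarray,
    slope_max: float = 10.0,
    alt_max: float = 470.0,
) -> HectareCoverMap:
    """Zero cover where slope > slope_max degrees or altitude > alt_max m.

    Inequalities are strict: cells at exactly 10 degrees / 470 m survive.
    Invalid cells stay invalid.
    """
    if slope.shape != cover.cover.shape or altitude.shape != cover.cover.shape:
        raise GridMismatchError("slope/altitude grids not aligned with cover map")
    out = cover.copy()
    kill = (slope > slope_max) | (altitude > alt_max)
    out.cover[kill & cover.valid] = 0.0
    return out


def mosaic(maps: list[HectareCoverMap], rule: str = "mean") -> HectareCoverMap:
    """Combine overlapping cover maps on a common grid.

    Per cell: mean (default), min or max of the valid values; cells valid in
    no map stay invalid.
    """
    if not maps:
        raise ValueError("no maps to mosaic")
    shape = maps[0].cover.shape
    for m in maps[1:]:
        if m.cover.shape != shape:
            raise GridMismatchError("mosaic inputs must share one grid")
    stack = np.stack([m.cover for m in maps])
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        if rule == "mean":
            out = np.nanmean(stack, axis=0)
        elif rule == "min":
            out = np.nanmin(stack, axis=0)
        elif rule == "max":
            out = np.nanmax(stack, axis=0)
        else:
            raise ValueError(f"unknown mosaic rule {rule!r}")
    counts = None
    if all(m.valid_pixels is not None for m in maps):
        counts = np.nanmax(np.stack([m.valid_pixels for m in maps]), axis=0)
    return HectareCoverMap(out, counts)


def total_extent(cover: HectareCoverMap) -> float:
    """Total mapped extent in hectares: sum of cover over valid 1 ha cells."""
    return float(np.nansum(cover.cover))
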