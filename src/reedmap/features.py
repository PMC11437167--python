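"""Spectral index layers for classification.

Seven indices per seasonal composite — NDVI, NDWI, SAVI, EVI, RG, GB, SB4 —
plus, in two-season mode, the summer-winter differences in SAVI and NDWI.
NDWI is the McFeeters green/NIR form (water-positive), which is what makes
winter-flooded reedbed light up against dry senescent grass.  SB4 is band 4
standardised by total 13-band brightness.  Zero denominators yield invalid
(NaN) pixels rather than exceptions.
"""

from __future__ import annotations

import numpy as np

from .core import FeatureStack, SeasonalComposite

INDEX_NAMES = ("NDVI", "NDWI", "SAVI", "EVI", "RG", "GB", "SB4")


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    return out


def compute_index(composite: SeasonalComposite, index_name: str) -> np.ndarray:
    """One index grid from a seasonal composite; NaN where undefined/invalid."""
    if index_name not in INDEX_NAMES:
        raise ValueError(f"unknown index {index_name!r}; expected one of {INDEX_NAMES}")
    b2 = composite.band("B2")
    b3 = composite.band("B3")
    b4 = composite.band("B4")
    b8 = composite.band("B8")
    with np.errstate(invalid="ignore", divide="ignore"):
        if index_name == "NDVI":
            out = _ratio(b8 - b4, b8 + b4)
        elif index_name == "NDWI":
            out = _ratio(b3 - b8, b3 + b8)
        elif index_name == "SAVI":
            out = 1.5 * _ratio(b8 - b4, b8 + b4 + 0.5)
        elif index_name == "EVI":
            out = 2.5 * _ratio(b8 - b4, b8 + 6.0 * b4 - 7.5 * b2 + 1.0)
        elif index_name == "RG":
            out = _ratio(b4, b3)
        elif index_name == "GB":
            out = _ratio(b3, b2)
        else:  # SB4
            out = _ratio(b4, composite.bands.sum(axis=0))
    out[~composite.valid] = np.nan
    return out


def build_feature_stack(
    composites: list[SeasonalComposite], season_mode: str = "two_season"
) -> FeatureStack:
    """Assemble the named index stack over all seasons.

    two_season: 7 indices x {summer, winter} + dSAVI + dNDWI = 16 layers.
    four_season: 7 indices x 4 seasons = 28 layers, no difference layers
    (differences are only defined for the summer/winter pair).
    Layer order is stable: indices in INDEX_NAMES order within each season,
    seasons in input order, differences last.
    """
    if season_mode not in ("two_season", "four_season"):
        raise ValueError(f"unknown season_mode {season_mode!r}")
    seasons = [c.season for c in composites]
    n_expected = 2 if season_mode == "two_season" else 4
    if len(composites) != n_expected:
        raise ValueError(
            f"{season_mode} mode needs {n_expected} composites, got {len(composites)}"
        )
    if season_mode == "two_season" and set(seasons) != {"summer", "winter"}:
        raise ValueError("two_season mode requires 'summer' and 'winter' composites")
    layers, names = [], []
    index_of: dict[str, np.ndarray] = {}
    for c in composites:
        for idx in INDEX_NAMES:
            grid = compute_index(c, idx)
            layers.append(grid)
            names.append(f"{idx}_{c.season}")
            index_of[f"{idx}_{c.season}"] = grid
    if season_mode == "two_season":
        for idx in ("SAVI", "NDWI"):
            diff = index_of[f"{idx}_summer"] - index_of[f"{idx}_winter"]
            layers.append(diff)
            names.append(f"d{idx}")
    return FeatureStack(np.stack(layers), names, season_mode)
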