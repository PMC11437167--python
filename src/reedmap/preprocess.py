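"""Pass-level corrections and seasonal median compositing.

Order of operations in the pipeline: dark-object subtraction, cloud masking
with a random-forest cloud model, integer co-registration against a
reference pass, then per-season per-band median compositing.  The median is
also the cloud-shadow defence: the cloud model cannot see shadows, so a
shadowed pass must be out-voted by clean passes within the season.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .core import (
    BAND_INDEX,
    N_BANDS,
    GridMismatchError,
    MultibandPass,
    NoValidPixelsError,
    RegistrationFailureError,
    SeasonalComposite,
    SeasonError,
    season_of,
)
from .synthetic_scene import translate_grid
from .vector import TruthPolygon, rasterize_polygon


def dark_object_subtract(p: MultibandPass, percentile: float = 0.01) -> MultibandPass:
    """Image-based haze correction: subtract each band's dark-object value.

    The dark object is the given low percentile of valid pixels (default the
    1st percentile, which resists single-pixel artefacts better than the
    minimum); the result is clamped at 0 and the validity mask is unchanged.
    """
    if not p.valid_mask.any():
        raise NoValidPixelsError("dark_object_subtract: pass has no valid pixels")
    bands = p.bands.copy()
    dark = np.quantile(p.bands[:, p.valid_mask], percentile, axis=1)
    bands -= dark[:, None, None]
    np.clip(bands, 0.0, None, out=bands)
    return MultibandPass(bands, p.date, p.valid_mask.copy())


@dataclass
class CloudModel:
    """Random-forest cloud classifier over the 13 raw bands."""

    classifier: RandomForestClassifier
    oob_error: float

    @property
    def cloud_class_index(self) -> int:
        return list(self.classifier.classes_).index("cloud")


def train_cloud_model(
    passes: list[MultibandPass],
    cloud_polygons: list[tuple[int, TruthPolygon]],
    n_trees: int = 500,
    vars_per_split: int = 3,
    seed: int = 0,
    max_pixels_per_polygon: int = 400,
) -> CloudModel:
    """Train the cloud/non-cloud forest on labelled polygons.

    ``cloud_polygons`` holds (pass_index, polygon) pairs labelled 'cloud' or
    'clear'.  Features are the 13 band reflectances of valid pixels inside
    each polygon (subsampled to ``max_pixels_per_polygon``).  The model
    reports its out-of-bag error estimate.
    """
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for ipass, poly in cloud_polygons:
        p = passes[ipass]
        mask = rasterize_polygon(poly.geometry, p.shape) & p.valid_mask
        rr, cc = np.nonzero(mask)
        if rr.size == 0:
            continue
        if rr.size > max_pixels_per_polygon:
            keep = rng.choice(rr.size, max_pixels_per_polygon, replace=False)
            rr, cc = rr[keep], cc[keep]
        X_parts.append(p.bands[:, rr, cc].T)
        y_parts.append(np.full(rr.size, poly.label))
    if not X_parts:
        raise ValueError("no training pixels found inside cloud polygons")
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    if len(np.unique(y)) < 2:
        raise ValueError("cloud training set contains a single class")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=vars_per_split,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return CloudModel(clf, 1.0 - float(clf.oob_score_))


def mask_clouds(p: MultibandPass, model: CloudModel) -> MultibandPass:
    """Invalidate every pixel the cloud model predicts as cloud."""
    out = p.copy()
    rr, cc = np.nonzero(p.valid_mask)
    if rr.size == 0:
        return out
    X = p.bands[:, rr, cc].T
    if X.shape[1] != model.classifier.n_features_in_:
        raise GridMismatchError("pass band count does not match cloud model")
    pred = model.classifier.predict(X)
    cloudy = pred == "cloud"
    out.valid_mask[rr[cloudy], cc[cloudy]] = False
    return out


def estimate_shift(
    reference: MultibandPass,
    secondary: MultibandPass,
    max_shift: int = 3,
    band: str = "B8",
    min_valid_fraction: float = 0.03,
) -> tuple[int, int]:
    """Estimate the integer (dx, dy) translation of ``secondary`` vs the reference.

    Scans all shifts in [-max_shift, max_shift]^2 and returns the one
    maximising the normalised cross-correlation of the registration band
    (NIR by default) over the jointly valid overlap.  Ties are broken by the
    smallest |dx|+|dy|, then row-major order.  A secondary with less than
    ``min_valid_fraction`` valid content raises
    :class:`RegistrationFailureError`; callers drop such passes.
    """
    if reference.shape != secondary.shape:
        raise GridMismatchError("reference and secondary grids differ in shape")
    if secondary.valid_fraction < min_valid_fraction:
        raise RegistrationFailureError(
            f"secondary valid fraction {secondary.valid_fraction:.3f} "
            f"< {min_valid_fraction:.0%}: pass should be dropped"
        )
    ib = BAND_INDEX[band]
    ref_b, ref_v = reference.bands[ib], reference.valid_mask
    sec_b, sec_v = secondary.bands[ib], secondary.valid_mask
    h, w = reference.shape
    best: tuple[float, int, tuple[int, int]] | None = None
    order = 0
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            # candidate alignment: sec[r + dy, c + dx] should match ref[r, c]
            r0, r1 = max(0, -dy), min(h, h - dy)
            c0, c1 = max(0, -dx), min(w, w - dx)
            if r1 <= r0 or c1 <= c0:
                continue
            a = ref_b[r0:r1, c0:c1]
            b = sec_b[r0 + dy:r1 + dy, c0 + dx:c1 + dx]
            m = ref_v[r0:r1, c0:c1] & sec_v[r0 + dy:r1 + dy, c0 + dx:c1 + dx]
            if m.sum() < 9:
                continue
            av, bv = a[m], b[m]
            sa, sb = av.std(), bv.std()
            if sa == 0 or sb == 0:
                score = -1.0
            else:
                score = float(np.mean((av - av.mean()) * (bv - bv.mean())) / (sa * sb))
            cand = (-score, abs(dx) + abs(dy), order, (dx, dy))
            if best is None or cand[:3] < best[:3]:
                best = cand
            order += 1
    if best is None:
        raise RegistrationFailureError("no overlapping valid pixels at any shift")
    return best[3]


def apply_shift(p: MultibandPass, shift: tuple[int, int]) -> MultibandPass:
    """Undo an estimated shift: translate the pass by (-dx, -dy).

    The margin exposed by the translation is flagged invalid.
    """
    dx, dy = shift
    if abs(dx) > 3 or abs(dy) > 3:
        raise ValueError("shift components must be <= 3 pixels")
    if (dx, dy) == (0, 0):
        return p.copy()
    bands = translate_grid(p.bands, -dx, -dy, 0.0)
    valid = translate_grid(p.valid_mask, -dx, -dy, False)
    return MultibandPass(bands, p.date, valid)


def seasonal_median_composite(
    passes: list[MultibandPass],
    season_windows: dict[str, tuple[int, int]],
    seasons: list[str] | None = None,
) -> list[SeasonalComposite]:
    """Per-pixel per-band median over valid contributions, per season.

    Passes whose dates fall in no window are ignored.  Even contribution
    counts take the mean of the two central values; pixels valid in no pass
    are invalid (NaN).  A requested season with zero passes raises
    :class:`SeasonError`.
    """
    if seasons is None:
        seasons = list(season_windows)
    by_season: dict[str, list[MultibandPass]] = {s: [] for s in seasons}
    for p in passes:
        s = season_of(p.date, season_windows)
        if s in by_season:
            by_season[s].append(p)
    missing = [s for s in seasons if not by_season[s]]
    if missing:
        raise SeasonError(f"no passes available for season(s): {', '.join(missing)}")
    out: list[SeasonalComposite] = []
    for s in seasons:
        group = by_season[s]
        stack = np.stack([p.bands for p in group])  # (P, 13, H, W)
        vmask = np.stack([p.valid_mask for p in group])  # (P, H, W)
        stack = np.where(vmask[:, None, :, :], stack, np.nan)
        import warnings as _warnings
        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
            med = np.nanmedian(stack, axis=0)
        coverage = vmask.sum(axis=0)
        med[:, coverage == 0] = np.nan
        out.append(SeasonalComposite(s, med, coverage))
    return out
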