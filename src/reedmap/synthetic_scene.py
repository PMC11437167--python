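"""Synthetic multi-temporal landscape generator.

Builds labelled land-cover maps and 13-band acquisition stacks with the
statistical structure the mapping pipeline assumes: a rare reedbed class in
contiguous monodominant patches, spectrally confusable agricultural classes,
class-specific seasonal phenology (reedbed 'green' in summer, 'brown' in
winter), clouds with displaced shadows, integer inter-pass mis-registration,
and per-pass multiplicative/additive reflectance error.

Reflectance profiles are free parameters of the simulator (nothing
quantitative is published for reedbed at Sentinel-2 bands); defaults are
plausible L1C-like values chosen once and documented in docs/methods.md.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    BAND_NAMES,
    N_BANDS,
    TWO_SEASON_WINDOWS,
    MultibandPass,
    SeasonError,
    season_of,
)
from .vector import TruthPolygon, mask_to_polygon

# ---------------------------------------------------------------------------
# Phenology
# ---------------------------------------------------------------------------


@dataclass
class ClassPhenology:
    """Seasonal 13-band reflectance model for one land-cover class.

    ``season_means`` holds one 13-vector per season label; ``band_sd`` is the
    per-band Gaussian reflectance scatter; ``latitude_shift`` delays the
    phenological calendar by so many days per km of northing (the 'green'
    season starts later and ends earlier further north).
    """

    class_id: str
    season_means: dict[str, np.ndarray]
    band_sd: np.ndarray
    latitude_shift: float = 0.0  # days per km northing

    def __post_init__(self) -> None:
        self.season_means = {
            s: np.asarray(v, dtype=float) for s, v in self.season_means.items()
        }
        self.band_sd = np.asarray(self.band_sd, dtype=float)
        for s, v in self.season_means.items():
            if v.shape != (N_BANDS,):
                raise ValueError(f"{self.class_id}/{s}: need {N_BANDS} band means")
            if (v < 0).any() or (v > 1).any():
                raise ValueError(f"{self.class_id}/{s}: means outside [0, 1]")
        if self.band_sd.shape != (N_BANDS,):
            raise ValueError("band_sd must have one entry per band")
        if (self.band_sd < 0).any():
            raise ValueError("band_sd must be >= 0")


def _profile(blue: float, green: float, red: float, nir: float,
             swir1: float, swir2: float) -> np.ndarray:
    """13-band vector from six anchor reflectances (red-edge interpolated)."""
    re1 = red + (nir - red) * 0.3
    re2 = red + (nir - red) * 0.6
    re3 = red + (nir - red) * 0.85
    return np.array([
        blue * 0.9,        # B1 coastal aerosol
        blue,              # B2
        green,             # B3
        red,               # B4
        re1, re2, re3,     # B5-B7 red edge
        nir,               # B8
        min(nir * 1.03, 1.0),  # B8A
        0.10,              # B9 water vapour
        0.02,              # B10 cirrus
        swir1,             # B11
        swir2,             # B12
    ])


# 'green' (growing) and 'brown' (senescent/bare) anchor profiles per class.
_GREEN = {
    "reedbed":   _profile(0.03, 0.06, 0.04, 0.45, 0.20, 0.10),
    "water":     _profile(0.06, 0.05, 0.04, 0.02, 0.01, 0.01),
    "grassland": _profile(0.03, 0.06, 0.04, 0.40, 0.18, 0.09),
    "arable":    _profile(0.03, 0.06, 0.045, 0.43, 0.19, 0.10),
}
# Winter: reedbed is wet senescent litter (low NIR, flooding pulls NDWI up);
# grassland stays green; arable reverts to bare soil.
_BROWN = {
    "reedbed":   _profile(0.06, 0.09, 0.11, 0.22, 0.18, 0.12),
    "water":     _profile(0.06, 0.05, 0.04, 0.02, 0.01, 0.01),
    "grassland": _profile(0.04, 0.07, 0.05, 0.30, 0.16, 0.08),
    "arable":    _profile(0.08, 0.10, 0.14, 0.26, 0.28, 0.22),
}

#: Which phase each default season label samples.
SEASON_PHASE = {
    "summer": "green", "winter": "brown",
    "feb_mar": "brown", "jun_jul": "green",
    "aug_sep": "green", "nov_dec": "brown",
}


def make_phenology(
    classes: tuple[str, ...] = ("reedbed", "water", "grassland", "arable"),
    seasons: tuple[str, ...] = ("summer", "winter"),
    band_sd: float | np.ndarray = 0.015,
    latitude_shift: float = 0.0,
    confusion_overlap: float = 0.6,
    season_phase: dict[str, str] | None = None,
) -> dict[str, ClassPhenology]:
    """Build the default phenology table.

    ``confusion_overlap`` in [0, 1] pulls the arable winter profile towards
    the reedbed winter profile, controlling how spectrally confusable the
    agricultural confusion class is (0 = fully distinct bare soil).
    """
    phase = dict(SEASON_PHASE)
    if season_phase:
        phase.update(season_phase)
    sd = np.full(N_BANDS, band_sd, dtype=float) if np.isscalar(band_sd) else np.asarray(band_sd)
    table: dict[str, ClassPhenology] = {}
    for cls in classes:
        means: dict[str, np.ndarray] = {}
        for s in seasons:
            if s not in phase:
                raise ValueError(f"no phase mapping for season {s!r}")
            base = (_GREEN if phase[s] == "green" else _BROWN)[cls].copy()
            if cls == "arable" and phase[s] == "brown" and confusion_overlap > 0:
                base = (1 - confusion_overlap) * base + confusion_overlap * _BROWN["reedbed"]
            means[s] = np.clip(base, 0.0, 1.0)
        table[cls] = ClassPhenology(cls, means, sd, latitude_shift)
    return table


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


@dataclass
class DemParams:
    base_altitude: float = 10.0   # m
    gradient: float = 0.0         # m per pixel along rows (southwards)
    hill_amplitude: float = 25.0  # m
    hill_scale: float = 15.0      # px, smoothing length of the hill field


@dataclass
class LandscapeSpec:
    """Target composition and geometry of a synthetic scene (10 m pixels)."""

    n_rows: int
    n_cols: int
    class_fractions: dict[str, float]
    reed_patch_size: float = 60.0  # mean reed patch area, pixels
    dem_params: DemParams = field(default_factory=DemParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive area")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, not 1")
        reed = self.class_fractions.get("reedbed", 0.0)
        if reed >= 0.05:
            raise ValueError("reedbed fraction must stay below 0.05 (rare-class regime)")

    @property
    def labels(self) -> list[str]:
        return list(self.class_fractions)


@dataclass
class Landscape:
    class_map: np.ndarray  # (H, W) int index into labels
    labels: list[str]
    dem: np.ndarray        # (H, W) float, metres

    def class_mask(self, label: str) -> np.ndarray:
        return self.class_map == self.labels.index(label)


_CROSS = ndimage.generate_binary_structure(2, 1)


def _grow_region(
    free: np.ndarray, target: int, mean_patch: float, rng: np.random.Generator
) -> np.ndarray:
    """Region-grow one class over currently-free pixels to ~``target`` px.

    Poisson-placed seeds (one per ``mean_patch`` pixels) grow by randomised
    dilation rounds, which yields contiguous irregular blobs.
    """
    region = np.zeros(free.shape, dtype=bool)
    if target <= 0:
        return region
    avail = np.flatnonzero(free)
    if avail.size == 0:
        return region
    n_seeds = max(1, int(round(target / mean_patch)))
    n_seeds = min(n_seeds, avail.size, target)
    seeds = rng.choice(avail, size=n_seeds, replace=False)
    region.ravel()[seeds] = True
    count = n_seeds
    while count < target:
        frontier = ndimage.binary_dilation(region, structure=_CROSS) & ~region & free
        idx = np.flatnonzero(frontier)
        if idx.size == 0:
            break  # boxed in: accept the shortfall
        keep = idx[rng.random(idx.size) < 0.7]
        if keep.size == 0:
            keep = idx[:1]
        if count + keep.size > target:
            keep = rng.choice(keep, size=target - count, replace=False)
        region.ravel()[keep] = True
        count += keep.size
    return region


def generate_landscape(spec: LandscapeSpec) -> Landscape:
    """Generate the labelled class map and DEM for ``spec`` (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.n_rows, spec.n_cols
    labels = spec.labels
    fractions = spec.class_fractions
    background = max(labels, key=lambda k: fractions[k])
    class_map = np.full((h, w), labels.index(background), dtype=np.int16)
    free = np.ones((h, w), dtype=bool)
    # grow rare classes first so they are not boxed in
    for label in sorted((l for l in labels if l != background), key=lambda k: fractions[k]):
        target = int(round(fractions[label] * h * w))
        if label == "reedbed":
            patch = spec.reed_patch_size
        else:
            patch = max(spec.reed_patch_size, min(target / 3.0, 1500.0))
        region = _grow_region(free, target, patch, rng)
        class_map[region] = labels.index(label)
        free &= ~region

    p = spec.dem_params
    hills = rng.standard_normal((h, w))
    hills = ndimage.gaussian_filter(hills, sigma=p.hill_scale)
    sd = hills.std()
    if sd > 0:
        hills = hills / sd * p.hill_amplitude
    rows = np.arange(h, dtype=float)[:, None]
    dem = p.base_altitude + p.gradient * rows + hills
    return Landscape(class_map, labels, dem)


# ---------------------------------------------------------------------------
# Passes
# ---------------------------------------------------------------------------


@dataclass
class PassSpec:
    """Acquisition conditions for one simulated pass."""

    date: dt.date
    cloud_fraction: float = 0.0
    shadow_fraction: float = 0.0
    shift: tuple[int, int] = (0, 0)  # (dx cols, dy rows), content moved by (+dx, +dy)
    gain: float | np.ndarray = 1.0
    offset: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        dx, dy = self.shift
        if abs(dx) > 3 or abs(dy) > 3:
            raise ValueError("mis-registration shift components must be <= 3 pixels")
        self.gain = np.broadcast_to(np.asarray(self.gain, dtype=float), (N_BANDS,)).copy()
        self.offset = np.broadcast_to(np.asarray(self.offset, dtype=float), (N_BANDS,)).copy()
        if (self.gain <= 0).any():
            raise ValueError("gain must be > 0")
        if (self.offset < 0).any():
            raise ValueError("offset (additive haze) must be >= 0")
        if not (0 <= self.cloud_fraction <= 1 and 0 <= self.shadow_fraction <= 1):
            raise ValueError("cloud/shadow fractions must lie in [0, 1]")


def translate_grid(arr: np.ndarray, dx: int, dy: int, fill) -> np.ndarray:
    """Translate a 2-D or (bands, H, W) grid so content moves by (+dx, +dy)."""
    out = np.full_like(arr, fill)
    h, w = arr.shape[-2:]
    sr0, sr1 = max(0, -dy), min(h, h - dy)
    sc0, sc1 = max(0, -dx), min(w, w - dx)
    dr0, dc0 = max(0, dy), max(0, dx)
    if sr1 > sr0 and sc1 > sc0:
        out[..., dr0:dr0 + (sr1 - sr0), dc0:dc0 + (sc1 - sc0)] = arr[..., sr0:sr1, sc0:sc1]
    return out


def _blob_mask(
    shape: tuple[int, int], fraction: float, rng: np.random.Generator,
    sigma: float = 8.0, displace: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Smooth-field threshold mask covering ~``fraction`` of the grid."""
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    if displace != (0, 0):
        field_ = np.roll(field_, displace, axis=(0, 1))
    if fraction >= 1:
        return np.ones(shape, dtype=bool)
    thr = np.quantile(field_, 1.0 - fraction)
    return field_ > thr


def simulate_pass(
    class_map: np.ndarray,
    labels: list[str],
    phenology: dict[str, ClassPhenology],
    pass_spec: PassSpec,
    season_windows: dict[str, tuple[int, int]] = TWO_SEASON_WINDOWS,
    seed: int = 0,
) -> tuple[MultibandPass, np.ndarray]:
    """Simulate one 13-band acquisition; returns (pass, cloud_truth).

    Per-pixel reflectance is gain x (class seasonal mean + Gaussian noise,
    clipped to [0, 1]) + offset.  Cloud pixels are overwritten with a bright
    (>= 0.6 in all bands, pre-gain) blob field; shadow pixels are darkened to
    40% of their surface value.  The whole grid is then translated by the
    mis-registration shift, with the exposed margin flagged invalid.
    ``cloud_truth`` covers clouds only (not shadows), in the delivered
    (shifted) frame.
    """
    for idx in np.unique(class_map):
        if labels[idx] not in phenology:
            raise ValueError(f"no phenology for class {labels[idx]!r}")
    base_season = season_of(pass_spec.date, season_windows)
    if base_season is None:
        raise SeasonError(
            f"pass date {pass_spec.date} falls outside every season window"
        )
    rng = np.random.default_rng(seed)
    h, w = class_map.shape
    ref = np.zeros((N_BANDS, h, w))
    sd_map = np.zeros((N_BANDS, h, w))
    northing_km = (h - 1 - np.arange(h)) * 0.01  # 10 m pixels, row 0 northmost
    for idx in np.unique(class_map):
        ph = phenology[labels[idx]]
        cmask = class_map == idx
        if ph.latitude_shift != 0.0:
            # phenology delayed with northing: shift the effective date per row
            for r in np.nonzero(cmask.any(axis=1))[0]:
                eff = pass_spec.date - dt.timedelta(days=ph.latitude_shift * northing_km[r])
                season = season_of(eff, season_windows) or base_season
                rmask = np.zeros((h, w), dtype=bool)
                rmask[r] = cmask[r]
                ref[:, rmask] = ph.season_means[season][:, None]
                sd_map[:, rmask] = ph.band_sd[:, None]
        else:
            ref[:, cmask] = ph.season_means[base_season][:, None]
            sd_map[:, cmask] = ph.band_sd[:, None]
    if (sd_map > 0).any():
        ref = ref + rng.standard_normal(ref.shape) * sd_map
    ref = np.clip(ref, 0.0, 1.0)

    cloud = _blob_mask((h, w), pass_spec.cloud_fraction, rng, sigma=8.0)
    shadow = np.zeros((h, w), dtype=bool)
    if pass_spec.shadow_fraction > 0:
        shadow = _blob_mask((h, w), pass_spec.shadow_fraction, rng,
                            sigma=8.0, displace=(14, 9)) & ~cloud
    if cloud.any():
        bright = 0.68 + 0.05 * rng.standard_normal((h, w))
        bright = np.clip(ndimage.gaussian_filter(bright, 3.0), 0.62, 0.85)
        ref[:, cloud] = bright[cloud]
    if shadow.any():
        ref[:, shadow] *= 0.4

    ref = pass_spec.gain[:, None, None] * ref + pass_spec.offset[:, None, None]

    dx, dy = pass_spec.shift
    valid = np.ones((h, w), dtype=bool)
    if (dx, dy) != (0, 0):
        ref = translate_grid(ref, dx, dy, np.nan)
        valid = translate_grid(valid, dx, dy, False)
        cloud = translate_grid(cloud, dx, dy, False)
        ref = np.nan_to_num(ref, nan=0.0)
    return MultibandPass(ref, pass_spec.date, valid), cloud


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """A complete simulated study area: truth, passes, polygons."""

    landscape: Landscape
    passes: list[MultibandPass]
    pass_specs: list[PassSpec]
    cloud_truth: list[np.ndarray]
    truth_polygons: list[TruthPolygon]
    season_windows: dict[str, tuple[int, int]]
    warnings_: list[str] = field(default_factory=list)

    @property
    def class_map(self) -> np.ndarray:
        return self.landscape.class_map

    @property
    def labels(self) -> list[str]:
        return self.landscape.labels

    @property
    def dem(self) -> np.ndarray:
        return self.landscape.dem

    @property
    def reed_truth(self) -> np.ndarray:
        if "reedbed" not in self.labels:
            return np.zeros(self.class_map.shape, dtype=bool)
        return self.landscape.class_mask("reedbed")


def _component_polygons(
    mask: np.ndarray, label: str, rng: np.random.Generator,
    max_polys: int = 40, max_poly_px: int = 1200, min_px: int = 4,
    window: int = 24,
) -> list[TruthPolygon]:
    """Polygonise connected patches of ``mask``, eroded by one pixel.

    Very large components (class backgrounds) are sampled as several
    window-sized sub-polygons instead of one enormous outline.
    """
    out: list[TruthPolygon] = []
    comp, n = ndimage.label(mask, structure=_CROSS)
    sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    for ci in order[:max_polys]:
        cmask = comp == ci
        eroded = ndimage.binary_erosion(cmask, structure=_CROSS)
        if not eroded.any():
            continue  # one-pixel-wide patch: erosion removes it entirely
        if eroded.sum() <= max_poly_px:
            parts, np_ = ndimage.label(eroded, structure=_CROSS)
            for pi in range(1, np_ + 1):
                pmask = parts == pi
                if pmask.sum() >= min_px:
                    geom = mask_to_polygon(pmask)
                    if geom is not None:
                        out.append(TruthPolygon(geom, label))
        else:
            # carve a few windows out of the big component
            rr, cc = np.nonzero(eroded)
            n_win = min(10, int(eroded.sum() // (window * window)) + 1)
            picks = rng.choice(rr.size, size=min(n_win, rr.size), replace=False)
            for k in picks:
                r0 = max(0, rr[k] - window // 2)
                c0 = max(0, cc[k] - window // 2)
                sub = np.zeros_like(eroded)
                sub[r0:r0 + window, c0:c0 + window] = eroded[r0:r0 + window, c0:c0 + window]
                parts, np_ = ndimage.label(sub, structure=_CROSS)
                if np_ == 0:
                    continue
                largest = np.argmax(ndimage.sum_labels(sub, parts, np.arange(1, np_ + 1))) + 1
                pmask = parts == largest
                if pmask.sum() >= min_px:
                    geom = mask_to_polygon(pmask)
                    if geom is not None:
                        out.append(TruthPolygon(geom, label))
    return out


def generate_dataset(
    landscape_spec: LandscapeSpec,
    pass_specs: list[PassSpec],
    phenology: dict[str, ClassPhenology],
    season_windows: dict[str, tuple[int, int]] = TWO_SEASON_WINDOWS,
) -> SyntheticDataset:
    """Generate a full dataset: landscape, passes, cloud truth, polygons.

    Training/validation truth polygons are the vectorised class patches,
    eroded by one pixel so polygon edges sit away from class boundaries.
    A season window with no pass is recorded as a warning (the dataset is
    still returned; the compositing stage will refuse that season).
    """
    landscape = generate_landscape(landscape_spec)
    seeds = np.random.SeedSequence(landscape_spec.seed).spawn(len(pass_specs) + 1)
    passes: list[MultibandPass] = []
    clouds: list[np.ndarray] = []
    for ps, ss in zip(pass_specs, seeds[:-1]):
        seed = int(ss.generate_state(1)[0] % (2**31))
        mp, ct = simulate_pass(landscape.class_map, landscape.labels, phenology,
                               ps, season_windows, seed=seed)
        passes.append(mp)
        clouds.append(ct)
    warns: list[str] = []
    counts = {s: 0 for s in season_windows}
    for ps in pass_specs:
        s = season_of(ps.date, season_windows)
        if s is not None:
            counts[s] += 1
    for s, c in counts.items():
        if c == 0:
            msg = f"season {s!r} has no passes"
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)
    poly_rng = np.random.default_rng(
        int(seeds[-1].generate_state(1)[0] % (2**31)))
    polygons: list[TruthPolygon] = []
    for label in landscape.labels:
        polygons.extend(
            _component_polygons(landscape.class_mask(label), label, poly_rng)
        )
    return SyntheticDataset(landscape, passes, list(pass_specs), clouds,
                            polygons, dict(season_windows), warns)


def cloud_training_polygons(
    dataset: SyntheticDataset, n_each: int = 8, window: int = 9, seed: int = 0
) -> list[tuple[int, TruthPolygon]]:
    """Labelled cloud/clear polygons from the simulator's cloud truth.

    Returns (pass_index, polygon) pairs, labels 'cloud' / 'clear'.  Shadow
    pixels are deliberately left in the 'clear' pool: the cloud classifier is
    not expected to see shadows, matching the workflow it feeds.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[int, TruthPolygon]] = []
    for ipass, cloud in enumerate(dataset.cloud_truth):
        if not cloud.any():
            continue
        valid = dataset.passes[ipass].valid_mask
        for label, mask in (("cloud", cloud & valid), ("clear", ~cloud & valid)):
            core = ndimage.binary_erosion(
                mask, structure=np.ones((window, window), dtype=bool))
            rr, cc = np.nonzero(core)
            if rr.size == 0:
                continue
            picks = rng.choice(rr.size, size=min(n_each, rr.size), replace=False)
            half = window // 2
            for k in picks:
                sub = np.zeros_like(mask)
                sub[rr[k] - half: rr[k] + half + 1, cc[k] - half: cc[k] + half + 1] = True
                geom = mask_to_polygon(sub & mask)
                if geom is not None:
                    out.append((ipass, TruthPolygon(geom, label)))
        if out:
            break  # one cloudy pass suffices, as in the source workflow
    return out
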