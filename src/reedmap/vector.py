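"""Pixel-grid <-> polygon helpers.

Polygons live in raster coordinates: x = column, y = row, with pixel
(r, c) occupying the unit square [c, c+1) x [r, r+1) and its centre at
(c + 0.5, r + 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry


@dataclass
class TruthPolygon:
    """A labelled polygon (training or validation truth)."""

    geometry: BaseGeometry
    label: str


def mask_to_polygon(mask: np.ndarray) -> BaseGeometry | None:
    """Union of pixel squares for a boolean mask; None if mask is empty."""
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        return None
    xs = cc.astype(float)
    ys = rr.astype(float)
    boxes = shapely.box(xs, ys, xs + 1, ys + 1)
    return shapely.union_all(boxes)


def rasterize_polygon(geom: BaseGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside ``geom``."""
    h, w = shape
    minx, miny, maxx, maxy = geom.bounds
    c0 = max(int(np.floor(minx)), 0)
    c1 = min(int(np.ceil(maxx)), w)
    r0 = max(int(np.floor(miny)), 0)
    r1 = min(int(np.ceil(maxy)), h)
    out = np.zeros(shape, dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return out
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.contains_xy(geom, cols.ravel() + 0.5, rows.ravel() + 0.5)
    out[rows.ravel()[inside], cols.ravel()[inside]] = True
    return out


def sample_points_in_polygon(
    geom: BaseGeometry, n: int, rng: np.random.Generator, max_tries: int = 200
) -> np.ndarray:
    """Uniform (x, y) draws inside ``geom`` by bounding-box rejection.

    Returns an (m, 2) array with m <= n (m < n only if the polygon is so
    thin that rejection fails persistently).
    """
    minx, miny, maxx, maxy = geom.bounds
    pts: list[np.ndarray] = []
    need = n
    for _ in range(max_tries):
        if need <= 0:
            break
        m = max(need * 2, 16)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        inside = shapely.contains_xy(geom, xs, ys)
        got = np.column_stack([xs[inside], ys[inside]])
        if got.shape[0] > 0:
            pts.append(got[:need])
            need -= min(need, got.shape[0])
    if not pts:
        return np.empty((0, 2))
    return np.concatenate(pts, axis=0)[:n]
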