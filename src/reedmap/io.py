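"""Disk formats: multi-band TIFF rasters, GeoJSON vectors, CSV manifests.

Rasters are plain pixel-grid TIFFs (the pipeline operates on one shared
grid; CRS handling is out of scope).  Band names and the nodata marker are
carried in the TIFF ImageDescription tag as JSON; NaN is the in-memory
nodata value for float rasters.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape

from .core import BAND_NAMES, MultibandPass
from .synthetic_scene import PassSpec, SyntheticDataset
from .vector import TruthPolygon


def write_raster(path, array: np.ndarray, band_names: list[str] | None = None,
                 nodata: float | None = None) -> None:
    """Write a (H, W) or (bands, H, W) array as TIFF with JSON metadata."""
    array = np.asarray(array)
    meta = {"band_names": band_names, "nodata": nodata}
    tifffile.imwrite(str(path), array, description=json.dumps(meta),
                     photometric="minisblack")


def read_raster(path) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(str(path)) as tif:
        array = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        try:
            meta = json.loads(desc.value) if desc else {}
        except (json.JSONDecodeError, TypeError):
            meta = {}
    return array, meta


def write_geojson(path, polygons: list[TruthPolygon], label_property: str = "class") -> None:
    features = [
        {
            "type": "Feature",
            "properties": {label_property: p.label},
            "geometry": mapping(p.geometry),
        }
        for p in polygons
    ]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))


def read_geojson(path, label_property: str = "class") -> list[TruthPolygon]:
    data = json.loads(Path(path).read_text())
    return [
        TruthPolygon(shape(f["geometry"]), f["properties"][label_property])
        for f in data["features"]
    ]


def write_pass_manifest(path, pass_specs: list[PassSpec],
                        filenames: list[str]) -> None:
    rows = []
    for ps, fn in zip(pass_specs, filenames):
        rows.append({
            "file": fn,
            "date": ps.date.isoformat(),
            "shift_dx": ps.shift[0],
            "shift_dy": ps.shift[1],
            "cloud_fraction": ps.cloud_fraction,
            "shadow_fraction": ps.shadow_fraction,
            "gain": json.dumps(np.asarray(ps.gain).tolist()),
            "offset": json.dumps(np.asarray(ps.offset).tolist()),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_dataset(dataset: SyntheticDataset, outdir) -> Path:
    """Write a synthetic dataset: rasters, polygons and the pass manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_raster(out / "class_map.tif", dataset.class_map.astype(np.int16),
                 band_names=dataset.labels)
    write_raster(out / "dem.tif", dataset.dem.astype(np.float32))
    filenames = []
    for i, (p, ct) in enumerate(zip(dataset.passes, dataset.cloud_truth)):
        fn = f"pass_{i:02d}_{p.date.isoformat()}.tif"
        write_raster(out / fn, p.bands.astype(np.float32),
                     band_names=list(BAND_NAMES))
        write_raster(out / fn.replace(".tif", "_valid.tif"),
                     p.valid_mask.astype(np.uint8))
        write_raster(out / fn.replace(".tif", "_cloudtruth.tif"),
                     ct.astype(np.uint8))
        filenames.append(fn)
    write_pass_manifest(out / "passes.csv", dataset.pass_specs, filenames)
    write_geojson(out / "truth_polygons.geojson", dataset.truth_polygons)
    (out / "season_windows.json").write_text(json.dumps(dataset.season_windows))
    return out


def read_passes(indir) -> list[MultibandPass]:
    indir = Path(indir)
    manifest = pd.read_csv(indir / "passes.csv")
    passes = []
    for _, row in manifest.iterrows():
        bands, _ = read_raster(indir / row["file"])
        valid, _ = read_raster(indir / str(row["file"]).replace(".tif", "_valid.tif"))
        passes.append(MultibandPass(
            bands.astype(float), dt.date.fromisoformat(row["date"]),
            valid.astype(bool)))
    return passes
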