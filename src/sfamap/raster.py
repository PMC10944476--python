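"""Raster and scene I/O.

Rasters are written as plain TIFF via :mod:`tifffile`, with georeferencing
(a simple north-up pixel-centre geotransform in WGS84 degrees), nodata and
band names serialized as JSON in the TIFF description tag.  Integer rasters
round-trip bit-exactly; float rasters are stored as float32.

A simulated scene is a directory:

    scene/
      date_000.tif ... date_NNN.tif   one six-band TIFF per acquisition
      dates.csv                       sidecar table: index, fractional year
      truth.tif                       uint16 truth (0 non-forest, 9999 stable)
      scene.json                      transform and span metadata
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import Scene
from .types import BANDS


def write_raster(
    path,
    array: np.ndarray,
    transform: dict | None = None,
    nodata=None,
    band_names: tuple | None = None,
) -> None:
    """Write an array (2-D, or 3-D band-last) with JSON metadata."""
    array = np.asarray(array)
    meta = {
        "transform": transform,
        "nodata": nodata,
        "band_names": list(band_names) if band_names else None,
    }
    kwargs = {}
    if array.ndim == 3:
        kwargs = {"photometric": "minisblack", "planarconfig": "contig"}
    tifffile.imwrite(str(path), array, description=json.dumps(meta), **kwargs)


def read_raster(path) -> tuple[np.ndarray, dict]:
    """Read a raster and its JSON metadata; malformed files raise with the
    offending path named."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    try:
        with tifffile.TiffFile(str(path)) as tif:
            array = tif.asarray()
            desc = tif.pages[0].tags.get("ImageDescription")
            meta = json.loads(desc.value) if desc is not None else {}
    except (tifffile.TiffFileError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed raster file {path}: {exc}") from exc
    return array, meta


def write_scene(scene: Scene, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i in range(scene.times.size):
        write_raster(
            out / f"date_{i:03d}.tif",
            scene.reflectance[:, :, i, :].astype(np.float32),
            transform=scene.transform,
            band_names=BANDS,
        )
        write_raster(out / f"qa_{i:03d}.tif", scene.qa[:, :, i])
    pd.DataFrame(
        {"index": np.arange(scene.times.size), "time": scene.times}
    ).to_csv(out / "dates.csv", index=False)
    write_raster(
        out / "truth.tif", scene.truth, transform=scene.transform, nodata=None
    )
    with open(out / "scene.json", "w") as fh:
        json.dump({"transform": scene.transform, "n_obs": int(scene.times.size)}, fh)


def read_scene(in_dir) -> Scene:
    src = Path(in_dir)
    dates_path = src / "dates.csv"
    if not dates_path.exists():
        raise FileNotFoundError(f"missing sidecar date table: {dates_path}")
    dates = pd.read_csv(dates_path)
    times = dates["time"].to_numpy(dtype=float)
    with open(src / "scene.json") as fh:
        meta = json.load(fh)
    truth, _ = read_raster(src / "truth.tif")
    n_rows, n_cols = truth.shape
    refl = np.empty((n_rows, n_cols, times.size, len(BANDS)), dtype=np.float32)
    qa = np.empty((n_rows, n_cols, times.size), dtype=np.uint8)
    for i in range(times.size):
        band_img, _ = read_raster(src / f"date_{i:03d}.tif")
        refl[:, :, i, :] = band_img
        qa_img, _ = read_raster(src / f"qa_{i:03d}.tif")
        qa[:, :, i] = qa_img
    return Scene(times, refl, qa, truth, scenarios=[], transform=meta["transform"])
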