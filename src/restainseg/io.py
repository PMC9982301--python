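"""Readers/writers for the pipeline's on-disk formats.

Images travel as TIFF (H&E: HxWx3 uint8; IF: HxWx2 uint8), binary masks
as 0/255 single-channel PNG, nucleus instances as 16-bit label PNG,
tables as CSV and annotations as GeoJSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


def write_image_pair(directory: str | Path, hne: np.ndarray, if_img: np.ndarray,
                     stem: str = "slide") -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hne_path = directory / f"{stem}_HE.tiff"
    if_path = directory / f"{stem}_IF.tiff"
    tifffile.imwrite(hne_path, hne.astype(np.uint8))
    tifffile.imwrite(if_path, if_img.astype(np.uint8))
    return hne_path, if_path


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_mask(path: str | Path, mask: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (mask.astype(bool) * np.uint8(255)))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return iio.imread(path) > 0


def write_label_map(path: str | Path, labels: np.ndarray) -> Path:
    """Instance/label image as 16-bit PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label image exceeds 16-bit range")
    iio.imwrite(path, labels.astype(np.uint16))
    return path


def read_label_map(path: str | Path) -> np.ndarray:
    return iio.imread(path).astype(np.int32)


def write_geojson(path: str | Path, features: list[dict]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_geojson(path: str | Path) -> list[dict]:
    data = json.loads(Path(path).read_text())
    return data.get("features", [])


def point_feature(row: float, col: float, **properties) -> dict:
    # GeoJSON geometry is (x, y) = (col, row)
    return {"type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(col), float(row)]},
            "properties": properties}


def polygon_feature(coords_rowcol: np.ndarray, **properties) -> dict:
    ring = [[float(c), float(r)] for r, c in np.asarray(coords_rowcol)]
    if ring and ring[0] != ring[-1]:
        ring.append(ring[0])
    return {"type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": properties}
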