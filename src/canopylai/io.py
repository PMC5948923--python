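"""File IO: 8-bit grayscale PNG/TIFF images, scene manifests, result tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from canopylai.imaging import FlatGeometry, Geometry, GrayscaleImage
from canopylai.synthetic import BinaryScene

__all__ = [
    "save_grayscale",
    "load_grayscale",
    "save_scene_mask",
    "write_scene_manifest",
    "write_run_manifest",
]


def save_grayscale(path: str | Path, intensities: np.ndarray) -> None:
    """Write a 2-D uint8 array as an 8-bit grayscale image."""
    iio.imwrite(Path(path), np.asarray(intensities, dtype=np.uint8))


def load_grayscale(path: str | Path, geometry: Geometry = FlatGeometry()) -> GrayscaleImage:
    """Read an 8-bit grayscale PNG/TIFF as a :class:`GrayscaleImage`."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:  # collapse an (unexpected) color image
        arr = arr[..., :3].mean(axis=2)
    return GrayscaleImage(intensities=np.asarray(arr, dtype=np.uint8), geometry=geometry)


def save_scene_mask(path: str | Path, scene: BinaryScene) -> None:
    """Write a scene mask as black (vegetation) on white (sky)."""
    save_grayscale(path, np.where(scene.mask, 0, 255).astype(np.uint8))


def write_scene_manifest(path: str | Path, scenes: list[BinaryScene]) -> pd.DataFrame:
    """Write the ground-truth manifest (exact covers and spec fields) as CSV."""
    rows = []
    for i, sc in enumerate(scenes):
        row = {"scene_id": f"scene_{i:03d}", "achieved_cover": sc.achieved_cover,
               "n_circles": sc.n_circles}
        row.update(dataclasses.asdict(sc.spec))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(Path(path), index=False)
    return df


def write_run_manifest(path: str | Path, config: dict, seed: int) -> None:
    """Record the run configuration and seed as JSON for reproducibility."""
    import canopylai

    payload = {"config": config, "seed": seed, "canopylai_version": canopylai.__version__}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
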