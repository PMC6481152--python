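"""File I/O: 16-bit images, 8-bit masks, dataset manifests, YAML configs.

Phantoms are generated as floats in [0, 1] and written losslessly as
16-bit grayscale TIFF or PNG; masks are 8-bit PNG with 0/255 values.  A
dataset directory carries a CSV manifest (image path, mask path, split,
seed) tying them together.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .phantom import Mammogram, MCMask, PhantomConfig, PhantomDataset


def save_image(image: Mammogram, path: str | Path) -> None:
    """Write a [0, 1] float image as 16-bit grayscale TIFF or PNG."""
    path = Path(path)
    arr = np.clip(image.pixels, 0.0, 1.0)
    arr16 = np.round(arr * np.iinfo(np.uint16).max).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr16)
    else:
        iio.imwrite(path, arr16)


def load_image(path: str | Path, pixel_spacing_mm: float = 0.05) -> Mammogram:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.max() > 1.0:  # 8- or 16-bit integer image back to [0, 1]
        arr = arr / (np.iinfo(np.uint16).max if arr.max() > 255 else 255)
    return Mammogram(arr, pixel_spacing_mm)


def save_mask(mask: MCMask, path: str | Path) -> None:
    iio.imwrite(Path(path), (mask.pixels * 255).astype(np.uint8))


def load_mask(path: str | Path) -> MCMask:
    arr = np.asarray(iio.imread(Path(path)))
    return MCMask((arr > 127).astype(np.uint8))


def write_dataset(dataset: PhantomDataset, out_dir: str | Path, image_format: str = "tiff") -> Path:
    """Write images, masks and the CSV manifest; returns the manifest path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    suffix = ".tif" if image_format in ("tif", "tiff") else ".png"
    rows = []
    for s in dataset.samples:
        img_path = out / "images" / f"{s.image_id}{suffix}"
        mask_path = out / "masks" / f"{s.image_id}.png"
        save_image(s.image, img_path)
        save_mask(s.mask, mask_path)
        rows.append(
            {
                "image_id": s.image_id,
                "image_path": str(img_path.relative_to(out)),
                "mask_path": str(mask_path.relative_to(out)),
                "split": s.split,
                "seed": s.seed,
                "pixel_spacing_mm": s.image.pixel_spacing_mm,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(manifest_path)
    required = {"image_id", "image_path", "mask_path", "split"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_phantom_config(path: str | Path) -> PhantomConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("mc_diameter_range", "mc_contrast_range"):
        if key in data:
            data[key] = tuple(data[key])
    return PhantomConfig(**data)


def save_phantom_config(config: PhantomConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    data["mc_diameter_range"] = list(config.mc_diameter_range)
    data["mc_contrast_range"] = list(config.mc_contrast_range)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
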