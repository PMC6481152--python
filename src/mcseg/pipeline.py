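"""Whole-mammogram inference: Otsu foreground, overlapped tiling, detector
screening, per-pixel segmentation of flagged ROIs.

The image is first thresholded with Otsu's method so background pixels are
excluded from all further evaluation.  It is then tiled with N x N windows
overlapped by floor(N/2) pixels in each direction (stride N - floor(N/2));
the overlap makes most pixels visible to the detector in several tiles,
limiting missed lesions.  Tiles that intersect the foreground are screened
by the detector CNN; every foreground pixel inside at least one flagged
tile is then classified by the segmentator CNN using the N x N patch
centered on it (reflect-padded at image borders), producing the predicted
microcalcification mask.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .patches import PatchDatabase, extract_window
from .phantom import Mammogram, MCMask
from .nn.network import TrainedModel


@dataclass
class ForegroundMask:
    """Binary breast-tissue mask and the Otsu threshold that produced it."""

    pixels: np.ndarray
    threshold: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class TileGrid:
    """Overlapped N x N tiling of an image, with per-tile detector decisions."""

    patch_side: int
    stride: int
    image_shape: tuple[int, int]
    row_origins: np.ndarray
    col_origins: np.ndarray
    #: -1 unset, 0 negative, 1 flagged; row-major over (row_origins x col_origins)
    decisions: np.ndarray = field(default=None)  # type: ignore[assignment]
    evaluated: int = 0

    def __post_init__(self) -> None:
        if self.decisions is None:
            self.decisions = np.full(
                len(self.row_origins) * len(self.col_origins), -1, dtype=np.int8
            )

    @property
    def origins(self) -> list[tuple[int, int]]:
        return [
            (int(r), int(c)) for r in self.row_origins for c in self.col_origins
        ]

    def flagged_origins(self) -> list[tuple[int, int]]:
        return [o for o, d in zip(self.origins, self.decisions) if d == 1]

    def __len__(self) -> int:
        return len(self.row_origins) * len(self.col_origins)


def otsu_foreground(image: Mammogram) -> ForegroundMask:
    """Breast foreground by Otsu's between-class-variance threshold.

    Pixels strictly above the threshold are foreground.  A constant image
    has no histogram split and raises ``ValueError``.
    """
    pixels = image.pixels
    if np.unique(pixels).size < 2:
        raise ValueError("constant image: Otsu threshold undefined")
    thr = float(threshold_otsu(pixels))
    return ForegroundMask(pixels=(pixels > thr), threshold=thr)


def _axis_origins(length: int, n: int, stride: int) -> np.ndarray:
    origins = list(range(0, length - n + 1, stride))
    if origins[-1] + n < length:
        origins.append(length - n)  # clamp a final tile flush to the edge
    return np.asarray(origins, dtype=int)


def tile_image(image_shape: tuple[int, int], n: int) -> TileGrid:
    """Overlapped tiling with stride ``n - floor(n/2)``.

    Consecutive tiles overlap by floor(n/2) pixels per axis; a final tile
    is clamped flush to each edge so every pixel lies in at least one tile.
    """
    h, w = image_shape
    if h < n or w < n:
        raise ValueError(f"image {image_shape} smaller than patch side {n}")
    stride = n - n // 2
    return TileGrid(
        patch_side=n,
        stride=stride,
        image_shape=(h, w),
        row_origins=_axis_origins(h, n, stride),
        col_origins=_axis_origins(w, n, stride),
    )


def detect_rois(
    detector: TrainedModel,
    image: Mammogram,
    grid: TileGrid,
    fg: ForegroundMask,
    threshold: float = 0.5,
    batch_size: int = 512,
) -> TileGrid:
    """Screen every tile with the detector.

    Tiles whose pixels are entirely background are marked negative without
    any network evaluation; the rest receive the detector's binary
    decision on the N x N tile.  ``grid.evaluated`` counts network calls.
    """
    n = grid.patch_side
    if detector.config.patch_side != n:
        raise ValueError(
            f"detector patch side {detector.config.patch_side} != grid side {n}"
        )
    norm = PatchDatabase.normalize_image(image.pixels)
    origins = grid.origins
    to_eval = [
        i for i, (r, c) in enumerate(origins) if fg.pixels[r : r + n, c : c + n].any()
    ]
    grid.decisions[:] = 0
    grid.evaluated = len(to_eval)
    if to_eval:
        tiles = np.stack(
            [norm[r : r + n, c : c + n] for r, c in (origins[i] for i in to_eval)]
        )[:, None].astype(np.float32)
        decisions = detector.network.predict(tiles, threshold, batch_size)
        grid.decisions[np.asarray(to_eval)] = decisions
    return grid


def segment_rois(
    segmentator: TrainedModel,
    image: Mammogram,
    flagged: TileGrid,
    fg: ForegroundMask,
    threshold: float = 0.5,
    batch_size: int = 512,
) -> MCMask:
    """Per-pixel classification of every foreground pixel in a flagged tile.

    Each such pixel is classified exactly once from the N x N patch
    centered on it (union semantics over overlapping tiles); pixels
    outside all flagged tiles, or outside the foreground, stay 0.
    """
    n = flagged.patch_side
    if segmentator.config.patch_side != n:
        raise ValueError(
            f"segmentator patch side {segmentator.config.patch_side} != grid side {n}"
        )
    h, w = flagged.image_shape
    in_flagged = np.zeros((h, w), dtype=bool)
    for r, c in flagged.flagged_origins():
        in_flagged[r : r + n, c : c + n] = True
    targets = np.argwhere(in_flagged & fg.pixels)
    mask = np.zeros((h, w), dtype=np.uint8)
    if targets.size == 0:
        return MCMask(mask)

    half = n // 2
    padded = np.pad(
        PatchDatabase.normalize_image(image.pixels), half, mode="symmetric"
    )
    windows = np.lib.stride_tricks.sliding_window_view(padded, (n, n))
    for i in range(0, len(targets), batch_size):
        chunk = targets[i : i + batch_size]
        patches = windows[chunk[:, 0], chunk[:, 1]][:, None].astype(np.float32)
        pred = segmentator.network.predict(patches, threshold, batch_size)
        mask[chunk[:, 0], chunk[:, 1]] = pred
    return MCMask(mask)


def run_pipeline(
    detector: TrainedModel,
    segmentator: TrainedModel,
    image: Mammogram,
    detector_threshold: float = 0.5,
    segmentator_threshold: float = 0.5,
) -> tuple[MCMask, TileGrid, ForegroundMask]:
    """Full two-stage pass over one mammogram.

    Composition ``otsu_foreground -> tile_image -> detect_rois ->
    segment_rois``; deterministic for fixed weights.  Tile statistics and
    the runtime are stored on the returned grid's ``stats`` attribute.
    """
    if detector.config.patch_side != segmentator.config.patch_side:
        raise ValueError("detector and segmentator must share the patch side")
    t0 = time.perf_counter()
    fg = otsu_foreground(image)
    grid = tile_image(image.shape, detector.config.patch_side)
    grid = detect_rois(detector, image, grid, fg, detector_threshold)
    mask = segment_rois(segmentator, image, grid, fg, segmentator_threshold)
    grid.stats = {  # type: ignore[attr-defined]
        "n_tiles": len(grid),
        "n_evaluated": grid.evaluated,
        "n_flagged": int((grid.decisions == 1).sum()),
        "flagged_fraction": float((grid.decisions == 1).mean()),
        "otsu_threshold": fg.threshold,
        "runtime_s": time.perf_counter() - t0,
    }
    return mask, grid, fg
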