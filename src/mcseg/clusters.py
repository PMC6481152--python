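"""Connected-component labelling of MC masks and cluster detection.

A predicted (or ground-truth) binary mask is decomposed into connected
components — one per microcalcification — and a square window of 1 cm
side (10 mm / pixel spacing; 200 px at 0.05 mm) is slid over the image.
Any window containing strictly more than ``threshold`` (default 5)
distinct MC centroids marks a cluster, following the radiological density
rule "more than 5 MCs per cm^2".  Overlapping qualifying windows are
merged into maximal cluster regions reported as bounding boxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .phantom import MCMask


@dataclass(frozen=True)
class MCObject:
    """One connected microcalcification component."""

    component_id: int
    pixel_count: int
    centroid: tuple[float, float]        # (row, col)
    bounding_box: tuple[int, int, int, int]  # (row0, col0, row1, col1) half-open


@dataclass(frozen=True)
class ClusterRegion:
    """A maximal union of qualifying density windows."""

    bounding_box: tuple[int, int, int, int]
    mc_count: int
    n_windows: int


@dataclass
class ClusterReport:
    mc_objects: list[MCObject]
    cluster_regions: list[ClusterRegion]
    qualifying_windows: list[tuple[tuple[int, int], int]]  # (origin, count)
    pixel_spacing_mm: float
    window_side_px: int
    threshold: int = 5

    def to_dict(self) -> dict:
        return {
            "pixel_spacing_mm": self.pixel_spacing_mm,
            "window_side_px": self.window_side_px,
            "threshold": self.threshold,
            "n_mc_objects": len(self.mc_objects),
            "mc_objects": [
                {
                    "id": o.component_id,
                    "pixel_count": o.pixel_count,
                    "centroid_row": o.centroid[0],
                    "centroid_col": o.centroid[1],
                    "bbox": list(o.bounding_box),
                }
                for o in self.mc_objects
            ],
            "cluster_regions": [
                {
                    "bbox": list(r.bounding_box),
                    "mc_count": r.mc_count,
                    "n_windows": r.n_windows,
                }
                for r in self.cluster_regions
            ],
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def label_components(mask: MCMask | np.ndarray, connectivity: int = 8) -> list[MCObject]:
    """Connected-component decomposition of a binary mask.

    Component ids are contiguous from 1; centroids are arithmetic means of
    member pixel coordinates.
    """
    pixels = mask.pixels if isinstance(mask, MCMask) else np.asarray(mask)
    if not np.all(np.isin(np.unique(pixels), (0, 1))):
        raise ValueError("mask must be binary")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labeled, n = ndimage.label(pixels, structure=_STRUCTURES[connectivity])
    objects: list[MCObject] = []
    if n == 0:
        return objects
    slices = ndimage.find_objects(labeled)
    centroids = ndimage.center_of_mass(pixels, labeled, index=range(1, n + 1))
    counts = ndimage.sum_labels(pixels, labeled, index=range(1, n + 1))
    for i, (sl, cen, cnt) in enumerate(zip(slices, centroids, counts), start=1):
        objects.append(
            MCObject(
                component_id=i,
                pixel_count=int(cnt),
                centroid=(float(cen[0]), float(cen[1])),
                bounding_box=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
            )
        )
    return objects


def _window_origins(length: int, side: int, step: int) -> list[int]:
    if length <= side:
        return [0]
    origins = list(range(0, length - side + 1, step))
    if origins[-1] != length - side:
        origins.append(length - side)
    return origins


def detect_clusters(
    objects: list[MCObject],
    image_shape: tuple[int, int],
    pixel_spacing_mm: float,
    threshold: int = 5,
    window_mm: float = 10.0,
    step_px: int = 25,
) -> ClusterReport:
    """Find regions whose MC density exceeds the radiological rule.

    A square window of side ``window_mm / pixel_spacing_mm`` pixels slides
    over the image at ``step_px``; a window qualifies iff strictly more
    than ``threshold`` object centroids fall inside it (half-open bounds).
    Overlapping qualifying windows are merged into maximal regions.
    ``step_px=1`` is the exhaustive scan used as the reference; coarser
    steps can only miss clusters, never invent them.
    """
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel spacing must be positive")
    side = int(round(window_mm / pixel_spacing_mm))
    h, w = image_shape
    report = ClusterReport(
        mc_objects=list(objects),
        cluster_regions=[],
        qualifying_windows=[],
        pixel_spacing_mm=pixel_spacing_mm,
        window_side_px=side,
        threshold=threshold,
    )
    if not objects:
        return report
    cen = np.array([o.centroid for o in objects])
    union = np.zeros((h, w), dtype=bool)
    for r0 in _window_origins(h, side, step_px):
        r_in = (cen[:, 0] >= r0) & (cen[:, 0] < r0 + side)
        if r_in.sum() <= threshold:
            continue
        for c0 in _window_origins(w, side, step_px):
            count = int((r_in & (cen[:, 1] >= c0) & (cen[:, 1] < c0 + side)).sum())
            if count > threshold:
                report.qualifying_windows.append(((r0, c0), count))
                union[r0 : min(r0 + side, h), c0 : min(c0 + side, w)] = True
    if report.qualifying_windows:
        labeled, _ = ndimage.label(union)
        cr = np.clip(np.floor(cen[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.floor(cen[:, 1]).astype(int), 0, w - 1)
        membership = labeled[cr, cc]  # which merged region each centroid is in
        for region_id, sl in enumerate(ndimage.find_objects(labeled), start=1):
            bbox = (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)
            n_windows = sum(
                1
                for (r0, c0), _ in report.qualifying_windows
                if labeled[r0, c0] == region_id
            )
            report.cluster_regions.append(
                ClusterRegion(
                    bounding_box=bbox,
                    mc_count=int((membership == region_id).sum()),
                    n_windows=n_windows,
                )
            )
    return report


def analyse_mask(
    mask: MCMask | np.ndarray,
    pixel_spacing_mm: float,
    connectivity: int = 8,
    threshold: int = 5,
    step_px: int = 25,
) -> ClusterReport:
    """Label a mask and run cluster detection in one call."""
    pixels = mask.pixels if isinstance(mask, MCMask) else np.asarray(mask)
    objects = label_components(pixels, connectivity)
    return detect_clusters(
        objects, pixels.shape, pixel_spacing_mm, threshold=threshold, step_px=step_px
    )
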