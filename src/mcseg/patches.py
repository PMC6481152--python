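"""Patch extraction, the four-class taxonomy, and balanced minibatch sampling.

Both networks are trained on square N x N windows cut from the mammogram.
Each eligible window (its center pixel must lie on breast foreground) gets
one of four classes from the ground-truth mask:

* ``C1`` — the central pixel belongs to a microcalcification;
* ``C2`` — the center is background but an MC pixel lies within a small
  radius of it (default 3 px, Euclidean): the ambiguous lesion-border shell;
* ``C3`` — an MC is present in the window but only peripherally;
* ``C4`` — no MC anywhere in the window.

The detector treats C1, C2 and C3 as positive (an MC is present in the
window); the segmentator treats only C1 as positive (the center pixel is
lesion).  Class C4 dominates by orders of magnitude, so minibatches are
built on the fly with exactly equal numbers of positive and negative
patches, each given a random dihedral (rotation/flip) augmentation.

Patch records store coordinates only, in an indexed SQLite table; pixels
are re-read from the source image at sampling time.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from scipy import ndimage

from .phantom import Mammogram, MCMask

PATCH_CLASSES = ("C1", "C2", "C3", "C4")
#: classes the detector labels positive (an MC lies somewhere in the window)
DETECTOR_POSITIVE = frozenset({"C1", "C2", "C3"})
#: classes the segmentator labels positive (the central pixel is lesion)
SEGMENTATOR_POSITIVE = frozenset({"C1"})

Role = Literal["detector", "segmentator"]


def role_positive_classes(role: Role) -> frozenset[str]:
    if role == "detector":
        return DETECTOR_POSITIVE
    if role == "segmentator":
        return SEGMENTATOR_POSITIVE
    raise ValueError(f"unknown network role: {role!r}")


@dataclass(frozen=True)
class PatchRecord:
    image_id: str
    center_row: int
    center_col: int
    patch_class: str

    @property
    def detector_label(self) -> int:
        return int(self.patch_class in DETECTOR_POSITIVE)

    @property
    def segmentator_label(self) -> int:
        return int(self.patch_class in SEGMENTATOR_POSITIVE)


def _check_window(window: np.ndarray) -> np.ndarray:
    window = np.asarray(window)
    if window.ndim != 2 or window.shape[0] != window.shape[1]:
        raise ValueError("patch window must be square")
    if window.shape[0] % 2 == 0:
        raise ValueError("patch side must be odd")
    if not np.all(np.isin(np.unique(window), (0, 1))):
        raise ValueError("mask window must be binary")
    return window.astype(np.uint8)


def classify_patch(mask_window: np.ndarray, c2_radius_px: float = 3.0) -> str:
    """Assign the four-class taxonomy to one mask window.

    C1 iff the center pixel is 1; C2 iff the center is 0 and the nearest MC
    pixel lies within Euclidean distance ``c2_radius_px`` of the center;
    C3 iff an MC pixel exists in the window but farther than that; C4 iff
    the window contains no MC pixel.
    """
    window = _check_window(mask_window)
    n = window.shape[0]
    c = n // 2
    if window[c, c]:
        return "C1"
    pos = np.argwhere(window)
    if pos.size == 0:
        return "C4"
    d = np.hypot(pos[:, 0] - c, pos[:, 1] - c).min()
    return "C2" if d <= c2_radius_px else "C3"


def extract_window(pixels: np.ndarray, row: int, col: int, n: int) -> np.ndarray:
    """N x N window centered on (row, col), symmetric-reflected at borders."""
    half = n // 2
    padded = np.pad(pixels, half, mode="symmetric")
    return padded[row : row + n, col : col + n]


def classify_all_centers(
    mask: np.ndarray, n: int, c2_radius_px: float = 3.0
) -> np.ndarray:
    """Patch class of every pixel-centered window, vectorized.

    Windows at the border are completed by symmetric reflection, matching
    :func:`extract_window`.  Agrees pixel-for-pixel with brute-force
    :func:`classify_patch` on each extracted window.

    Returns an int array with codes 1..4 for C1..C4.
    """
    mask = np.asarray(mask).astype(bool)
    half = n // 2
    padded = np.pad(mask, half, mode="symmetric")
    # distance from each pixel to nearest MC pixel in the reflected image;
    # any distance <= c2_radius (< half+1) is realized inside the window
    if padded.any():
        dist = ndimage.distance_transform_edt(~padded)[half:-half, half:-half]
    else:
        dist = np.full(mask.shape, np.inf)
    presence = ndimage.maximum_filter(mask.astype(np.uint8), size=n, mode="reflect") > 0
    codes = np.full(mask.shape, 4, dtype=np.int8)
    codes[presence] = 3
    codes[(~mask) & (dist <= c2_radius_px)] = 2
    codes[mask] = 1
    return codes


_SCHEMA = """
CREATE TABLE IF NOT EXISTS patches (
    image_id TEXT NOT NULL,
    row INTEGER NOT NULL,
    col INTEGER NOT NULL,
    class TEXT NOT NULL,
    split TEXT NOT NULL
);
CREATE INDEX IF NOT EXISTS idx_patches ON patches (split, class);
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE IF NOT EXISTS images (
    image_id TEXT PRIMARY KEY,
    image_path TEXT,
    mask_path TEXT,
    split TEXT
);
"""


class PatchDatabase:
    """SQLite-backed index of patch records plus an in-memory image registry.

    Only coordinates and classes live in the database; pixels are re-read
    from the registered images when minibatches are assembled.  Images are
    registered already normalized (zero mean, unit variance per image) so
    training and inference see identical inputs.
    """

    def __init__(self, patch_side: int, c2_radius_px: float = 3.0, path: str | Path = ":memory:"):
        if patch_side % 2 == 0 or patch_side < 9:
            raise ValueError("patch side must be odd and >= 9")
        self.patch_side = int(patch_side)
        self.c2_radius_px = float(c2_radius_px)
        self.conn = sqlite3.connect(str(path))
        self.conn.executescript(_SCHEMA)
        self.conn.execute(
            "INSERT OR REPLACE INTO meta VALUES ('patch_side', ?)", (str(patch_side),)
        )
        self.conn.execute(
            "INSERT OR REPLACE INTO meta VALUES ('c2_radius_px', ?)", (str(c2_radius_px),)
        )
        self.conn.commit()
        self._images: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._pool_cache: dict[tuple, np.ndarray] = {}

    # -- registration -----------------------------------------------------
    @staticmethod
    def normalize_image(pixels: np.ndarray) -> np.ndarray:
        """Per-image standardization applied before the networks."""
        pixels = np.asarray(pixels, dtype=np.float32)
        sd = pixels.std()
        if sd == 0:
            raise ValueError("cannot normalize a constant image")
        return (pixels - pixels.mean()) / sd

    def add_image(
        self,
        image_id: str,
        image: Mammogram,
        mask: MCMask,
        foreground: np.ndarray,
        split: str = "train",
    ) -> int:
        """Index every eligible center of one image; returns record count."""
        if image.shape != mask.shape or image.shape != foreground.shape:
            raise ValueError("image, mask and foreground shapes must agree")
        fg = np.asarray(foreground).astype(bool)
        if not fg.any():
            raise ValueError(f"image {image_id!r} has no foreground pixels")
        codes = classify_all_centers(mask.pixels, self.patch_side, self.c2_radius_px)
        rows, cols = np.nonzero(fg)
        classes = codes[rows, cols]
        self.conn.executemany(
            "INSERT INTO patches VALUES (?,?,?,?,?)",
            (
                (image_id, int(r), int(c), PATCH_CLASSES[k - 1], split)
                for r, c, k in zip(rows, cols, classes)
            ),
        )
        self.conn.execute(
            "INSERT OR REPLACE INTO images VALUES (?,?,?,?)",
            (image_id, None, None, split),
        )
        self.conn.commit()
        self._images[image_id] = (
            self.normalize_image(image.pixels),
            mask.pixels,
        )
        self._pool_cache.clear()
        return len(rows)

    # -- queries ----------------------------------------------------------
    def class_counts(self, split: str | None = None) -> dict[str, int]:
        q = "SELECT class, COUNT(*) FROM patches"
        args: tuple = ()
        if split is not None:
            q += " WHERE split = ?"
            args = (split,)
        q += " GROUP BY class"
        counts = dict.fromkeys(PATCH_CLASSES, 0)
        counts.update(dict(self.conn.execute(q, args).fetchall()))
        return counts

    def records(
        self, split: str | None = None, classes: Iterable[str] | None = None
    ) -> list[PatchRecord]:
        q = "SELECT image_id, row, col, class FROM patches"
        clauses, args = [], []
        if split is not None:
            clauses.append("split = ?")
            args.append(split)
        if classes is not None:
            cls = sorted(set(classes))
            clauses.append(f"class IN ({','.join('?' * len(cls))})")
            args.extend(cls)
        if clauses:
            q += " WHERE " + " AND ".join(clauses)
        q += " ORDER BY image_id, row, col"
        return [PatchRecord(i, r, c, k) for i, r, c, k in self.conn.execute(q, args)]

    def _pool(self, split: str, classes: frozenset[str]) -> list[tuple[str, int, int, str]]:
        key = (split, classes)
        if key not in self._pool_cache:
            cls = sorted(classes)
            q = (
                "SELECT image_id, row, col, class FROM patches WHERE split = ? "
                f"AND class IN ({','.join('?' * len(cls))}) ORDER BY image_id, row, col"
            )
            self._pool_cache[key] = self.conn.execute(q, (split, *cls)).fetchall()
        return self._pool_cache[key]

    def patch_pixels(self, image_id: str, row: int, col: int) -> np.ndarray:
        image, _ = self._images[image_id]
        return extract_window(image, row, col, self.patch_side)

    def mask_window(self, image_id: str, row: int, col: int) -> np.ndarray:
        _, mask = self._images[image_id]
        return extract_window(mask, row, col, self.patch_side)

    def close(self) -> None:
        self.conn.close()


def build_patch_index(
    image: Mammogram,
    mask: MCMask,
    n: int,
    foreground: np.ndarray,
    c2_radius_px: float = 3.0,
    image_id: str = "image_0000",
    split: str = "train",
) -> PatchDatabase:
    """Index one mammogram into a fresh in-memory :class:`PatchDatabase`."""
    db = PatchDatabase(n, c2_radius_px)
    db.add_image(image_id, image, mask, foreground, split)
    return db


def augment(
    patch_pixels: np.ndarray, label_window: np.ndarray | None, transform_id: int
) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply one of the 8 dihedral symmetries to a patch (and its labels).

    ``transform_id`` 0-3 are counterclockwise right-angle rotations,
    4-7 the same rotations preceded by a left-right flip.  Identity is 0.
    The center pixel of an odd-sided patch is fixed by every transform, so
    the patch class is invariant.
    """
    if not 0 <= transform_id <= 7:
        raise ValueError("transform_id must be in 0..7")

    def _apply(a: np.ndarray) -> np.ndarray:
        a = np.asarray(a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("augment expects square 2D inputs")
        if transform_id >= 4:
            a = np.fliplr(a)
        return np.rot90(a, k=transform_id % 4)

    out_label = None if label_window is None else _apply(label_window)
    return _apply(patch_pixels), out_label


@dataclass
class Minibatch:
    """A balanced batch of patches with one-hot labels over {negative, positive}."""

    pixels: np.ndarray        # (B, 1, N, N) float32
    labels: np.ndarray        # (B, 2) one-hot, column 1 = positive
    patch_classes: list[str]  # provenance

    def __len__(self) -> int:
        return self.pixels.shape[0]


def sample_minibatch(
    db: PatchDatabase,
    network_role: Role,
    batch_size: int,
    rng: np.random.Generator,
    split: str = "train",
) -> Minibatch:
    """Draw a balanced, dihedral-augmented minibatch.

    Exactly ``batch_size/2`` positive and negative patches, drawn uniformly
    within their label pool without replacement inside the batch (with
    replacement across batches, so successive minibatches differ).
    Deterministic given the generator state.
    """
    if batch_size % 2 != 0 or batch_size <= 0:
        raise ValueError("batch_size must be a positive even number")
    pos_classes = role_positive_classes(network_role)
    neg_classes = frozenset(PATCH_CLASSES) - pos_classes
    half = batch_size // 2

    chosen: list[tuple[str, int, int, str]] = []
    labels = np.zeros((batch_size, 2), dtype=np.float32)
    for i, classes in enumerate((neg_classes, pos_classes)):
        pool = db._pool(split, classes)
        if len(pool) == 0:
            raise ValueError(
                f"no {'positive' if i else 'negative'} records for role "
                f"{network_role!r} in split {split!r}"
            )
        idx = rng.choice(len(pool), size=half, replace=len(pool) < half)
        chosen.extend(pool[j] for j in idx)
        labels[i * half : (i + 1) * half, i] = 1.0

    n = db.patch_side
    pixels = np.empty((batch_size, 1, n, n), dtype=np.float32)
    classes_out: list[str] = []
    transforms = rng.integers(0, 8, size=batch_size)
    for b, ((image_id, row, col, klass), t) in enumerate(zip(chosen, transforms)):
        patch = db.patch_pixels(image_id, row, col)
        patch, _ = augment(patch, None, int(t))
        pixels[b, 0] = patch
        classes_out.append(klass)

    order = rng.permutation(batch_size)
    return Minibatch(
        pixels=pixels[order],
        labels=labels[order],
        patch_classes=[classes_out[i] for i in order],
    )
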