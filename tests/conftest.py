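import numpy as np
import pytest

from mcseg.phantom import PhantomConfig, generate_phantom
from mcseg.patches import PatchDatabase
from mcseg.pipeline import otsu_foreground


@pytest.fixture(scope="session")
def small_phantom():
    """One 128x128 phantom with 7 well-separated MCs and its mask."""
    cfg = PhantomConfig(
        image_height=128, image_width=128, n_mcs=7, mc_diameter_range=(2, 11), seed=3
    )
    image, mask = generate_phantom(cfg)
    return cfg, image, mask


@pytest.fixture(scope="session")
def small_db(small_phantom):
    """Patch database (N=21) over the small phantom, all splits 'train'."""
    _, image, mask = small_phantom
    fg = otsu_foreground(image)
    db = PatchDatabase(patch_side=21)
    db.add_image("phantom_a", image, mask, fg.pixels, split="train")
    return db


# ---------------------------------------------------------------- oracles

def unionfind_components(mask: np.ndarray, connectivity: int = 8) -> int:
    """Independent connected-component count via explicit union-find."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    parent: dict[tuple[int, int], tuple[int, int]] = {}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    coords = [(r, c) for r, c in zip(*np.nonzero(mask))]
    for p in coords:
        parent[p] = p
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1)]
    else:
        neigh = [(-1, 0), (0, -1)]
    for r, c in coords:
        for dr, dc in neigh:
            q = (r + dr, c + dc)
            if 0 <= q[0] < h and 0 <= q[1] < w and mask[q]:
                union((r, c), q)
    return len({find(p) for p in coords})


def brute_force_patch_class(window: np.ndarray, c2_radius: float = 3.0) -> str:
    """Naive per-pixel scan reference for the C1..C4 taxonomy."""
    window = np.asarray(window)
    n = window.shape[0]
    c = n // 2
    if window[c, c] == 1:
        return "C1"
    best = None
    for r in range(n):
        for col in range(n):
            if window[r, col] == 1:
                d = ((r - c) ** 2 + (col - c) ** 2) ** 0.5
                best = d if best is None else min(best, d)
    if best is None:
        return "C4"
    return "C2" if best <= c2_radius else "C3"


def exhaustive_otsu(pixels: np.ndarray) -> float:
    """Scan every histogram bin edge for the max between-class variance."""
    flat = np.asarray(pixels).ravel()
    hist, edges = np.histogram(flat, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    total = hist.sum()
    best_t, best_v = centers[0], -1.0
    for k in range(1, 256):
        w0 = hist[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:k] * centers[:k]).sum() / w0
        m1 = (hist[k:] * centers[k:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, centers[k - 1]
    return best_t
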