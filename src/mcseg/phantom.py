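"""Synthetic mammogram phantoms with pixel-exact microcalcification masks.

Clinical mammograms annotated for microcalcifications (MCs) are rarely
shareable, so every downstream stage of this package is exercised on
synthetic phantoms: a smooth breast-shaped region with low-frequency tissue
texture over a near-zero background, into which small bright blobs are
injected.  Each injected blob is recorded pixel-exactly in a binary
ground-truth mask, which makes detector/segmentator training and pixel-level
evaluation possible without any clinical data.

The phantom is deliberately simple; it emulates the *contrast statistics*
that matter to a patch classifier (locally bright, small, circular to
irregular lesions on textured tissue), not breast anatomy or X-ray physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage


class PlacementError(RuntimeError):
    """Raised when the requested MCs cannot be placed without overlap."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic phantom.

    Sizes are in pixels at ``pixel_spacing_mm`` mm/pixel (default 0.05 mm,
    the sampling pitch of high-resolution digital mammography).
    """

    image_height: int = 256
    image_width: int = 256
    pixel_spacing_mm: float = 0.05
    n_mcs: int = 12
    mc_diameter_range: tuple[float, float] = (2.0, 15.0)
    #: peak added intensity as a fraction of the local tissue intensity
    mc_contrast_range: tuple[float, float] = (0.3, 0.9)
    #: 0 = circular lesions, 1 = strongly irregular star-shaped outlines
    mc_shape_irregularity: float = 0.4
    n_clusters: int = 0
    cluster_radius_px: float = 40.0
    #: correlation length (pixels) of the low-pass tissue texture field
    tissue_texture_scale: float = 8.0
    #: additive white noise level; raise to mimic noisy digitized film
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")
        lo, hi = self.mc_diameter_range
        if not (0 < lo <= hi):
            raise ValueError("mc_diameter_range must be positive and ordered")
        if hi >= min(self.image_height, self.image_width) / 4:
            raise ValueError("largest MC diameter must be < min(image dims)/4")
        clo, chi = self.mc_contrast_range
        if not (0 < clo <= chi):
            raise ValueError("mc_contrast_range must be positive and ordered")
        if not 0 <= self.mc_shape_irregularity <= 1:
            raise ValueError("mc_shape_irregularity must lie in [0, 1]")
        if self.n_mcs < 0 or self.n_clusters < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sigma < 0 or self.tissue_texture_scale <= 0:
            raise ValueError("noise_sigma >= 0 and tissue_texture_scale > 0 required")


@dataclass
class Mammogram:
    """A 2D grayscale intensity image with a physical pixel spacing."""

    pixels: np.ndarray
    pixel_spacing_mm: float = 0.05

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("mammogram pixels must be a 2D array")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be finite and non-negative")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MCMask:
    """Binary per-pixel microcalcification mask paired with a mammogram."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("mask must be a 2D array")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.pixels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def breast_support(config: PhantomConfig) -> np.ndarray:
    """Binary breast region: a half-ellipse flush against the left edge.

    The boundary is smoothed so the tissue-to-background transition spans a
    few pixels, as it does on real mammograms.
    """
    h, w = config.image_height, config.image_width
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    a = 0.46 * h   # semi-axis along rows
    b = 0.85 * w   # semi-axis along columns
    ell = ((rr - h / 2.0) / a) ** 2 + (cc / b) ** 2
    return ell <= 1.0


def _soft_breast_edge(support: np.ndarray, width_px: float = 3.0) -> np.ndarray:
    """Smooth [0, 1] apodization of the binary support."""
    return ndimage.gaussian_filter(support.astype(np.float64), sigma=width_px)


def _tissue_field(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Low-pass-filtered random field emulating mixed tissue density."""
    h, w = config.image_height, config.image_width
    raw = rng.standard_normal((h, w))
    smooth = ndimage.gaussian_filter(raw, sigma=config.tissue_texture_scale)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return 0.45 + 0.08 * smooth   # mean tissue level with mild variation


def _blob_profile(
    diameter_px: float,
    irregularity: float,
    softness_px: float,
    anisotropy: float,
    angle: float,
    harmonics: np.ndarray,
    phases: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One MC: a star-shaped mask and a soft-shouldered intensity bump.

    The outline radius is ``r0 * (1 + irregularity * w(theta))`` with w a
    band-limited periodic perturbation, so the shape ranges continuously
    from circular (irregularity 0) to strongly irregular.  The intensity
    profile extends ``softness_px`` beyond the mask boundary, giving the
    weakly defined borders typical of small lesions under partial-volume
    blurring.
    """
    r0 = diameter_px / 2.0
    half = int(np.ceil(r0 * (1.0 + irregularity) + softness_px + 2))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * xx + sa * yy
    v = -sa * xx + ca * yy
    dist = np.hypot(u / anisotropy, v * anisotropy)
    theta = np.arctan2(v, u)
    # amplitude halved per harmonic; total |w| <= 1 so the radius stays > 0
    pert = np.zeros_like(theta)
    norm = 0.0
    for k, (hk, ph) in enumerate(zip(harmonics, phases), start=1):
        pert += hk * np.cos(k * theta + ph)
        norm += abs(hk)
    if norm > 0:
        pert = pert / norm
    radius = r0 * (1.0 + 0.5 * irregularity * pert)
    mask = dist <= radius
    # soft shoulder: 1 inside, cosine falloff across softness_px outside
    excess = np.clip((dist - radius) / max(softness_px, 1e-6), 0.0, 1.0)
    bump = 0.5 * (1.0 + np.cos(np.pi * excess))
    return mask, bump


def _sample_centers(
    config: PhantomConfig,
    allowed: np.ndarray,
    radii: Sequence[float],
    rng: np.random.Generator,
    max_retries: int = 200,
) -> list[tuple[int, int]]:
    """Rejection-sample non-overlapping MC centers inside ``allowed``.

    With clustering enabled, MCs are assigned round-robin to cluster seeds
    and drawn within ``cluster_radius_px`` of their seed.
    """
    coords = np.argwhere(allowed)
    if coords.size == 0:
        raise PlacementError("no interior breast pixels available for MC placement")
    cluster_seeds: list[np.ndarray] = []
    if config.n_clusters > 0:
        picks = rng.choice(len(coords), size=config.n_clusters, replace=False)
        cluster_seeds = [coords[p].astype(np.float64) for p in picks]

    centers: list[tuple[int, int]] = []
    for i, r_i in enumerate(radii):
        placed = False
        for _ in range(max_retries):
            if cluster_seeds:
                seed_pt = cluster_seeds[i % len(cluster_seeds)]
                ang = rng.uniform(0, 2 * np.pi)
                rad = config.cluster_radius_px * np.sqrt(rng.uniform())
                cand = np.rint(seed_pt + rad * np.array([np.sin(ang), np.cos(ang)]))
                r, c = int(cand[0]), int(cand[1])
                if not (
                    0 <= r < allowed.shape[0]
                    and 0 <= c < allowed.shape[1]
                    and allowed[r, c]
                ):
                    continue
            else:
                r, c = coords[rng.integers(len(coords))]
            ok = True
            for j, (pr, pc) in enumerate(centers):
                min_sep = r_i + radii[j] + 3.0
                if (r - pr) ** 2 + (c - pc) ** 2 < min_sep**2:
                    ok = False
                    break
            if ok:
                centers.append((int(r), int(c)))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place MC {i + 1}/{len(radii)} without overlap "
                f"after {max_retries} retries"
            )
    return centers


def generate_phantom(config: PhantomConfig) -> tuple[Mammogram, MCMask]:
    """Generate one phantom image and its ground-truth MC mask.

    Deterministic given ``config.seed``.  Raises :class:`PlacementError`
    when the requested number of non-overlapping MCs does not fit.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width

    support = breast_support(config)
    apod = _soft_breast_edge(support)
    tissue = _tissue_field(config, rng)
    image = 0.02 + tissue * apod

    mask = np.zeros((h, w), dtype=np.uint8)
    if config.n_mcs > 0:
        diam_lo, diam_hi = config.mc_diameter_range
        diams = rng.uniform(diam_lo, diam_hi, size=config.n_mcs)
        radii = [
            d / 2.0 * (1 + 0.5 * config.mc_shape_irregularity) + 3 for d in diams
        ]
        # keep whole blobs (incl. soft shoulder) strictly inside the breast
        margin = int(np.ceil(max(radii) + 3))
        allowed = ndimage.binary_erosion(support, iterations=margin)
        centers = _sample_centers(config, allowed, radii, rng)
        for (r, c), d in zip(centers, diams):
            contrast = rng.uniform(*config.mc_contrast_range)
            anis = np.exp(rng.uniform(-0.25, 0.25))
            angle = rng.uniform(0, np.pi)
            harmonics = rng.uniform(0.0, 1.0, size=4)
            phases = rng.uniform(0, 2 * np.pi, size=4)
            blob_mask, bump = _blob_profile(
                d,
                config.mc_shape_irregularity,
                softness_px=1.5,
                anisotropy=anis,
                angle=angle,
                harmonics=harmonics,
                phases=phases,
            )
            half = blob_mask.shape[0] // 2
            r0, r1 = r - half, r + half + 1
            c0, c1 = c - half, c + half + 1
            local_bg = image[r, c]
            image[r0:r1, c0:c1] += contrast * local_bg * bump
            mask[r0:r1, c0:c1] |= blob_mask.astype(np.uint8)

    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=(h, w))
    image = np.clip(image, 0.0, 1.0)
    return Mammogram(image, config.pixel_spacing_mm), MCMask(mask)


@dataclass
class PhantomSample:
    """One generated phantom with its split assignment."""

    image_id: str
    image: Mammogram
    mask: MCMask
    split: str
    seed: int


@dataclass
class PhantomDataset:
    """Image-level train/validation/test partition of generated phantoms."""

    samples: list[PhantomSample] = field(default_factory=list)

    def split_ids(self, split: str) -> list[str]:
        return [s.image_id for s in self.samples if s.split == split]

    def subset(self, split: str) -> list[PhantomSample]:
        return [s for s in self.samples if s.split == split]

    def __len__(self) -> int:
        return len(self.samples)


def generate_dataset(
    config_list: Sequence[PhantomConfig],
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    shuffle_seed: int | None = None,
) -> PhantomDataset:
    """Generate phantoms and partition them into disjoint image-level splits.

    The split is by whole image: no image contributes patches to two splits.
    Counts are ``round(n * f_train)`` / ``round(n * f_val)`` with the test
    split taking the remainder.
    """
    if len(config_list) == 0:
        raise ValueError("config_list must contain at least one PhantomConfig")
    fr = np.asarray(split_fractions, dtype=float)
    if fr.shape != (3,) or np.any(fr < 0) or not np.isclose(fr.sum(), 1.0):
        raise ValueError("split_fractions must be 3 non-negative values summing to 1")

    n = len(config_list)
    order = np.arange(n)
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(n)
    n_train = int(round(n * fr[0]))
    n_val = int(round(n * fr[1]))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)

    ds = PhantomDataset()
    for pos, idx in enumerate(order):
        split = "train" if pos < n_train else ("val" if pos < n_train + n_val else "test")
        cfg = config_list[idx]
        image, mask = generate_phantom(cfg)
        ds.samples.append(
            PhantomSample(
                image_id=f"phantom_{idx:04d}",
                image=image,
                mask=mask,
                split=split,
                seed=cfg.seed,
            )
        )
    return ds


def phantom_grid_configs(
    n: int, base: PhantomConfig | None = None, seed0: int = 0
) -> list[PhantomConfig]:
    """Convenience: n copies of a base config with consecutive seeds."""
    base = base if base is not None else PhantomConfig()
    return [replace(base, seed=seed0 + i) for i in range(n)]
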