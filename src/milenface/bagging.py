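"""Pre-processing and bag decomposition of en face images.

An en face image is denoised with a Gaussian filter, standardized to zero
mean / unit standard deviation over the whole image, and cut into a
``grid_side x grid_side`` checkerboard of equally sized instances that
inherit the image's bag label. The grid is taken from a centered crop when
the image side is not divisible by the grid side (e.g. 2044x2048 on a 10x10
grid gives 100 instances of 204x204 from a crop offset of (2, 4)), so the
information loss is symmetric at the border. ``stitch_instances`` inverts
the decomposition, which is how per-instance saliency maps are reassembled
into whole-image overlays.

Conventions fixed here and relied on everywhere else: origin top-left,
0-based (row, col) coordinates, row-major instance order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "EnFaceImage",
    "Bag",
    "DegenerateImageError",
    "denoise_standardize",
    "make_bag",
    "stitch_instances",
    "augment_instance",
]


class DegenerateImageError(ValueError):
    """Raised when an image cannot be standardized (zero variance)."""


@dataclass
class EnFaceImage:
    """One grayscale retina image with its weak (bag-level) label."""

    pixels: np.ndarray
    bag_label: int = 0
    severity: str = "unknown"
    source_path: str | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.bag_label not in (0, 1):
            raise ValueError("bag_label must be 0 or 1")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class Bag:
    """Row-major ordered grid of instances inheriting the bag label."""

    instances: list[np.ndarray]
    grid_side: int
    crop_offset: tuple[int, int]
    bag_label: int
    full_shape: tuple[int, int]
    severity: str = "unknown"
    source_path: str | None = None

    def __post_init__(self) -> None:
        if len(self.instances) != self.grid_side**2:
            raise ValueError(
                f"expected {self.grid_side ** 2} instances, got {len(self.instances)}"
            )
        shapes = {inst.shape for inst in self.instances}
        if len(shapes) != 1:
            raise ValueError(f"instances have inhomogeneous shapes: {shapes}")

    @property
    def instance_shape(self) -> tuple[int, int]:
        return self.instances[0].shape

    def __len__(self) -> int:
        return len(self.instances)


def denoise_standardize(
    image: EnFaceImage, sigma: float = 1.0, blur: bool = True
) -> EnFaceImage:
    """Gaussian-denoise (reflect boundary) and standardize an image.

    After this call the pixel mean is 0 and the standard deviation 1 over
    the whole image. Standardization is idempotent: a second application
    (with ``blur=False``) is a no-op up to floating-point error.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    pix = image.pixels
    if blur and sigma > 0:
        pix = gaussian_filter(pix, sigma=sigma, mode="reflect")
    std = pix.std()
    if std == 0 or not np.isfinite(std):
        raise DegenerateImageError(
            "image has zero variance after blurring; cannot standardize"
        )
    pix = (pix - pix.mean()) / std
    return replace(image, pixels=pix, standardized=True)


def make_bag(image: EnFaceImage, grid_side: int) -> Bag:
    """Cut an image into ``grid_side**2`` equal instances (centered crop).

    Instance sides are ``floor(H / grid_side)`` by ``floor(W / grid_side)``;
    leftover rows/columns are split evenly between the opposing borders
    (extra pixel going to the bottom/right).
    """
    if grid_side < 1:
        raise ValueError("grid_side must be >= 1")
    h, w = image.pixels.shape
    if grid_side > h or grid_side > w:
        raise ValueError(f"grid_side {grid_side} exceeds image shape {(h, w)}")
    s_h, s_w = h // grid_side, w // grid_side
    off_r = (h - s_h * grid_side) // 2
    off_c = (w - s_w * grid_side) // 2
    instances = []
    for gi in range(grid_side):
        for gj in range(grid_side):
            r0 = off_r + gi * s_h
            c0 = off_c + gj * s_w
            instances.append(image.pixels[r0 : r0 + s_h, c0 : c0 + s_w].copy())
    return Bag(
        instances=instances,
        grid_side=grid_side,
        crop_offset=(off_r, off_c),
        bag_label=image.bag_label,
        full_shape=(h, w),
        severity=image.severity,
        source_path=image.source_path,
    )


def stitch_instances(
    maps: list[np.ndarray],
    grid_side: int,
    crop_offset: tuple[int, int] = (0, 0),
    full_shape: tuple[int, int] | None = None,
    fill_value: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Reassemble per-instance maps into a full-image array.

    The inverse of :func:`make_bag` on the cropped region. Returns the
    stitched array and a boolean coverage mask; pixels outside the crop
    (present only when the image side was not grid-divisible) hold
    ``fill_value`` and are flagged False in the mask.
    """
    if len(maps) != grid_side**2:
        raise ValueError(f"expected {grid_side ** 2} maps, got {len(maps)}")
    shapes = {np.asarray(m).shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"maps have inhomogeneous shapes: {shapes}")
    (s_h, s_w) = shapes.pop()
    off_r, off_c = crop_offset
    if full_shape is None:
        full_shape = (off_r + s_h * grid_side, off_c + s_w * grid_side)
    out = np.full(full_shape, fill_value, dtype=np.float64)
    covered = np.zeros(full_shape, dtype=bool)
    for idx, m in enumerate(maps):
        gi, gj = divmod(idx, grid_side)
        r0 = off_r + gi * s_h
        c0 = off_c + gj * s_w
        out[r0 : r0 + s_h, c0 : c0 + s_w] = m
        covered[r0 : r0 + s_h, c0 : c0 + s_w] = True
    return out, covered


def augment_instance(
    instance: np.ndarray,
    rng: np.random.Generator,
    brightness_range: float = 0.1,
    contrast_range: float = 0.1,
) -> np.ndarray:
    """Random quarter-rotation plus brightness/contrast jitter.

    The rotation count k is uniform over {0,1,2,3}; brightness is an
    additive shift U(-b, b) in standardized units and contrast a
    multiplicative scale U(1-c, 1+c). Deterministic under a fixed rng state.
    """
    k = int(rng.integers(0, 4))
    delta = rng.uniform(-brightness_range, brightness_range)
    gamma = rng.uniform(1.0 - contrast_range, 1.0 + contrast_range)
    out = np.rot90(instance, k)
    return gamma * out + delta
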