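"""Grad-CAM saliency maps per instance, stitched to whole-image overlays.

For a convolutional feature map A with channels c, the class-activation map
is ReLU(sum_c w_c * A_c) with w_c the spatial average of the score gradient
d(score)/dA_c, bilinearly upsampled to the instance size. Per-instance maps
of a bag are min-max normalized jointly (one normalization record per bag)
so the stitched overlay is comparable across the whole image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .bagging import Bag, stitch_instances
from .nn import Conv2d, Network, ResidualBlock

__all__ = ["SaliencyMap", "grad_cam", "explain_bag", "save_overlay", "save_raw_map", "lesion_mass"]


def default_target(model: Network) -> str:
    """The final convolution before global average pooling."""
    for layer in reversed(model.layers):
        if isinstance(layer, ResidualBlock):
            return layer.conv3.name
        if isinstance(layer, Conv2d):
            return layer.name
    raise ValueError("model has no convolutional layer to target")


@dataclass
class SaliencyMap:
    """Per-instance heatmaps plus their stitched full-image assembly."""

    per_instance: list[np.ndarray]  # raw nonnegative maps, instance-sized
    normalized: list[np.ndarray]  # jointly min-max normalized to [0, 1]
    stitched: np.ndarray  # normalized maps in bag geometry
    coverage: np.ndarray  # False where the crop left the source uncovered
    vmin: float
    vmax: float


def grad_cam(
    model: Network, instance: np.ndarray, target_layer: str | None = None
) -> np.ndarray:
    """Raw (unnormalized) Grad-CAM heatmap of one instance.

    Gradients are taken of the instance score (the pre-sigmoid logit), not
    of a loss, so the map highlights what pushes the score up. The default
    target is the last convolution before global average pooling.
    """
    layer = model.get_layer(target_layer or default_target(model))
    layer.capture = True
    try:
        x = np.asarray(instance, dtype=np.float32)[None, :, :, None]
        score = model.forward(x)
        model.backward(np.ones_like(score))
        activation = layer.captured_activation
        gradient = layer.captured_gradient
    finally:
        layer.capture = False
        layer.captured_activation = None
        layer.captured_gradient = None
    if activation is None or activation.ndim != 4:
        raise ValueError(
            f"layer {target_layer!r} has no spatial feature map; pick a convolution"
        )
    weights = gradient[0].mean(axis=(0, 1))  # (C,)
    cam = np.maximum(activation[0] @ weights, 0.0)
    return resize(
        cam.astype(np.float64),
        instance.shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


def explain_bag(
    model: Network,
    bag: Bag,
    target_layer: str | None = None,
    normalize: str = "bag",
) -> SaliencyMap:
    """Grad-CAM every instance of a bag and stitch the normalized maps.

    ``normalize='bag'`` (default) min-max normalizes jointly over the bag;
    ``'instance'`` normalizes each map on its own.
    """
    maps = [grad_cam(model, inst, target_layer) for inst in bag.instances]
    if normalize == "bag":
        vmin = float(min(m.min() for m in maps))
        vmax = float(max(m.max() for m in maps))
        span = (vmax - vmin) or 1.0
        normed = [(m - vmin) / span for m in maps]
    elif normalize == "instance":
        vmin, vmax = float("nan"), float("nan")
        normed = []
        for m in maps:
            span = (m.max() - m.min()) or 1.0
            normed.append((m - m.min()) / span)
    else:
        raise ValueError("normalize must be 'bag' or 'instance'")
    stitched, coverage = stitch_instances(
        normed, bag.grid_side, bag.crop_offset, bag.full_shape
    )
    return SaliencyMap(
        per_instance=maps,
        normalized=normed,
        stitched=stitched,
        coverage=coverage,
        vmin=vmin,
        vmax=vmax,
    )


def save_overlay(
    image_pixels: np.ndarray,
    saliency: SaliencyMap,
    path: str | Path,
    alpha: float = 0.45,
    cmap: str = "inferno",
) -> None:
    """Blend the stitched heatmap over the grayscale image and write a PNG."""
    import imageio.v3 as iio
    import matplotlib

    gray = np.asarray(image_pixels, dtype=np.float64)
    lo, hi = gray.min(), gray.max()
    gray = (gray - lo) / ((hi - lo) or 1.0)
    heat = matplotlib.colormaps[cmap](np.clip(saliency.stitched, 0.0, 1.0))[..., :3]
    rgb = (1.0 - alpha) * gray[..., None] + alpha * heat
    iio.imwrite(Path(path), np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8))


def save_raw_map(saliency: SaliencyMap, path: str | Path) -> None:
    """Write the stitched (normalized) map as a 32-bit float TIFF."""
    import tifffile

    tifffile.imwrite(Path(path), saliency.stitched.astype(np.float32))


def lesion_mass(
    stitched: np.ndarray,
    lesion_mask: np.ndarray,
    rng: np.random.Generator,
    n_controls: int = 20,
) -> tuple[float, float]:
    """Mean saliency inside the lesion mask vs matched random controls.

    Controls are circular shifts of the mask, preserving its area and shape,
    so the comparison is not confounded by lesion size. Returns
    ``(mass_inside, mean_control_mass)``.
    """
    mask = np.asarray(lesion_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lesion mask")
    inside = float(stitched[mask].mean())
    controls = []
    for _ in range(n_controls):
        dr = int(rng.integers(0, mask.shape[0]))
        dc = int(rng.integers(0, mask.shape[1]))
        shifted = np.roll(np.roll(mask, dr, axis=0), dc, axis=1)
        controls.append(float(stitched[shifted].mean()))
    return inside, float(np.mean(controls))
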