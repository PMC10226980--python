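"""Synthetic widefield OCTA en face phantoms with ground-truth lesions.

The clinical dataset behind the method is not publicly available, so this
module renders stand-in phantoms that reproduce the *structure* the MIL
pipeline depends on rather than OCTA physics: a dark speckle background, a
bright branching vessel tree radiating from an optic-nerve-head disc, a
capillary-scale mesh, a darker foveal spot, and — in diabetic-labeled images
only — localized lesions of three kinds (dark ischemic dropouts, tortuous
abnormal vessel segments, bright dot lesions) planted in a random subset of
grid cells. Every lesion pixel is recorded in a binary mask, so instance-level
ground truth exists even though the training pipeline never sees it.

Label structure mirrors the clinical study: lesions occur only in positive
bags (the standard multiple-instance assumption), only a fraction of cells in
a positive bag carry lesions (asymmetric label noise once instances inherit
the bag label), and a configurable fraction of positive bags carries no
lesion at all (the "diabetic, no visible signs" subgroup).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .bagging import EnFaceImage
from .config import PhantomConfig, child_rng

__all__ = [
    "BackgroundScene",
    "Phantom",
    "render_background",
    "plant_lesions",
    "generate_phantoms",
    "generate_dataset",
]

_SPLIT_INDEX = {"train": 0, "val": 1, "test": 2}


@dataclass
class BackgroundScene:
    """A lesion-free rendered retina with its vessel mask and landmarks."""

    image: np.ndarray
    vessel_mask: np.ndarray
    onh_center: tuple[float, float]
    fovea_center: tuple[float, float]


@dataclass
class Phantom:
    """A rendered bag with ground truth the pipeline never trains on."""

    image: np.ndarray
    bag_label: int
    severity: str
    lesion_mask: np.ndarray
    cell_flags: np.ndarray  # row-major grid_side**2 booleans
    grid_side: int

    def __post_init__(self) -> None:
        if self.lesion_mask.any() and self.bag_label != 1:
            raise ValueError("lesions may only occur in positive bags")

    def to_enface(self) -> EnFaceImage:
        return EnFaceImage(
            pixels=self.image, bag_label=self.bag_label, severity=self.severity
        )


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _stamp_disk(
    canvas: np.ndarray, row: float, col: float, radius: float, value: float
) -> None:
    """Max-blend a soft Gaussian disk into the canvas."""
    side = canvas.shape[0]
    r_ext = int(np.ceil(2.2 * radius)) + 1
    r0, r1 = int(row) - r_ext, int(row) + r_ext + 1
    c0, c1 = int(col) - r_ext, int(col) + r_ext + 1
    r0c, r1c = max(r0, 0), min(r1, side)
    c0c, c1c = max(c0, 0), min(c1, canvas.shape[1])
    if r0c >= r1c or c0c >= c1c:
        return
    rr = np.arange(r0c, r1c, dtype=np.float64)[:, None] - row
    cc = np.arange(c0c, c1c, dtype=np.float64)[None, :] - col
    blob = value * np.exp(-(rr**2 + cc**2) / (2.0 * max(radius, 0.5) ** 2))
    region = canvas[r0c:r1c, c0c:c1c]
    np.maximum(region, blob, out=region)


def _grow_vessel(
    canvas: np.ndarray,
    rng: np.random.Generator,
    pos: np.ndarray,
    angle: float,
    width: float,
    n_steps: int,
    depth: int,
    intensity: float,
    wiggle: float = 0.12,
) -> None:
    side = canvas.shape[0]
    step = 1.5
    for _ in range(n_steps):
        pos = pos + step * np.array([np.sin(angle), np.cos(angle)])
        if not (0 <= pos[0] < side and 0 <= pos[1] < side):
            return
        _stamp_disk(canvas, pos[0], pos[1], width, intensity)
        angle += rng.normal(0.0, wiggle)
        width = max(0.6, width * 0.9965)
        if depth < 2 and rng.random() < 0.025:
            _grow_vessel(
                canvas,
                rng,
                pos.copy(),
                angle + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0),
                width * 0.65,
                int(n_steps * 0.6),
                depth + 1,
                intensity * 0.9,
                wiggle,
            )


def render_background(config: PhantomConfig, rng: np.random.Generator) -> BackgroundScene:
    """Render one lesion-free phantom retina in [0, 1]."""
    side = config.image_side
    # dark multiplicative-looking speckle floor
    speckle = rng.gamma(2.0, 0.5, size=(side, side))
    image = 0.07 * gaussian_filter(speckle, 0.8)
    image += config.noise_level * rng.standard_normal((side, side))
    # capillary mesh: bright filaments along the zero crossings of smooth noise
    smooth = gaussian_filter(rng.standard_normal((side, side)), 2.0 * side / 384.0)
    ridges = np.exp(-((smooth / (0.25 * smooth.std() + 1e-12)) ** 2))
    image += 0.22 * ridges

    # optic nerve head on the left or right margin, fovea offset toward center
    onh_row = rng.uniform(0.35, 0.65) * side
    onh_col = (0.12 if rng.random() < 0.5 else 0.88) * side
    fovea_row = onh_row + rng.uniform(-0.05, 0.05) * side
    fovea_col = side / 2.0 + (side * 0.18 if onh_col < side / 2 else -side * 0.18)

    vessels = np.zeros((side, side))
    if config.vessel_intensity > 0:
        toward_center = np.arctan2(side / 2.0 - onh_row, side / 2.0 - onh_col)
        for _ in range(config.n_branches):
            angle = toward_center + rng.uniform(-1.2, 1.2)
            _grow_vessel(
                vessels,
                rng,
                np.array([onh_row, onh_col]),
                angle,
                width=config.vessel_width * rng.uniform(0.8, 1.3),
                n_steps=int(side * 0.9 / 1.5),
                depth=0,
                intensity=config.vessel_intensity,
            )
        # ONH disc
        rr = np.arange(side)[:, None] - onh_row
        cc = np.arange(side)[None, :] - onh_col
        dist2 = rr**2 + cc**2
        disc = 0.5 * np.exp(-((np.sqrt(dist2) / (0.045 * side)) ** 4))
        vessels = np.maximum(vessels, disc)
    vessel_mask = vessels > 0.3 * max(config.vessel_intensity, 1e-9)
    image = np.maximum(image, vessels)

    # foveal dip (darker avascular spot)
    rr = np.arange(side)[:, None] - fovea_row
    cc = np.arange(side)[None, :] - fovea_col
    dip = np.exp(-(rr**2 + cc**2) / (2.0 * (0.045 * side) ** 2))
    image *= 1.0 - 0.55 * dip

    return BackgroundScene(
        image=np.clip(image, 0.0, 1.0),
        vessel_mask=vessel_mask,
        onh_center=(onh_row, onh_col),
        fovea_center=(fovea_row, fovea_col),
    )


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------

def _cell_box(config: PhantomConfig, cell_index: int) -> tuple[int, int, int]:
    """(row0, col0, side) of a grid cell, matching make_bag's centered crop."""
    g = config.grid_side
    s = config.image_side // g
    off = (config.image_side - s * g) // 2
    gi, gj = divmod(cell_index, g)
    return off + gi * s, off + gj * s, s


def _plant_ischemia(img, mask, rng, box) -> None:
    """Elliptical capillary dropout: signal attenuated to the dark floor.

    Confined to the cell so the ground-truth cell flags stay exact.
    """
    r0, c0, s = box
    cell = img[r0 : r0 + s, c0 : c0 + s]
    cr = rng.uniform(0.35, 0.65) * s
    cc = rng.uniform(0.35, 0.65) * s
    a = rng.uniform(0.28, 0.45) * s
    b = rng.uniform(0.28, 0.45) * s
    theta = rng.uniform(0, np.pi)
    rr = np.arange(s)[:, None] - cr
    ccg = np.arange(s)[None, :] - cc
    u = rr * np.cos(theta) + ccg * np.sin(theta)
    v = -rr * np.sin(theta) + ccg * np.cos(theta)
    d2 = (u / a) ** 2 + (v / b) ** 2
    soft = np.exp(-(d2**2))  # flat-ish core, quick falloff
    cell *= 1.0 - 0.95 * soft
    cell += 0.03 * soft  # residual dark floor, like capillary dropout
    mask[r0 : r0 + s, c0 : c0 + s] |= soft > 0.35


def _plant_abnormal_vessel(img, mask, rng, box) -> None:
    r0, c0, s = box
    canvas = np.zeros((s, s))
    pos = np.array([rng.uniform(0.25, 0.75) * s, rng.uniform(0.25, 0.75) * s])
    angle = rng.uniform(0, 2 * np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    base_w = rng.uniform(1.8, 3.0)  # wide enough to survive sigma-1 denoising
    margin = 8.0  # keep the stamped footprint inside the cell
    for t in range(int(s * 1.1)):
        pos += 1.1 * np.array([np.sin(angle), np.cos(angle)])
        # reflect off the cell walls to stay inside the instance
        if not margin <= pos[0] < s - margin:
            angle = -angle
            pos[0] = np.clip(pos[0], margin, s - margin - 1)
        if not margin <= pos[1] < s - margin:
            angle = np.pi - angle
            pos[1] = np.clip(pos[1], margin, s - margin - 1)
        width = base_w * (1.0 + 0.5 * np.sin(t / 3.0 + phase))
        _stamp_disk(canvas, pos[0], pos[1], max(width, 1.0), 1.0)
        angle += rng.normal(0.0, 0.55)  # high tortuosity
    cell = img[r0 : r0 + s, c0 : c0 + s]
    np.maximum(cell, canvas, out=cell)
    mask[r0 : r0 + s, c0 : c0 + s] |= canvas > 0.3


def _plant_dots(img, mask, rng, box) -> None:
    r0, c0, s = box
    canvas = np.zeros((s, s))
    for _ in range(int(rng.integers(5, 12))):
        row = rng.uniform(0.15, 0.85) * s
        col = rng.uniform(0.15, 0.85) * s
        _stamp_disk(canvas, row, col, rng.uniform(1.8, 3.2), 1.0)
    cell = img[r0 : r0 + s, c0 : c0 + s]
    np.maximum(cell, canvas, out=cell)
    mask[r0 : r0 + s, c0 : c0 + s] |= canvas > 0.3


_PLANTERS = (_plant_ischemia, _plant_abnormal_vessel, _plant_dots)


def plant_lesions(
    scene: BackgroundScene,
    config: PhantomConfig,
    rng: np.random.Generator,
    bag_label: int,
    force_no_signs: bool | None = None,
) -> Phantom:
    """Plant lesions into a rendered background and derive ground truth.

    Healthy bags never receive a lesion. A positive bag is lesion-free with
    probability ``no_signs_fraction`` (severity ``no_signs``); otherwise a
    uniformly drawn fraction of grid cells receives one lesion each, and
    severity is ``mild`` for at most ``mild_max_cells`` affected cells,
    ``severe`` beyond.
    """
    g = config.grid_side
    img = scene.image.copy()
    mask = np.zeros_like(img, dtype=bool)
    if bag_label == 0:
        severity = "healthy"
    else:
        no_signs = (
            force_no_signs
            if force_no_signs is not None
            else bool(rng.random() < config.no_signs_fraction)
        )
        if not no_signs:
            frac = rng.uniform(config.f_min, config.f_max)
            n_cells = int(np.clip(round(frac * g * g), 1, g * g))
            cells = rng.choice(g * g, size=n_cells, replace=False)
            probs = np.array(
                [config.ischemia_prob, config.abnormal_vessel_prob, config.dot_lesion_prob]
            )
            probs = probs / probs.sum()
            for cell in cells:
                planter = _PLANTERS[int(rng.choice(3, p=probs))]
                planter(img, mask, rng, _cell_box(config, int(cell)))
        severity = None  # assigned from the mask below

    flags = np.zeros(g * g, dtype=bool)
    for idx in range(g * g):
        r0, c0, s = _cell_box(config, idx)
        flags[idx] = bool(mask[r0 : r0 + s, c0 : c0 + s].any())
    if bag_label == 1:
        n_flagged = int(flags.sum())
        if n_flagged == 0:
            severity = "no_signs"
        elif n_flagged <= config.mild_max_cells:
            severity = "mild"
        else:
            severity = "severe"
    return Phantom(
        image=np.clip(img, 0.0, 1.0),
        bag_label=bag_label,
        severity=severity,
        lesion_mask=mask,
        cell_flags=flags,
        grid_side=g,
    )


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def generate_phantoms(config: PhantomConfig) -> dict[str, list[Phantom]]:
    """Generate all splits in memory, reproducibly from ``config.seed``."""
    out: dict[str, list[Phantom]] = {}
    for split, (n_pos, n_neg) in config.split_counts.items():
        phantoms = []
        for i in range(n_pos + n_neg):
            label = 1 if i < n_pos else 0
            rng = child_rng(config.seed, _SPLIT_INDEX[split], i)
            scene = render_background(config, rng)
            phantoms.append(plant_lesions(scene, config, rng, label))
        out[split] = phantoms
    return out


def generate_dataset(config: PhantomConfig, out_dir: str | Path):
    """Render all splits to disk: PNG images, binary PNG masks, manifest CSV.

    Returns the written :class:`~milenface.io.Manifest`.
    """
    from . import io as mio  # deferred: io imports mil_core

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    records = []
    for split, phantoms in generate_phantoms(config).items():
        for i, ph in enumerate(phantoms):
            stem = f"{split}_{i:03d}"
            img_rel = f"images/{stem}.png"
            mask_rel = f"masks/{stem}.png"
            mio.write_image(ph.image, out_dir / img_rel, bit_depth=8)
            mio.write_image(ph.lesion_mask.astype(np.float64), out_dir / mask_rel, bit_depth=8)
            records.append(
                mio.ManifestRecord(
                    image_path=img_rel,
                    bag_label=ph.bag_label,
                    severity=ph.severity,
                    subject_id=f"subject_{split}_{i:03d}",
                    split=split,
                    mask_path=mask_rel,
                )
            )
    manifest = mio.Manifest(records=records, root=out_dir)
    mio.write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
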