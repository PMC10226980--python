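"""The compact residual instance classifier.

One grayscale patch in, one unbounded real score (a logit) out. The network
is a stem convolution followed by four residual blocks (three 3x3
convolutions + SeLU each, with a skip connection and 2x2 average pooling),
then global average pooling and a single-unit dense head. SeLU everywhere,
no batch-coupled normalization, so each instance's score depends on that
instance alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Conv2d, Dense, GlobalAvgPool, Network, ResidualBlock, SeLU

__all__ = [
    "InstanceClassifierSpec",
    "build_instance_classifier",
    "predict_instances",
    "count_parameters",
]


@dataclass(frozen=True)
class InstanceClassifierSpec:
    """Architecture hyperparameters of the instance classifier.

    Widths are not dictated by the method; the defaults are sized for
    CPU training on desk-scale phantoms and are freely configurable.
    """

    stem_channels: int = 8
    block_channels: tuple[int, int, int, int] = (12, 16, 24, 32)
    kernel_size: int = 3
    use_residual: bool = True

    def __post_init__(self) -> None:
        if len(self.block_channels) != 4:
            raise ValueError("exactly four blocks are required")
        if self.stem_channels < 1 or any(c < 1 for c in self.block_channels):
            raise ValueError("channel counts must be >= 1")


def build_instance_classifier(
    spec: InstanceClassifierSpec = InstanceClassifierSpec(),
    input_side: int = 64,
    seed: int = 0,
) -> Network:
    """Build the (seeded, deterministic) instance classifier.

    ``input_side`` is only validated, not baked into the weights: the network
    is fully convolutional up to the global average pool, so the same spec
    applied to whole images yields the single-instance-learning benchmark.
    """
    if input_side < 2**4:
        raise ValueError(
            f"input side {input_side} too small: four 2x2 poolings need >= 16"
        )
    side = input_side
    for _ in range(4):
        if side % 2:
            raise ValueError(
                f"input side {input_side} is not divisible by 16 (pooling stages)"
            )
        side //= 2
    rng = np.random.default_rng(seed)
    layers = [
        Conv2d(1, spec.stem_channels, spec.kernel_size, rng, "stem"),
        SeLU("stem_act"),
    ]
    in_ch = spec.stem_channels
    for i, out_ch in enumerate(spec.block_channels, start=1):
        layers.append(
            ResidualBlock(
                in_ch,
                out_ch,
                spec.kernel_size,
                use_residual=spec.use_residual,
                rng=rng,
                name=f"block{i}",
            )
        )
        in_ch = out_ch
    layers.append(GlobalAvgPool("gap"))
    layers.append(Dense(in_ch, 1, rng, "head"))
    return Network(layers)


def predict_instances(model: Network, bag, batch_size: int = 64):
    """Score every instance of a bag, preserving row-major order.

    Returns a :class:`~milenface.mil_core.ScoreSet` of unbounded real scores
    (no sigmoid squashing — the sigmoid lives inside the losses only).
    """
    from .mil_core import ScoreSet  # local import to avoid a cycle

    arr = np.asarray(bag.instances, dtype=np.float32)[..., None]
    scores = predict_array(model, arr, batch_size=batch_size)
    return ScoreSet(
        instance_scores=scores,
        bag_label=bag.bag_label,
        source_path=getattr(bag, "source_path", None),
    )


def predict_array(
    model: Network, instances: np.ndarray, batch_size: int = 64
) -> np.ndarray:
    """Score a (N,1,H,W) batch of instances; returns (N,) float64 logits."""
    out = []
    for start in range(0, len(instances), batch_size):
        chunk = instances[start : start + batch_size]
        out.append(model.forward(chunk)[:, 0].astype(np.float64))
    return np.concatenate(out) if out else np.empty(0)


def count_parameters(model: Network, trainable_only: bool = True) -> int:
    """Exact count of (trainable) scalar parameters."""
    return model.n_parameters(trainable_only=trainable_only)
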