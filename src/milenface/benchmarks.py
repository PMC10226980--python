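"""Single-instance-learning (SIL) benchmark classifiers.

Two comparison architectures trained on whole en face images with plain
supervised binary cross entropy: (1) the same residual network as the MIL
instance classifier, just consuming the full image (the builder is shared,
so "identical architecture" holds by construction); (2) a VGG16
convolutional base with a small custom head — global average pooling, a
512->64 affine layer and a 64->1 output — in which only the final
convolutional block and the head are trainable. The VGG16 parameter
identities (14,747,585 total, 7,112,321 trainable) are architecture-forced
and independent of data or weights; the head width 64 is the unique width
consistent with those totals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .bagging import EnFaceImage, augment_instance
from .config import RunConfig, child_rng
from .instance_model import InstanceClassifierSpec, build_instance_classifier
from .nn import Adam, Conv2d, Dense, GlobalAvgPool, MaxPool2d, Network, SeLU
from .mil_core import instance_loss_grad

__all__ = ["build_sil_resnet", "build_vgg16_head", "train_sil", "VGG16_WIDTHS"]

logger = logging.getLogger("milenface.benchmarks")

# the standard VGG16 convolutional configuration: (width, convs per block)
VGG16_WIDTHS = ((64, 2), (128, 2), (256, 3), (512, 3), (512, 3))


def build_sil_resnet(
    spec: InstanceClassifierSpec, input_side: int, seed: int = 0
) -> Network:
    """The instance classifier applied to whole images (shared builder)."""
    return build_instance_classifier(spec, input_side, seed=seed)


def build_vgg16_head(seed: int = 0, n_trainable_conv_blocks: int = 1) -> Network:
    """VGG16 base + GAP + 512->64 + 64->1 head with frozen early blocks.

    Only the last ``n_trainable_conv_blocks`` convolutional blocks (default:
    block 5, i.e. three 3x3x512 convolutions) and the two affine head layers
    are trainable — the classic transfer-learning layout of retraining the
    last six layers over a frozen pretrained base. Weights are seeded
    random; pretrained weights can be loaded into ``params`` when available.
    """
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = 3  # VGG16 is an RGB architecture; grayscale inputs are replicated
    n_blocks = len(VGG16_WIDTHS)
    for b, (width, n_convs) in enumerate(VGG16_WIDTHS, start=1):
        trainable = b > n_blocks - n_trainable_conv_blocks
        for c in range(1, n_convs + 1):
            conv = Conv2d(in_ch, width, 3, rng, f"block{b}.conv{c}")
            conv.trainable = trainable
            layers.append(conv)
            layers.append(SeLU())
            in_ch = width
        layers.append(MaxPool2d(f"block{b}.pool"))
    layers.append(GlobalAvgPool("gap"))
    layers.append(Dense(512, 64, rng, "fc1"))
    layers.append(SeLU())
    layers.append(Dense(64, 1, rng, "fc2"))
    return Network(layers)


def train_sil(
    model: Network,
    images_by_split: dict[str, list[EnFaceImage]],
    config: RunConfig,
    batch_size: int = 8,
) -> tuple[Network, pd.DataFrame]:
    """Supervised whole-image training with early stopping on val ROC AUC.

    Shares the augmentation and seeding machinery of the MIL loop; the loss
    is unweighted binary cross entropy on image labels (no label noise here,
    so no healthy-instance preference).
    """
    train_imgs = images_by_split.get("train") or []
    val_imgs = images_by_split.get("val") or []
    if not train_imgs:
        raise ValueError("train split is empty")
    if len({im.bag_label for im in val_imgs}) < 2:
        raise ValueError("validation split must contain both classes")
    rng = child_rng(config.seed, 21)
    optimizer = Adam(model, learning_rate=config.learning_rate)
    x_train = np.asarray([im.pixels for im in train_imgs], dtype=np.float32)[..., None]
    y_train = np.array([im.bag_label for im in train_imgs])
    x_val = np.asarray([im.pixels for im in val_imgs], dtype=np.float32)[..., None]
    y_val = np.array([im.bag_label for im in val_imgs])
    in_ch = _input_channels(model)

    def scores(x: np.ndarray) -> np.ndarray:
        out = []
        for start in range(0, len(x), batch_size):
            chunk = np.repeat(x[start : start + batch_size], in_ch, axis=3)
            out.append(model.forward(chunk)[:, 0].astype(np.float64))
        return np.concatenate(out)

    history_rows = []
    best_state, best_auc, since = model.clone_state(), -np.inf, 0
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(perm), batch_size):
            idx = perm[start : start + batch_size]
            batch = np.stack(
                [
                    augment_instance(
                        x_train[i, :, :, 0],
                        rng,
                        config.brightness_range,
                        config.contrast_range,
                    )
                    for i in idx
                ]
            ).astype(np.float32)[..., None]
            batch = np.repeat(batch, in_ch, axis=3)
            logits = model.forward(batch)[:, 0].astype(np.float64)
            loss, grad = instance_loss_grad(logits, y_train[idx], 1.0)
            model.backward(grad.astype(np.float32)[:, None])
            optimizer.step()
            losses.append(loss * len(idx))
        val_auc = float(roc_auc_score(y_val, scores(x_val)))
        history_rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.sum(losses) / len(perm)),
                "val_roc_auc": val_auc,
            }
        )
        logger.info("SIL epoch %d: val ROC AUC %.3f", epoch, val_auc)
        if val_auc > best_auc:
            best_auc, best_state, since = val_auc, model.clone_state(), 0
        else:
            since += 1
        if since >= config.patience:
            break
    model.load_state_dict(best_state)
    return model, pd.DataFrame(history_rows)


def _input_channels(model: Network) -> int:
    for layer in model.layers:
        if isinstance(layer, Conv2d):
            return layer.in_channels
    return 1
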