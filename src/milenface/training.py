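"""Instance-level training with bag-level model selection.

The classifier is trained on shuffled instances that carry only their
inherited bag label — no bag affiliation reaches the network. Model
selection, however, happens at the bag level: after every epoch the
validation bags are scored, instance scores are MIL-pooled, and the weights
of the epoch with the highest bag ROC AUC are retained (early stopping with
patience). The deployed decision applies the geometric-mean-optimal ROC
threshold, selected on validation bags, to the top-k-pooled bag score.

The public surface is a model/results pair: build a :class:`MILModel` from
bags (or a manifest on disk, or phantoms in memory), call :meth:`MILModel.fit`,
and read estimates and diagnostics off the returned :class:`MILResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bagging import Bag, augment_instance, denoise_standardize, make_bag
from .config import RunConfig, child_rng
from .instance_model import (
    InstanceClassifierSpec,
    build_instance_classifier,
    predict_array,
)
from .mil_core import (
    EvalReport,
    ScoreSet,
    ThresholdResult,
    auc_mil,
    evaluate,
    instance_loss_grad,
    pool,
    select_threshold,
)
from .nn import Adam, Network

__all__ = ["MILModel", "MILResults", "train", "infer", "load_bags", "bags_from_phantoms"]

logger = logging.getLogger("milenface.training")


def load_bags(manifest, config: RunConfig, splits=("train", "val", "test")) -> dict[str, list[Bag]]:
    """Read, denoise/standardize and decompose every manifest image."""
    from . import io as mio

    out: dict[str, list[Bag]] = {}
    for split in splits:
        bags = []
        for rec in manifest.split(split):
            img = mio.read_image(
                manifest.resolve(rec.image_path), rec.bag_label, rec.severity
            )
            img.source_path = rec.image_path  # manifest-relative: portable outputs
            img = denoise_standardize(img, config.gaussian_sigma)
            bags.append(make_bag(img, config.grid_side))
        out[split] = bags
    return out


def load_images(manifest, config: RunConfig, splits=("train", "val", "test")):
    """Read and standardize whole images (the SIL benchmarks' input)."""
    from . import io as mio

    out: dict[str, list] = {}
    for split in splits:
        images = []
        for rec in manifest.split(split):
            img = mio.read_image(
                manifest.resolve(rec.image_path), rec.bag_label, rec.severity
            )
            img.source_path = rec.image_path
            images.append(denoise_standardize(img, config.gaussian_sigma))
        out[split] = images
    return out


def bags_from_phantoms(phantoms_by_split, config: RunConfig) -> dict[str, list[Bag]]:
    """Decompose in-memory phantoms (same preprocessing as from disk)."""
    out: dict[str, list[Bag]] = {}
    for split, phantoms in phantoms_by_split.items():
        bags = []
        for ph in phantoms:
            img = denoise_standardize(ph.to_enface(), config.gaussian_sigma)
            bags.append(make_bag(img, config.grid_side))
        out[split] = bags
    return out


def _instances_tensor(bags: list[Bag]) -> tuple[np.ndarray, np.ndarray]:
    """Stack all instances (NHWC) with their inherited labels."""
    xs, ys = [], []
    for bag in bags:
        for inst in bag.instances:
            xs.append(inst)
            ys.append(bag.bag_label)
    x = np.asarray(xs, dtype=np.float32)[..., None]
    return x, np.asarray(ys, dtype=np.int64)


@dataclass
class MILModel:
    """The MIL en face classifier, bound to its dataset and configuration."""

    bags: dict[str, list[Bag]]
    config: RunConfig

    def __post_init__(self) -> None:
        if not self.bags.get("train"):
            raise ValueError("train split is empty")
        val = self.bags.get("val") or []
        if len({b.bag_label for b in val}) < 2:
            raise ValueError("validation split must contain both classes")
        shapes = {b.instance_shape for split in self.bags.values() for b in split}
        if len(shapes) != 1:
            raise ValueError(f"instance shapes differ across bags: {shapes}")
        (self.instance_shape,) = shapes
        if self.instance_shape[0] != self.instance_shape[1]:
            raise ValueError("instances must be square for the classifier")

    @classmethod
    def from_manifest(cls, manifest, config: RunConfig) -> "MILModel":
        return cls(load_bags(manifest, config), config)

    @classmethod
    def from_phantoms(cls, phantoms_by_split, config: RunConfig) -> "MILModel":
        return cls(bags_from_phantoms(phantoms_by_split, config), config)

    def build_network(self) -> Network:
        spec = InstanceClassifierSpec(
            stem_channels=self.config.stem_channels,
            block_channels=tuple(self.config.block_channels),
            kernel_size=self.config.kernel_size,
            use_residual=self.config.use_residual,
        )
        init_seed = int(child_rng(self.config.seed, 10).integers(2**31))
        return build_instance_classifier(spec, self.instance_shape[0], seed=init_seed)

    def fit(self) -> "MILResults":
        cfg = self.config
        net = self.build_network()
        optimizer = Adam(net, learning_rate=cfg.learning_rate)
        rng = child_rng(cfg.seed, 11)

        x_train, y_train = _instances_tensor(self.bags["train"])
        val_bags = self.bags["val"]
        val_labels = np.array([b.bag_label for b in val_bags])

        history_rows = []
        best_state = net.clone_state()
        best_auc = -np.inf
        best_epoch = 0
        since_improved = 0
        for epoch in range(1, cfg.epochs + 1):
            perm = rng.permutation(len(x_train))
            losses, n_correct = [], 0
            for start in range(0, len(perm), cfg.batch_size):
                idx = perm[start : start + cfg.batch_size]
                batch = np.stack(
                    [
                        augment_instance(
                            x_train[i, :, :, 0],
                            rng,
                            cfg.brightness_range,
                            cfg.contrast_range,
                        )
                        for i in idx
                    ]
                ).astype(np.float32)[..., None]
                labels = y_train[idx]
                logits = net.forward(batch)[:, 0].astype(np.float64)
                loss, grad = instance_loss_grad(logits, labels, cfg.healthy_weight)
                net.backward(grad.astype(np.float32)[:, None])
                optimizer.step()
                losses.append(loss * len(idx))
                n_correct += int(np.sum((logits > 0).astype(int) == labels))
            train_loss = float(np.sum(losses) / len(perm))
            train_acc = n_correct / len(perm)

            val_scores = [self._score_instances(net, b) for b in val_bags]
            val_auc = auc_mil(
                val_labels, val_scores, cfg.early_stop_pooling, cfg.pool_k
            )
            val_inst_acc = float(
                np.mean(
                    [
                        np.mean((s > 0).astype(int) == b.bag_label)
                        for s, b in zip(val_scores, val_bags)
                    ]
                )
            )
            history_rows.append(
                {
                    "epoch": epoch,
                    "train_inst_acc": train_acc,
                    "val_inst_acc": val_inst_acc,
                    "train_loss": train_loss,
                    "val_bag_auc": val_auc,
                }
            )
            logger.info(
                "epoch %d: train_loss=%.4f train_inst_acc=%.3f val_bag_auc=%.3f",
                epoch,
                train_loss,
                train_acc,
                val_auc,
            )
            if val_auc > best_auc:
                best_auc = val_auc
                best_epoch = epoch
                best_state = net.clone_state()
                since_improved = 0
            else:
                since_improved += 1
            if since_improved >= cfg.patience:
                break

        net.load_state_dict(best_state)
        val_bag_scores = [
            pool(self._score_instances(net, b), cfg.pooling, cfg.pool_k) for b in val_bags
        ]
        threshold = select_threshold(val_labels, val_bag_scores)
        return MILResults(
            model=self,
            network=net,
            history=pd.DataFrame(history_rows),
            best_epoch=best_epoch,
            best_val_auc=float(best_auc),
            threshold=threshold,
        )

    @staticmethod
    def _score_instances(net: Network, bag: Bag) -> np.ndarray:
        arr = np.asarray(bag.instances, dtype=np.float32)[..., None]
        return predict_array(net, arr)


@dataclass
class MILResults:
    """Fitted classifier: best weights, training history and threshold."""

    model: MILModel
    network: Network
    history: pd.DataFrame
    best_epoch: int
    best_val_auc: float
    threshold: ThresholdResult

    @property
    def config(self) -> RunConfig:
        return self.model.config

    def score_bag(self, bag: Bag) -> ScoreSet:
        cfg = self.config
        scores = MILModel._score_instances(self.network, bag)
        bag_score = pool(scores, cfg.pooling, cfg.pool_k)
        return ScoreSet(
            instance_scores=scores,
            bag_label=bag.bag_label,
            bag_score=bag_score,
            decision=int(bag_score > self.threshold.threshold),
            source_path=bag.source_path,
        )

    def score_sets(self, split: str) -> list[ScoreSet]:
        return [self.score_bag(b) for b in self.model.bags[split]]

    def evaluate(self, split: str = "test") -> EvalReport:
        bags = self.model.bags[split]
        sets = [self.score_bag(b) for b in bags]
        thr = self.threshold.threshold
        inst_labels = np.concatenate(
            [np.full(len(s.instance_scores), b.bag_label) for s, b in zip(sets, bags)]
        )
        inst_decisions = np.concatenate(
            [(s.instance_scores > thr).astype(int) for s in sets]
        )
        return evaluate(
            bag_labels=[b.bag_label for b in bags],
            severities=[b.severity for b in bags],
            decisions=[s.decision for s in sets],
            bag_scores=[s.bag_score for s in sets],
            instance_scores_per_bag=[s.instance_scores for s in sets],
            instance_labels=inst_labels,
            instance_decisions=inst_decisions,
            early_stop_pooling=self.config.early_stop_pooling,
            pool_k=self.config.pool_k,
        )

    def summary(self) -> str:
        cfg = self.config
        val = self.evaluate("val")
        lines = [
            "MIL en face classifier results",
            "=" * 38,
            f"epochs run            {len(self.history):>10d}",
            f"best epoch (bag AUC)  {self.best_epoch:>10d}",
            f"best val bag AUC      {self.best_val_auc:>10.4f}",
            f"threshold (gmean ROC) {self.threshold.threshold:>10.4f}",
            f"  at TPR / FPR        {self.threshold.tpr:>6.3f} / {self.threshold.fpr:.3f}",
            f"pooling               {cfg.pooling:>10s} (k={cfg.pool_k})",
            f"val corrected acc.    {val.corrected_accuracy:>10.4f}",
            f"val F1                {val.f1:>10.4f}",
        ]
        return "\n".join(lines)

    def save_history(self, path: str | Path) -> None:
        self.history.to_csv(path, index=False, float_format="%.10g")

    def save_weights(self, path: str | Path) -> None:
        self.network.save_weights(path)


def train(bags_by_split, config: RunConfig) -> tuple[Network, pd.DataFrame]:
    """Functional wrapper: fit on the given bags, return (network, history)."""
    results = MILModel(bags_by_split, config).fit()
    return results.network, results.history


def infer(results: MILResults, bags: list[Bag]) -> list[ScoreSet]:
    """Score arbitrary bags with a fitted model's pooling and threshold."""
    if results.threshold is None:
        raise ValueError("no operating threshold: fit the model first")
    return [results.score_bag(b) for b in bags]
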