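"""FGSM adversarial robustness evaluation.

The fast gradient sign method perturbs an input x by epsilon * sign of the
gradient of the loss with respect to x: a single step of the strongest
max-norm-bounded attack on a linearized model. Perturbations act in
standardized pixel units (the network's input space); sign(0) = 0, so the
max-norm bound epsilon is attained exactly wherever the gradient is nonzero.

For the MIL classifier each instance is attacked independently through the
instance loss under its inherited bag label (a pooled-loss attack through
the top-k bag score is available as a config switch); for the
single-instance-learning benchmarks the whole image is the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mil_core import EvalReport, evaluate, instance_loss_grad, pool
from .nn import Network

__all__ = ["fgsm_perturb", "fgsm_perturb_pooled", "attack_evaluate", "AttackOutcome"]


def fgsm_perturb(
    model: Network,
    inputs: np.ndarray,
    labels: np.ndarray,
    epsilon: float,
    healthy_weight: float = 1.0,
    clip_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """One FGSM step on a (N, H, W, 1) batch under per-input binary labels.

    Gradients are of the (weighted) binary cross entropy of each input's
    score against its label; inputs are independent through the network, so
    batching equals attacking one by one. ``clip_range`` optionally clamps
    the result back to a raw intensity range (off by default: standardized
    inputs are unbounded).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    x = np.asarray(inputs, dtype=np.float32)
    logits = model.forward(x)[:, 0].astype(np.float64)
    _, dlogit = instance_loss_grad(logits, labels, healthy_weight)
    grad = model.backward(dlogit.astype(np.float32)[:, None])
    adv = x + np.float32(epsilon) * np.sign(grad, dtype=np.float32)
    if clip_range is not None:
        adv = np.clip(adv, *clip_range)
    return adv


def fgsm_perturb_pooled(
    model: Network,
    instances: np.ndarray,
    bag_label: int,
    epsilon: float,
    pooling: str = "topk",
    k: int = 3,
) -> np.ndarray:
    """FGSM against the pooled bag loss of one bag's instances.

    Only the instances that participate in the pooled score receive
    gradient (the top-k set for top-k/max pooling; all of them for mean).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    x = np.asarray(instances, dtype=np.float32)
    logits = model.forward(x)[:, 0].astype(np.float64)
    n = len(logits)
    pooled = pool(logits, pooling, k)
    sig = 1.0 / (1.0 + np.exp(-pooled))
    dpool = sig - bag_label  # d BCE / d pooled logit
    dlogit = np.zeros(n)
    if pooling == "mean":
        dlogit[:] = dpool / n
    else:
        kk = 1 if pooling == "max" else min(k, n)
        top = np.argsort(logits)[-kk:]
        dlogit[top] = dpool / kk
    grad = model.backward(dlogit.astype(np.float32)[:, None])
    return x + np.float32(epsilon) * np.sign(grad, dtype=np.float32)


@dataclass
class AttackOutcome:
    clean: EvalReport
    attacked: EvalReport

    @property
    def corrected_accuracy_drop(self) -> float:
        return self.clean.corrected_accuracy - self.attacked.corrected_accuracy


def attack_evaluate(results, split: str = "test", epsilon: float | None = None) -> AttackOutcome:
    """Re-evaluate a fitted MIL model on FGSM-perturbed bags.

    ``results`` is a fitted :class:`~milenface.training.MILResults`; the
    decision threshold stays fixed at the one selected on clean validation
    data. Returns the clean and attacked reports side by side.
    """
    cfg = results.config
    eps = cfg.epsilon_fgsm if epsilon is None else epsilon
    bags = results.model.bags[split]
    net = results.network
    thr = results.threshold.threshold

    def report(score_lists):
        bag_scores = [pool(s, cfg.pooling, cfg.pool_k) for s in score_lists]
        decisions = [int(bs > thr) for bs in bag_scores]
        inst_labels = np.concatenate(
            [np.full(len(s), b.bag_label) for s, b in zip(score_lists, bags)]
        )
        inst_decisions = np.concatenate([(s > thr).astype(int) for s in score_lists])
        return evaluate(
            bag_labels=[b.bag_label for b in bags],
            severities=[b.severity for b in bags],
            decisions=decisions,
            bag_scores=bag_scores,
            instance_scores_per_bag=score_lists,
            instance_labels=inst_labels,
            instance_decisions=inst_decisions,
            early_stop_pooling=cfg.early_stop_pooling,
            pool_k=cfg.pool_k,
        )

    clean_scores, attacked_scores = [], []
    for bag in bags:
        x = np.asarray(bag.instances, dtype=np.float32)[..., None]
        clean_scores.append(net.forward(x)[:, 0].astype(np.float64))
        if cfg.attack_target == "pooled":
            adv = fgsm_perturb_pooled(
                net, x, bag.bag_label, eps, cfg.pooling, cfg.pool_k
            )
        else:
            labels = np.full(len(bag.instances), bag.bag_label)
            adv = fgsm_perturb(net, x, labels, eps, cfg.healthy_weight)
        attacked_scores.append(net.forward(adv)[:, 0].astype(np.float64))
    return AttackOutcome(clean=report(clean_scores), attacked=report(attacked_scores))
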