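"""Shared fixtures.

``trained_study`` runs the full desk-scale synthetic study once per session
(phantom generation, MIL training, threshold selection) and is shared by the
end-to-end tests; everything else is small and fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import milenface as mf
from milenface.config import desk_scale_run_config


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_phantom_config() -> mf.PhantomConfig:
    """A miniature phantom study for fast pipeline tests."""
    return mf.PhantomConfig(
        image_side=96,
        grid_side=3,
        n_train_pos=6,
        n_train_neg=3,
        n_val_pos=3,
        n_val_neg=3,
        n_test_pos=3,
        n_test_neg=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_run_config() -> mf.RunConfig:
    return mf.RunConfig(
        grid_side=3,
        epochs=2,
        seed=7,
        batch_size=32,
        stem_channels=4,
        block_channels=(4, 6, 6, 8),
    )


def make_separable_bags(
    n_pos: int = 6,
    n_neg: int = 6,
    grid_side: int = 2,
    instance_side: int = 16,
    seed: int = 0,
) -> dict[str, list[mf.Bag]]:
    """Toy bags of flat patches: positives bright, negatives dark.

    Linearly separable at the instance level, so a few epochs suffice for a
    perfect bag AUC.
    """
    rng = np.random.default_rng(seed)
    side = instance_side * grid_side

    def bags(n, label):
        out = []
        for _ in range(n):
            mu = 1.0 if label else -1.0
            pixels = np.repeat(
                np.repeat(
                    rng.normal(mu, 0.1, size=(grid_side, grid_side)),
                    instance_side,
                    axis=0,
                ),
                instance_side,
                axis=1,
            )
            img = mf.EnFaceImage(pixels, bag_label=label, severity="unknown")
            out.append(mf.make_bag(img, grid_side))
        return out

    half = {"train": (n_pos, n_neg), "val": (max(n_pos // 2, 1), max(n_neg // 2, 1))}
    return {
        split: bags(np_, 1) + bags(nn, 0) for split, (np_, nn) in half.items()
    }


@pytest.fixture(scope="session")
def separable_results() -> mf.MILResults:
    """A model fitted on the separable toy problem (shared, ~seconds)."""
    bags = make_separable_bags()
    cfg = mf.RunConfig(
        grid_side=2,
        epochs=5,
        seed=3,
        batch_size=16,
        stem_channels=4,
        block_channels=(4, 4, 6, 6),
    )
    return mf.MILModel(bags, cfg).fit()


@pytest.fixture(scope="session")
def trained_study():
    """The full desk-scale synthetic study: default phantoms, one MIL fit.

    Returns (phantoms_by_split, MILModel, MILResults).
    """
    phantoms = mf.generate_phantoms(mf.PhantomConfig(seed=1))
    model = mf.MILModel.from_phantoms(phantoms, desk_scale_run_config(seed=1))
    results = model.fit()
    return phantoms, model, results
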