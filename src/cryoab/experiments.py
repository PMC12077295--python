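"""The desk-scale parameter-recovery benchmark.

Trains the detector on simulated maps with known planted poses and measures
how well it recovers them on held-out maps — the package's end-to-end
self-check.  Problem sizes are chosen for a single CPU: 64 Å maps (32³
voxels at 2 Å) containing 1-3 antibodies each, 50 training and 20 test
maps.  The default detector is a single network with a slimmed encoder
(one convolution per block at the two finest levels, which feed no decoder
skip) trained long; a small deep ensemble is available as an alternative
but splits the same time budget across members, which at this scale leaves
each member underconfident.  All randomness derives from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import MatchResult, evaluate_system, summary
from .losses import LossWeights, total_loss
from .model import (
    EnsembleModel,
    ModelConfig,
    TrainConfig,
    UNet3D,
    predict_grid,
    train,
)
from .nms import DEFAULT_LIFETIME_THRESHOLD
from .pipeline import detections_from_prediction
from .synthetic import SyntheticSpec, make_dataset, make_pseudo_template


@dataclass
class RecoveryConfig:
    """Study conditions of the benchmark (sizes, training schedule)."""

    n_train: int = 50
    n_test: int = 20
    spec: SyntheticSpec = field(
        default_factory=lambda: SyntheticSpec(extent=64.0, border=12.0, max_antibodies=3)
    )
    model: ModelConfig = field(
        default_factory=lambda: ModelConfig(base_channels=8, slim_low_levels=True)
    )
    n_members: int = 1            # deep-ensemble size (1 = single network)
    epochs: int = 180             # per member
    learning_rate: float = 2e-3
    augment_until: float = 0.7    # disable augmentation for the final epochs
    polyak_tail: float = 0.12     # average weights over the last epochs
    lifetime_threshold: float = DEFAULT_LIFETIME_THRESHOLD


def train_detector(
    train_data, cfg: RecoveryConfig, seed: int, log_every: int = 0
):
    """Train the benchmark's ensemble detector on an encoded dataset."""
    weights = LossWeights()

    def loss_fn(pred, target):
        return total_loss(pred, target, weights)[0]

    members = []
    histories = []
    for mi in range(cfg.n_members):
        member_seed = (seed + 7919 * mi) % 2**31
        model_cfg = ModelConfig(**{**cfg.model.__dict__, "init_seed": member_seed})
        member = UNet3D(model_cfg)
        train_cfg = TrainConfig(
            epochs=cfg.epochs,
            learning_rate=cfg.learning_rate,
            lr_milestones=(int(cfg.epochs * 0.55), int(cfg.epochs * 0.8)),
            lr_decay=0.3,
            seed=member_seed,
            augment=True,
            augment_until=cfg.augment_until,
            polyak_tail=cfg.polyak_tail,
            log_every=log_every,
        )
        member, history = train(member, train_data, loss_fn, train_cfg)
        members.append(member)
        histories.append(history)
    model = members[0] if len(members) == 1 else EnsembleModel(members)
    return model, histories


def run_recovery_experiment(
    seed: int, config: RecoveryConfig | None = None, log_every: int = 0
):
    """Train from scratch and evaluate on held-out maps.

    Returns ``(model, results, stats)``: the trained detector, per-system
    :class:`MatchResult` objects for the held-out maps, and the corpus-level
    metric summary (F1s in percent, distances in Å, angles in degrees).
    """
    cfg = config or RecoveryConfig()
    root = np.random.default_rng(seed)
    train_seed = int(root.integers(2**31 - 1))
    test_seed = int(root.integers(2**31 - 1))
    train_data = make_dataset(cfg.n_train, cfg.spec, seed=train_seed)
    test_data = make_dataset(cfg.n_test, cfg.spec, seed=test_seed)

    model, histories = train_detector(
        [(g, t) for g, t, _ in train_data], cfg, seed, log_every
    )

    templates = {c: make_pseudo_template(c) for c in ("fab", "vhh")}
    results: list[MatchResult] = []
    for grid, _, poses in test_data:
        prediction = predict_grid(model, grid)
        detections = detections_from_prediction(
            prediction, lifetime_threshold=cfg.lifetime_threshold
        )
        results.append(evaluate_system([d.pose for d in detections], poses, templates))
    stats = summary(results)
    stats["final_train_loss"] = float(np.mean([h[-1] for h in histories]))
    return model, results, stats
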